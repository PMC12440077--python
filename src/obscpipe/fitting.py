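"""Heuristic model selection for dose-response data.

The pipeline mirrors an experienced analyst's workflow:

1. *Categorize* the dataset from its per-dose mean survivals into
   Decreasing, Plateau (biphasic), or Growth (hormetic) behavior.
2. Fit every candidate family for that category by bounded nonlinear
   least squares on the replicate points, multi-start around a
   data-driven initial guess.
3. Score each converged fit by Gaussian AIC and a lack-of-fit F-test
   against the saturated cell-means model, merged into a single
   combined criterion (CC): AIC/LoF when AIC > 0, AIC*LoF when AIC < 0,
   lower is better, so a more negative AIC and a LoF closer to 1 are
   always rewarded.
4. Discard fits that over- or undershoot the observed data range, and
   return the best-ranked plausible fit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import models
from .models import ModelSpec

CATEGORIES = ("Decreasing", "Plateau", "Growth")


@dataclass(frozen=True)
class HeuristicThresholds:
    """Tunable constants of the categorization and plausibility rules.

    Defaults are the operational values of the assay: growth means any
    dose-group mean at or above 110% survival; a plateau is a run of at
    least three dose groups whose consecutive mean changes stay under 15
    percentage points, flanked by a larger change; fitted curves may not
    exceed 1.1x the highest observed group mean nor drop more than 50
    percentage points below the lowest.
    """

    growth_threshold: float = 1.10
    plateau_step: float = 0.15
    plateau_min_run: int = 3
    overshoot_factor: float = 1.1
    undershoot_margin: float = 0.50
    require_both_flanks: bool = False
    bp_alpha: float = 0.05

    def __post_init__(self):
        for name in ("growth_threshold", "plateau_step", "overshoot_factor",
                     "undershoot_margin", "bp_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.plateau_min_run < 2:
            raise ValueError("plateau_min_run must be >= 2")


DEFAULT_THRESHOLDS = HeuristicThresholds()


@dataclass
class FittedModel:
    """One fitted family with its goodness-of-fit bookkeeping."""

    spec: ModelSpec
    estimates: dict[str, float]
    rss: float
    n_obs: int
    converged: bool
    aic: float = math.nan
    lof: float | None = None
    cc: float = math.nan
    plausible: bool | None = None
    category: str | None = None

    @property
    def family(self) -> str:
        return self.spec.family

    @property
    def n_free(self) -> int:
        return self.spec.n_free

    def params(self) -> dict[str, float]:
        return self.spec.full_params([self.estimates[p] for p in self.spec.free_params])

    def predict(self, dose) -> np.ndarray | float:
        """Predicted survival fraction at the given dose(s)."""
        return models.evaluate(self.family, self.params(), dose)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "estimates": dict(self.estimates),
            "fixed_params": dict(self.spec.fixed_params),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "lof": self.lof,
            "cc": None if math.isnan(self.cc) else self.cc,
            "converged": self.converged,
            "plausible": self.plausible,
            "category": self.category,
        }


def constant_fit(level: float) -> FittedModel:
    """A degenerate flat 'fit' at a constant survival fraction.

    Useful for constructing reference curves (e.g. an untreated-slice
    control that stays at 100%) without running the optimizer.
    """
    spec = ModelSpec("EXD.3", (), {"c": level, "d": level, "e": 1.0}, {}, {})
    return FittedModel(spec=spec, estimates={}, rss=0.0, n_obs=0, converged=True)


def from_params(family: str, **params: float) -> FittedModel:
    """Wrap explicit parameter values as a converged FittedModel."""
    M = params.pop("M", None)
    spec = models.get_spec(family, M=M)
    estimates = {p: float(params[p]) for p in spec.free_params}
    return FittedModel(spec=spec, estimates=estimates, rss=0.0,
                       n_obs=0, converged=True)


# --------------------------------------------------------------------------
# categorization


def categorize(dataset, thresholds: HeuristicThresholds = DEFAULT_THRESHOLDS) -> str:
    """Sort a dataset into Growth, Plateau, or Decreasing behavior.

    Growth: any dose-group mean survival at or above the growth threshold.
    Plateau: a run of >= plateau_min_run consecutive dose groups whose
    consecutive changes are all below plateau_step, flanked on at least
    one side (both, if ``require_both_flanks``) by a change above it.
    Otherwise Decreasing.
    """
    means = dataset.group_means()
    if len(means) < 4:
        raise ValueError("categorization needs at least 4 dose groups")
    vals = means.to_numpy(dtype=float)

    if np.any(vals >= thresholds.growth_threshold):
        return "Growth"

    steps = np.abs(np.diff(vals))
    small = steps < thresholds.plateau_step
    # runs of consecutive small steps; a run of r small steps spans r+1 groups
    i = 0
    while i < len(small):
        if small[i]:
            j = i
            while j < len(small) and small[j]:
                j += 1
            run_groups = (j - i) + 1
            if run_groups >= thresholds.plateau_min_run:
                left = i > 0 and steps[i - 1] > thresholds.plateau_step
                right = j < len(steps) and steps[j] > thresholds.plateau_step
                flanked = (left and right) if thresholds.require_both_flanks else (left or right)
                if flanked:
                    return "Plateau"
            i = j
        else:
            i += 1
    return "Decreasing"


# --------------------------------------------------------------------------
# fitting


def fit_model(
    spec: ModelSpec,
    dataset,
    starter: Sequence[float] | dict[str, float] | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Bounded least squares on replicate points with jittered multi-start.

    ``n_starts`` initial points (the starter plus seeded 10% multiplicative
    jitters) are tried; the best converged solution is kept.  A fit with no
    converged start is returned with ``converged=False`` and excluded from
    ranking downstream.
    """
    x = dataset.dose_array()
    y = dataset.response_fractions()
    k = len(np.unique(x))
    if spec.n_free > k - 1:
        raise ValueError(
            f"{spec.family}: {spec.n_free} free parameters need more than "
            f"{k} distinct doses for identifiability"
        )

    if starter is None:
        start0 = models.default_starter(spec, dataset)
    elif isinstance(starter, dict):
        start0 = spec.clip_to_bounds([starter[p] for p in spec.free_params])
    else:
        start0 = spec.clip_to_bounds(starter)

    lo, hi = spec.bounds_arrays()
    rng = np.random.default_rng(seed)

    def residuals(free):
        return models.evaluate(spec.family, spec.full_params(free), x) - y

    best = None
    for i in range(max(n_starts, 1)):
        if i == 0:
            p0 = start0
        else:
            p0 = spec.clip_to_bounds(start0 * rng.lognormal(0.0, 0.1, size=start0.size))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.least_squares(
                    residuals, p0, bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
                )
        except Exception:
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
        if rss < 1e-14:  # exact fit; no better start exists
            break

    if best is None:
        return FittedModel(spec=spec, estimates=dict(zip(spec.free_params, start0)),
                           rss=math.inf, n_obs=len(y), converged=False)
    rss, xhat = best
    fit = FittedModel(
        spec=spec,
        estimates={p: float(v) for p, v in zip(spec.free_params, xhat)},
        rss=rss,
        n_obs=len(y),
        converged=True,
    )
    fit.aic = aic(fit)
    fit.lof = lack_of_fit(fit, dataset)
    fit.cc = combined_criterion(fit.aic, fit.lof)
    return fit


def aic(fit: FittedModel) -> float:
    """Gaussian-likelihood AIC with plugged-in variance.

    AIC = n*(ln(2*pi*RSS/n) + 1) + 2*(p + 1); the +1 counts the estimated
    residual variance.  RSS = 0 returns -inf (an exact fit wins any
    comparison; flagged by the sentinel itself).
    """
    if not fit.converged:
        raise ValueError("AIC undefined for non-converged fit")
    n, p, rss = fit.n_obs, fit.n_free, fit.rss
    if rss <= 0.0:
        return -math.inf
    return n * (math.log(2 * math.pi * rss / n) + 1) + 2 * (p + 1)


def lack_of_fit(fit: FittedModel, dataset) -> float | None:
    """Lack-of-fit F-test p-value against the saturated cell-means model.

    F = [(RSS_model - RSS_sat)/(k - p)] / [RSS_sat/(n - k)] with k distinct
    doses and p free parameters; the upper-tail p-value is returned.  A
    value near 1 means the parametric curve tracks the per-dose means as
    well as pure replicate noise allows.  ``None`` when there is no
    replication (or no residual degrees of freedom) to test against.
    """
    x = dataset.dose_array()
    y = dataset.response_fractions()
    k = len(np.unique(x))
    n = len(y)
    p = fit.n_free
    if n <= k or k <= p:
        return None
    group_mean = {d: y[x == d].mean() for d in np.unique(x)}
    rss_sat = float(sum((y[x == d] - group_mean[d]) @ (y[x == d] - group_mean[d])
                        for d in group_mean))
    rss_model = fit.rss
    if rss_sat <= 0.0:
        # replicates identical: any model residual is infinitely unlikely
        return 1.0 if rss_model <= 1e-300 else 0.0
    f_stat = max(rss_model - rss_sat, 0.0) / (k - p) / (rss_sat / (n - k))
    return float(stats.f.sf(f_stat, k - p, n - k))


def combined_criterion(aic_value: float, lof: float | None) -> float:
    """Merge AIC and lack-of-fit into one ranking value (lower is better).

    CC = AIC/LoF when AIC > 0, AIC*LoF when AIC < 0.  Without replication
    (LoF unavailable) CC degrades to the AIC alone.
    """
    if lof is None:
        return aic_value
    if not 0.0 <= lof <= 1.0:
        raise ValueError("LoF must lie in [0, 1]")
    if aic_value == -math.inf:
        return -math.inf
    if aic_value > 0:
        return math.inf if lof == 0.0 else aic_value / lof
    return aic_value * lof


def plausibility_check(
    fit: FittedModel,
    dataset,
    thresholds: HeuristicThresholds = DEFAULT_THRESHOLDS,
    n_grid: int = 1000,
) -> bool:
    """Reject fits that stray outside the range of the observed data.

    The curve is evaluated on a uniform grid over [0, max dose]; it is
    plausible iff its maximum stays at or below overshoot_factor times the
    highest observed group mean and its minimum at or above the lowest
    group mean minus undershoot_margin (fractional scale).
    """
    means = dataset.group_means()
    grid = np.linspace(0.0, dataset.max_dose, n_grid)
    pred = np.asarray(fit.predict(grid))
    hi_ok = float(np.max(pred)) <= thresholds.overshoot_factor * float(means.max())
    lo_ok = float(np.min(pred)) >= float(means.min()) - thresholds.undershoot_margin
    return bool(hi_ok and lo_ok)


def select_model(
    dataset,
    thresholds: HeuristicThresholds = DEFAULT_THRESHOLDS,
    seed: int = 0,
    n_starts: int = 5,
) -> FittedModel:
    """Fit every in-category candidate and return the best plausible one.

    Converged fits are ranked by ascending combined criterion (ties broken
    by fewer free parameters, then registry order); the first plausible fit
    wins.  When none is plausible the best-CC fit is returned flagged
    implausible, with a warning, so whole-plate runs never silently fail.
    """
    category = categorize(dataset, thresholds)
    M = models.dynamic_rbc_M(dataset) if category == "Growth" else None
    specs = models.model_registry(category, M=M)

    logger = logging.getLogger("obscpipe")
    logger.info("category: %s (%d candidate families)", category, len(specs))
    fits: list[FittedModel] = []
    for order, spec in enumerate(specs):
        k = len(dataset.doses)
        if spec.n_free > k - 1:
            logger.info("  %-7s skipped: %d free params, %d doses",
                        spec.family, spec.n_free, k)
            continue  # unidentifiable on this dose ladder
        fit = fit_model(spec, dataset, n_starts=n_starts, seed=seed + order)
        fit.category = category
        if fit.converged:
            logger.info("  %-7s AIC %10.3f  LoF %s  CC %10.3f", fit.family,
                        fit.aic, "n/a " if fit.lof is None else f"{fit.lof:.3f}",
                        fit.cc)
            fits.append(fit)
        else:
            logger.info("  %-7s did not converge", spec.family)
    if not fits:
        raise RuntimeError("no candidate model converged")

    order_index = {spec.family: i for i, spec in enumerate(specs)}
    fits.sort(key=lambda f: (f.cc, f.n_free, order_index[f.family]))
    for fit in fits:
        if plausibility_check(fit, dataset, thresholds):
            fit.plausible = True
            logger.info("selected %s (CC %.3f)", fit.family, fit.cc)
            return fit
        logger.info("  %-7s eliminated: prediction outside plausible range",
                    fit.family)
    warnings.warn("no plausible candidate model; returning best-CC fit flagged "
                  "implausible", stacklevel=2)
    best = fits[0]
    best.plausible = False
    return best
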