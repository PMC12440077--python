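"""The Drug Sensitivity Score: eleven bounded tumor-vs-slice windows.

Each window contrasts on-target tumor kill with off-target toxicity to the
host brain slice and takes a value in [-1, 1]: +1 means the treatment acts
far more on the tumor, -1 far more on the slice.  The weighted sum of the
eleven windows is the DSS, ranging from -100 to +100.

Windows (with default weights in percent points):

=========  ======  ====================================================
window     weight  meaning
=========  ======  ====================================================
ED10..90   5/10/5  tumor-vs-slice kill gap at the dose of xx% tumor kill
                   (ED50 weighs 10; the other four 5 each)
AUC        35      normalized difference of the curves' areas
TGA        5       penalty for treatment-accelerated tumor growth
IK         10      penalty for incomplete tumor kill at the top dose
MK         10      tumor vs slice kill at the top dose
BP         5       biphasic check: are the three highest tumor dose
                   groups statistically distinguishable?
Slope      5       steepness comparison at the tumor ED50 (or top dose)
=========  ======  ====================================================

All evaluations are confined to the tested dose range [0, max dose]; no
extrapolation.  An EDxx window whose kill level the tumor curve never
reaches in range is undefined and contributes 0 points (incomplete kill
is already penalized by IK).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

ED_LEVELS = (10, 25, 50, 75, 90)
WINDOW_NAMES = ("ED10", "ED25", "ED50", "ED75", "ED90",
                "AUC", "TGA", "IK", "MK", "BP", "Slope")

DEFAULT_WEIGHTS: dict[str, float] = {
    "AUC": 35.0,
    "MK": 10.0, "IK": 10.0, "ED50": 10.0,
    "BP": 5.0, "ED10": 5.0, "ED25": 5.0, "ED75": 5.0, "ED90": 5.0,
    "TGA": 5.0, "Slope": 5.0,
}

_SLOPE_FLAT_TOL = 1e-6


@dataclass
class WindowSet:
    """The eleven window values; EDxx entries may be None (undefined)."""

    ED10: float | None
    ED25: float | None
    ED50: float | None
    ED75: float | None
    ED90: float | None
    AUC: float
    TGA: float
    IK: float
    MK: float
    BP: float | None
    Slope: float

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __post_init__(self):
        for name, value in self.as_dict().items():
            if value is not None and not -1.0 <= value <= 1.0:
                raise ValueError(f"window {name}={value} outside [-1, 1]")


class WeightTable(dict):
    """Per-window weights in percent points; must sum to 100."""

    def __init__(self, weights: Mapping[str, float] | None = None):
        super().__init__(DEFAULT_WEIGHTS if weights is None else dict(weights))
        missing = set(WINDOW_NAMES) - set(self)
        if missing:
            raise ValueError(f"missing weights for {sorted(missing)}")
        total = sum(self[w] for w in WINDOW_NAMES)
        if not math.isclose(total, 100.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 100, got {total}")


@dataclass
class DSSResult:
    windows: WindowSet
    weights: WeightTable
    contributions: dict[str, float]
    total: float
    undefined_windows: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "windows": self.windows.as_dict(),
            "weights": dict(self.weights),
            "contributions": dict(self.contributions),
            "total": self.total,
            "undefined_windows": list(self.undefined_windows),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def waterfall(self) -> pd.DataFrame:
        """Window-by-window decomposition with a running total."""
        rows, running = [], 0.0
        for name in WINDOW_NAMES:
            contrib = self.contributions[name]
            running += contrib
            rows.append({"window": name, "value": self.windows.as_dict()[name],
                         "weight": self.weights[name], "contribution": contrib,
                         "running_total": running})
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# per-window computations; "fit" arguments are any object with .predict(dose)
# returning survival fraction and a .converged flag


def _check_converged(*fits) -> None:
    for fit in fits:
        if not getattr(fit, "converged", True):
            raise ValueError("window evaluation requires converged fits")


def ed_dose(tumor_fit, level: int, max_dose: float) -> float | None:
    """Smallest dose in [0, max_dose] where the tumor curve predicts
    ``level``% killing (survival 1 - level/100); None if never reached."""
    _check_converged(tumor_fit)
    if level not in ED_LEVELS:
        raise ValueError(f"ED level must be one of {ED_LEVELS}")
    target = 1.0 - level / 100.0
    grid = np.linspace(0.0, max_dose, 2048)
    pred = np.asarray(tumor_fit.predict(grid)) - target
    if pred[0] <= 0:
        return 0.0
    below = np.nonzero(pred <= 0)[0]
    if below.size == 0:
        return None
    j = below[0]
    return float(optimize.brentq(
        lambda x: float(tumor_fit.predict(x)) - target, grid[j - 1], grid[j],
        xtol=1e-10 * max(max_dose, 1.0),
    ))


def edxx_window(tumor_fit, obsc_fit, level: int, max_dose: float) -> float | None:
    """Tumor-vs-slice kill gap at the tumor's EDxx dose.

    Slice survival above 100% at that dose scores the maximal 1.  Otherwise
    the gap (TumorKill - OBSCKill) is normalized by the larger of the two
    kills, keeping the value in [-1, 1].
    """
    _check_converged(tumor_fit, obsc_fit)
    dose = ed_dose(tumor_fit, level, max_dose)
    if dose is None:
        return None
    obsc_surv = 100.0 * float(obsc_fit.predict(dose))
    if obsc_surv > 100.0:
        return 1.0
    tumor_kill = float(level)
    obsc_kill = 100.0 - obsc_surv
    if obsc_kill < tumor_kill:
        return (tumor_kill - obsc_kill) / tumor_kill
    if obsc_kill == tumor_kill:
        return 0.0
    return (tumor_kill - obsc_kill) / obsc_kill


def auc_window(tumor_fit, obsc_fit, max_dose: float) -> float:
    """Normalized difference of the areas under the two survival curves."""
    _check_converged(tumor_fit, obsc_fit)
    t_auc = integrate.quad(lambda x: float(tumor_fit.predict(x)), 0.0, max_dose,
                           limit=200)[0]
    o_auc = integrate.quad(lambda x: float(obsc_fit.predict(x)), 0.0, max_dose,
                           limit=200)[0]
    if t_auc == 0.0 and o_auc == 0.0:
        return 0.0
    denom = o_auc if o_auc > t_auc else t_auc
    return float(np.clip((o_auc - t_auc) / denom, -1.0, 1.0))


def tga_window(tumor_fit, max_dose: float, n_grid: int = 1000,
               dataset=None) -> float:
    """Tumor-growth-acceleration check on the fitted tumor curve.

    Max predicted survival over [0, max dose] above 150% scores -1, above
    125% scores 0, otherwise +1.  Passing ``dataset`` switches the check
    to the observed group means instead of the fitted curve.
    """
    _check_converged(tumor_fit)
    if dataset is not None:
        max_surv = 100.0 * float(dataset.group_means().max())
    else:
        grid = np.linspace(0.0, max_dose, n_grid)
        max_surv = 100.0 * float(np.max(np.asarray(tumor_fit.predict(grid))))
    if max_surv > 150.0:
        return -1.0
    if max_surv > 125.0:
        return 0.0
    return 1.0


def ik_window(tumor_fit, max_dose: float, dataset=None) -> float:
    """Incomplete-kill check: tumor survival at the highest tested dose.

    Above 25% scores -1, above 10% scores 0, at or below 10% scores +1.
    Passing ``dataset`` reads the observed group mean at the top dose
    instead of the fitted curve.
    """
    _check_converged(tumor_fit)
    if dataset is not None:
        surv = 100.0 * float(dataset.group_means().loc[dataset.max_dose])
    else:
        surv = 100.0 * float(tumor_fit.predict(max_dose))
    if surv > 25.0:
        return -1.0
    if surv > 10.0:
        return 0.0
    return 1.0


def mk_window(tumor_fit, obsc_fit, max_dose: float) -> float:
    """Tumor kill vs slice kill at the highest tested dose, normalized by
    the larger kill and clamped to [-1, 1] when a kill is negative
    (net growth at the top dose)."""
    _check_converged(tumor_fit, obsc_fit)
    tk = 100.0 - 100.0 * float(tumor_fit.predict(max_dose))
    ok = 100.0 - 100.0 * float(obsc_fit.predict(max_dose))
    if tk == ok:
        return 0.0
    denom = tk if tk > ok else ok
    if denom <= 0.0:
        denom = max(abs(tk), abs(ok))
        if denom == 0.0:
            return 0.0
    return float(np.clip((tk - ok) / denom, -1.0, 1.0))


def bp_window(tumor_dataset, alpha: float = 0.05) -> float | None:
    """Biphasic check: one-way ANOVA across the three highest tumor dose
    groups at significance level ``alpha``; significant separation scores
    +1 (still actively killing), indistinguishable groups score -1.

    None (undefined; contributes 0) when fewer than three dose groups or
    any of them lacks replication.
    """
    counts = tumor_dataset.replicate_counts()
    doses = counts.index.to_numpy(dtype=float)
    if len(doses) < 3:
        return None
    top3 = np.sort(doses)[-3:]
    if any(counts[d] < 2 for d in top3):
        return None
    x = tumor_dataset.dose_array()
    y = tumor_dataset.response_fractions()
    groups = [y[x == d] for d in top3]
    stat, p = stats.f_oneway(*groups)
    if not np.isfinite(p):  # identical groups: zero within-group variance
        p = 1.0 if np.isclose(stat, 0) or np.isnan(stat) else 0.0
    return 1.0 if p < alpha else -1.0


def slope_window(tumor_fit, obsc_fit, max_dose: float) -> float:
    """Compare curve steepness at the tumor ED50 (top dose if undefined).

    Slopes are absolute central finite differences (step 1e-4 x max dose);
    two flat curves score 0, otherwise the difference is normalized by the
    larger magnitude.
    """
    _check_converged(tumor_fit, obsc_fit)
    dose = ed_dose(tumor_fit, 50, max_dose)
    if dose is None:
        dose = max_dose
    h = 1e-4 * max_dose
    lo, hi = max(dose - h, 0.0), min(dose + h, max_dose)

    def abs_slope(fit):
        return abs((float(fit.predict(hi)) - float(fit.predict(lo))) / (hi - lo))

    t, o = abs_slope(tumor_fit), abs_slope(obsc_fit)
    if t < _SLOPE_FLAT_TOL and o < _SLOPE_FLAT_TOL:
        return 0.0
    denom = t if t > o else o
    return float(np.clip((t - o) / denom, -1.0, 1.0))


# --------------------------------------------------------------------------


def compute_windows(tumor_fit, obsc_fit, tumor_dataset,
                    max_dose: float | None = None,
                    alpha: float = 0.05) -> WindowSet:
    """Evaluate all eleven windows for a paired tumor/slice experiment."""
    if max_dose is None:
        max_dose = tumor_dataset.max_dose
    ed = {lvl: edxx_window(tumor_fit, obsc_fit, lvl, max_dose) for lvl in ED_LEVELS}
    return WindowSet(
        ED10=ed[10], ED25=ed[25], ED50=ed[50], ED75=ed[75], ED90=ed[90],
        AUC=auc_window(tumor_fit, obsc_fit, max_dose),
        TGA=tga_window(tumor_fit, max_dose),
        IK=ik_window(tumor_fit, max_dose),
        MK=mk_window(tumor_fit, obsc_fit, max_dose),
        BP=bp_window(tumor_dataset, alpha=alpha),
        Slope=slope_window(tumor_fit, obsc_fit, max_dose),
    )


def compute_dss(windows: WindowSet, weights: WeightTable | Mapping | None = None) -> DSSResult:
    """Weighted sum of the windows; undefined windows contribute 0 points."""
    if not isinstance(weights, WeightTable):
        weights = WeightTable(weights)
    contributions: dict[str, float] = {}
    undefined: list[str] = []
    values = windows.as_dict()
    for name in WINDOW_NAMES:
        value = values[name]
        if value is None:
            contributions[name] = 0.0
            undefined.append(name)
        else:
            contributions[name] = weights[name] * value
    total = float(sum(contributions.values()))
    return DSSResult(windows=windows, weights=weights,
                     contributions=contributions, total=total,
                     undefined_windows=undefined)
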