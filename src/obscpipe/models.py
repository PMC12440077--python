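"""Dose-response model families, fixed parameters, and box constraints.

Eleven families are considered, on the fractional survival scale
(1.0 == 100%), all anchored so that survival at dose 0 equals the upper
asymptote ``d`` (fixed at 1 wherever the family permits fixing):

* ``LL.4``   four-parameter log-logistic
* ``W1.4``   Weibull type 1
* ``W2.4``   Weibull type 2 (slope ``b`` negative by convention)
* ``EXD.3``  three-parameter exponential decay
* ``CRS.4a/b/c``, ``CRS.5a/b``  Cedergreen-Ritz-Streibig hormesis models
  (the a/b/c variants fix the hormesis shape exponent ``alpha`` at
  1, 0.5 and 0.25 respectively; the 4-parameter variants pin the lower
  asymptote at 0, the 5-parameter variants leave it free)
* ``BC.5``   Brain-Cousens hormesis model
* ``RBC.5``  Brain-Cousens reparametrized so that the dose of maximum
  (hormetic) growth, ``M``, is an explicit parameter fixed from the data

Box limits follow the operational parameter tables used by the assay;
open limits written (a, inf) are implemented as [a + 1e-9, 1e9] for the
optimizer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

OPEN_EPS = 1e-9
BIG = 1e9

FAMILIES = (
    "LL.4", "W1.4", "W2.4", "EXD.3",
    "CRS.4a", "CRS.4b", "CRS.4c", "CRS.5a", "CRS.5b",
    "BC.5", "RBC.5",
)

CATEGORY_FAMILIES = {
    "Decreasing": ["LL.4", "W1.4", "W2.4", "EXD.3"],
    "Plateau": ["LL.4", "W1.4", "W2.4", "EXD.3",
                "CRS.4a", "CRS.4b", "CRS.4c", "CRS.5a", "CRS.5b"],
    "Growth": ["LL.4", "W1.4", "W2.4", "EXD.3",
               "CRS.4a", "CRS.4b", "CRS.4c", "CRS.5a", "CRS.5b",
               "BC.5", "RBC.5"],
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family with its fixed parameters and free-parameter bounds."""

    family: str
    free_params: tuple[str, ...]
    fixed_params: Mapping[str, float]
    lower: Mapping[str, float]
    upper: Mapping[str, float]

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def full_params(self, free_values: Sequence[float]) -> dict[str, float]:
        params = dict(self.fixed_params)
        params.update(zip(self.free_params, free_values))
        return params

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.lower[p] for p in self.free_params])
        hi = np.array([self.upper[p] for p in self.free_params])
        return lo, hi

    def clip_to_bounds(self, free_values: Sequence[float]) -> np.ndarray:
        lo, hi = self.bounds_arrays()
        return np.clip(np.asarray(free_values, dtype=float), lo, hi)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "free_params": list(self.free_params),
            "fixed_params": dict(self.fixed_params),
            "lower": dict(self.lower),
            "upper": dict(self.upper),
        }


# --------------------------------------------------------------------------
# curve functions; params is a full map {b, c, d, e, f, alpha, M} as needed


def _loglogistic_gate(b: float, e: float, x: np.ndarray) -> np.ndarray:
    """1 + exp(b*(ln x - ln e)) = 1 + (x/e)^b, with the dose-0 limit built in."""
    out = np.ones_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):
        out[pos] = 1.0 + np.exp(np.clip(b * (np.log(x[pos]) - math.log(e)), -700, 700))
    if b < 0:
        out[~pos] = np.inf
    return out


def ll4(params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    b, c, d, e = params["b"], params["c"], params["d"], params["e"]
    return c + (d - c) / _loglogistic_gate(b, e, x)


def w14(params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    b, c, d, e = params["b"], params["c"], params["d"], params["e"]
    out = np.full_like(x, d, dtype=float)
    pos = x > 0
    t = np.exp(np.clip(b * (np.log(x[pos]) - math.log(e)), -700, 700))
    out[pos] = c + (d - c) * np.exp(-t)
    return out


def w24(params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    b, c, d, e = params["b"], params["c"], params["d"], params["e"]
    out = np.full_like(x, d, dtype=float)  # b < 0: limit at dose 0 is d
    pos = x > 0
    t = np.exp(np.clip(b * (np.log(x[pos]) - math.log(e)), -700, 700))
    out[pos] = c + (d - c) * (1.0 - np.exp(-t))
    return out


def exd3(params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    c, d, e = params["c"], params["d"], params["e"]
    return c + (d - c) * np.exp(-x / e)


def crs(params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    b, c, d, e, f, alpha = (params[k] for k in ("b", "c", "d", "e", "f", "alpha"))
    out = np.full_like(x, d, dtype=float)
    pos = x > 0
    xp = x[pos]
    horm = f * np.exp(-1.0 / xp**alpha)
    gate = 1.0 + np.exp(np.clip(b * (np.log(xp) - math.log(e)), -700, 700))
    out[pos] = c + (d - c + horm) / gate
    return out


def bc5(params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    b, c, d, e, f = (params[k] for k in ("b", "c", "d", "e", "f"))
    out = np.full_like(x, d, dtype=float)
    pos = x > 0
    xp = x[pos]
    gate = 1.0 + np.exp(np.clip(b * (np.log(xp) - math.log(e)), -700, 700))
    out[pos] = c + (d - c + f * xp) / gate
    return out


def rbc_e_star(b: float, c: float, d: float, f: float, M: float) -> float:
    """The e that places the Brain-Cousens maximum exactly at dose M.

    Setting dBC.5/dx = 0 at x = M gives (M/e)^b = f*M / (b*(d-c+f*M) - f*M),
    positive whenever b >= 1, d > c and f > 0.
    """
    denom = b * (d - c + f * M) - f * M
    if denom <= 0 or f <= 0 or M <= 0:
        raise ValueError("no interior hormesis maximum for these parameters")
    u = f * M / denom
    return M / u ** (1.0 / b)


def rbc5(params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    b, c, d, f, M = (params[k] for k in ("b", "c", "d", "f", "M"))
    e = rbc_e_star(b, c, d, f, M)
    return bc5({"b": b, "c": c, "d": d, "e": e, "f": f}, x)


CURVES: dict[str, Callable[[Mapping[str, float], np.ndarray], np.ndarray]] = {
    "LL.4": ll4,
    "W1.4": w14,
    "W2.4": w24,
    "EXD.3": exd3,
    "CRS.4a": crs,
    "CRS.4b": crs,
    "CRS.4c": crs,
    "CRS.5a": crs,
    "CRS.5b": crs,
    "BC.5": bc5,
    "RBC.5": rbc5,
}


def evaluate(family: str, params: Mapping[str, float], dose) -> np.ndarray | float:
    """Evaluate a family's survival fraction at one or many doses >= 0."""
    if family not in CURVES:
        raise KeyError(f"unknown model family {family!r}")
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise ValueError("doses must be non-negative")
    scalar = x.ndim == 0
    y = CURVES[family](params, np.atleast_1d(x).astype(float))
    return float(y[0]) if scalar else y


# --------------------------------------------------------------------------
# registry


def _spec(family, free, fixed, lower, upper) -> ModelSpec:
    return ModelSpec(family, tuple(free), dict(fixed), dict(lower), dict(upper))


def _build_registry() -> dict[str, ModelSpec]:
    reg = {}
    reg["LL.4"] = _spec(
        "LL.4", ("b", "c", "e"), {"d": 1.0},
        {"b": 1 + OPEN_EPS, "c": OPEN_EPS, "e": 0.0001},
        {"b": BIG, "c": 1 - OPEN_EPS, "e": BIG},
    )
    reg["W1.4"] = _spec(
        "W1.4", ("b", "c", "e"), {"d": 1.0},
        {"b": 1 + OPEN_EPS, "c": OPEN_EPS, "e": 0.0001},
        {"b": 50.0, "c": 1 - OPEN_EPS, "e": BIG},
    )
    reg["W2.4"] = _spec(
        "W2.4", ("b", "c", "e"), {"d": 1.0},
        {"b": -50.0, "c": OPEN_EPS, "e": 0.0001},
        {"b": -0.3, "c": 1 - OPEN_EPS, "e": 10000.0},
    )
    reg["EXD.3"] = _spec(
        "EXD.3", ("c", "e"), {"d": 1.0},
        {"c": OPEN_EPS, "e": 0.0001},
        {"c": BIG, "e": 10000.0},
    )
    for variant, alpha in (("a", 1.0), ("b", 0.5), ("c", 0.25)):
        reg[f"CRS.4{variant}"] = _spec(
            f"CRS.4{variant}", ("b", "d", "e", "f"), {"c": 0.0, "alpha": alpha},
            {"b": 1 + OPEN_EPS, "d": 0.95, "e": 0.000001, "f": -BIG},
            {"b": 250.0, "d": 1.05, "e": BIG, "f": BIG},
        )
    for variant, alpha in (("a", 1.0), ("b", 0.5)):
        reg[f"CRS.5{variant}"] = _spec(
            f"CRS.5{variant}", ("b", "c", "d", "e", "f"), {"alpha": alpha},
            {"b": 1 + OPEN_EPS, "c": OPEN_EPS, "d": 0.95, "e": 0.000001, "f": -10.0},
            {"b": 250.0, "c": 10.0, "d": 1.05, "e": BIG, "f": BIG},
        )
    reg["BC.5"] = _spec(
        "BC.5", ("b", "c", "e", "f"), {"d": 1.0},
        {"b": 1 + OPEN_EPS, "c": OPEN_EPS, "e": OPEN_EPS, "f": 0.000001},
        {"b": BIG, "c": BIG, "e": BIG, "f": BIG},
    )
    # M is fixed dynamically per dataset; a placeholder spec carries the bounds
    reg["RBC.5"] = _spec(
        "RBC.5", ("b", "c", "f"), {"d": 1.0},
        {"b": 1 + OPEN_EPS, "c": OPEN_EPS, "f": 0.000001},
        {"b": 50.0, "c": BIG, "f": BIG},
    )
    return reg


REGISTRY: dict[str, ModelSpec] = _build_registry()


def get_spec(family: str, M: float | None = None) -> ModelSpec:
    """Look up a family spec; RBC.5 requires the dynamically fixed peak dose M."""
    if family not in REGISTRY:
        raise KeyError(f"unknown model family {family!r}")
    spec = REGISTRY[family]
    if family == "RBC.5":
        if M is None:
            raise ValueError("RBC.5 needs the dynamically determined peak dose M")
        fixed = dict(spec.fixed_params)
        fixed["M"] = float(M)
        spec = ModelSpec(spec.family, spec.free_params, fixed, spec.lower, spec.upper)
    return spec


def model_registry(category: str, M: float | None = None) -> list[ModelSpec]:
    """Candidate models for one heuristic category of dose-response behavior."""
    if category not in CATEGORY_FAMILIES:
        raise KeyError(f"unknown category {category!r}")
    return [get_spec(f, M=M) for f in CATEGORY_FAMILIES[category]]


def registry_to_json(path: str | Path) -> None:
    payload = {fam: REGISTRY[fam].to_dict() for fam in FAMILIES}
    Path(path).write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# data-driven parameter helpers


def dynamic_rbc_M(dataset) -> float:
    """Peak-growth dose for RBC.5: the nonzero dose with maximal mean survival.

    Ties break toward the smaller dose.  On monotone-decreasing data this
    degenerates to the smallest nonzero dose (flagged via warning).
    """
    means = dataset.group_means()
    nz = means[means.index > 0]
    if nz.empty:
        raise ValueError("no nonzero dose group")
    best = float(nz.index[np.argmax(nz.to_numpy())])  # argmax takes first on ties
    if np.argmax(nz.to_numpy()) == 0 and nz.iloc[0] <= means.iloc[0] and nz.is_monotonic_decreasing:
        import warnings

        warnings.warn("monotone-decreasing means: RBC.5 peak dose degenerates to the "
                      "smallest nonzero dose", stacklevel=2)
    return best


def exd_self_start(dataset) -> dict[str, float]:
    """Initial EXD.3 parameters from linear interpolation of group means.

    c0 is the smallest group mean (clamped into bounds); e0 is the dose at
    which the piecewise-linear interpolant of the group means first crosses
    the 1/e decay level c0 + (1 - c0)*exp(-1), falling back to the maximum
    dose when the means never cross it.
    """
    means = dataset.group_means()
    if len(means) < 3:
        raise ValueError("self-starter needs >= 3 dose groups")
    spec = REGISTRY["EXD.3"]
    c0 = float(np.clip(means.min(), spec.lower["c"], spec.upper["c"]))
    target = c0 + (1.0 - c0) * math.exp(-1.0)
    doses = means.index.to_numpy(dtype=float)
    vals = means.to_numpy(dtype=float)
    e0 = doses[-1]
    for i in range(len(doses) - 1):
        y0, y1 = vals[i], vals[i + 1]
        if (y0 - target) * (y1 - target) <= 0 and y0 != y1:
            e0 = doses[i] + (target - y0) * (doses[i + 1] - doses[i]) / (y1 - y0)
            break
    e0 = float(np.clip(e0, spec.lower["e"], spec.upper["e"]))
    return {"c": c0, "e": e0}


def default_starter(spec: ModelSpec, dataset) -> np.ndarray:
    """A data-driven initial point inside the box for any registry family."""
    means = dataset.group_means()
    min_mean = float(means.min())
    max_mean = float(means.max())
    pos_doses = means.index.to_numpy(dtype=float)
    pos_doses = pos_doses[pos_doses > 0]
    mid_dose = float(np.exp(np.mean(np.log(pos_doses)))) if pos_doses.size else 1.0

    if spec.family == "EXD.3":
        start = exd_self_start(dataset)
        start = {"c": start["c"], "e": start["e"]}
    elif spec.family == "W2.4":
        start = {"b": -2.0, "c": min_mean, "e": mid_dose}
    elif spec.family in ("LL.4", "W1.4"):
        start = {"b": 2.0, "c": min_mean, "e": mid_dose}
    elif spec.family.startswith("CRS"):
        alpha = spec.fixed_params["alpha"]
        c0 = min(min_mean, 0.9)
        nz = means[means.index > 0]
        x_peak = float(nz.idxmax())
        peak_val = float(nz.max())
        # e0: dose where the means fall halfway from the peak to the floor
        half = (peak_val + min_mean) / 2.0
        e0 = mid_dose
        after = nz.loc[nz.index >= x_peak]
        for x0, x1 in zip(after.index[:-1], after.index[1:]):
            y0, y1 = after[x0], after[x1]
            if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
                e0 = float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
                break
        b0 = 3.0
        # invert the curve at the observed peak for the hormesis height f
        gate = 1.0 + (x_peak / e0) ** b0
        f0 = ((peak_val - c0) * gate - (1.0 - c0)) / math.exp(-1.0 / x_peak**alpha)
        if not math.isfinite(f0) or f0 == 0:
            f0 = 0.5
        start = {"b": b0, "c": c0, "d": 1.0, "e": e0, "f": f0}
    elif spec.family == "BC.5":
        peak_dose = dynamic_rbc_M(dataset) if max_mean > 1 else mid_dose
        start = {"b": 2.0, "c": min_mean, "e": mid_dose,
                 "f": max((max_mean - 1.0) / max(peak_dose, 1e-6), 1e-4)}
    elif spec.family == "RBC.5":
        M = spec.fixed_params["M"]
        start = {"b": 2.0, "c": min_mean,
                 "f": max((max_mean - 1.0) / max(M, 1e-6), 1e-4)}
    else:  # pragma: no cover
        raise KeyError(spec.family)

    vec = np.array([start[p] for p in spec.free_params], dtype=float)
    return spec.clip_to_bounds(vec)
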