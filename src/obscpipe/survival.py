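"""Control-normalized percent survival and method-agreement statistics.

Two normalization schemes are used by the assay:

* Micro-tumor survival (bioluminescence): every raw signal is divided by
  the mean of the untreated (dose 0) negative-control group, so the
  negative controls have a defined mean survival of 100%.
* Slice (OBSC) survival (propidium-iodide fluorescence): the assay carries
  both a negative control (healthy slices) and a positive control (fully
  killed slices).  The negative-control mean is subtracted from every
  signal, the result is divided by the post-subtraction positive-control
  mean to give percent *killing*, and survival = 100 - killing.  A signal
  at the negative-control mean maps to 100% survival, at the
  positive-control mean to 0%, and halfway between to 50%.

Survival is stored as percent in records and on disk, and converted to the
fractional scale (1.0 == 100%) for model fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"
TREATED = "treated"
GROUP_ROLES = (NEGATIVE_CONTROL, POSITIVE_CONTROL, TREATED)

#: on-disk column order for survival CSV files
CSV_COLUMNS = ["target_id", "dose", "dose_units", "group_role", "survival_pct"]


@dataclass
class SurvivalRecord:
    """One target (micro-tumor or slice) with its normalized survival."""

    target_id: str
    dose: float
    group_role: str
    survival_pct: float
    dose_units: str = "uM"
    raw_signal: float | None = None

    def __post_init__(self) -> None:
        if self.group_role not in GROUP_ROLES:
            raise ValueError(f"unknown group_role {self.group_role!r}")
        if self.group_role == NEGATIVE_CONTROL and self.dose != 0:
            raise ValueError("negative controls must have dose 0")
        if not np.isfinite(self.survival_pct):
            raise ValueError("survival_pct must be finite")


class DoseResponseDataset:
    """Replicate percent-survival measurements grouped by dose.

    Positive-control records are retained but excluded from the dose
    ladder and group statistics: they calibrate the normalization, not
    the dose-response curve.
    """

    def __init__(self, records: Sequence[SurvivalRecord]):
        records = list(records)
        if not records:
            raise ValueError("dataset needs at least one record")
        self.records = records
        curve = [r for r in records if r.group_role != POSITIVE_CONTROL]
        doses = sorted({r.dose for r in curve})
        if len(doses) < 2 or 0.0 not in doses:
            raise ValueError("need >= 2 distinct doses including dose 0")
        self.doses = np.asarray(doses, dtype=float)
        self._curve = curve

    # -- array views used by the fitting code -------------------------------

    def dose_array(self) -> np.ndarray:
        return np.array([r.dose for r in self._curve], dtype=float)

    def response_fractions(self) -> np.ndarray:
        return np.array([r.survival_pct for r in self._curve], dtype=float) / 100.0

    def group_means(self) -> pd.Series:
        """Per-dose mean survival on the fractional scale, indexed by dose."""
        s = pd.Series(self.response_fractions(), index=self.dose_array())
        return s.groupby(level=0).mean().sort_index()

    def group_sds(self) -> pd.Series:
        s = pd.Series(self.response_fractions(), index=self.dose_array())
        return s.groupby(level=0).std(ddof=1).sort_index()

    def replicate_counts(self) -> pd.Series:
        s = pd.Series(self.response_fractions(), index=self.dose_array())
        return s.groupby(level=0).size().sort_index()

    @property
    def max_dose(self) -> float:
        return float(self.doses[-1])

    def __len__(self) -> int:
        return len(self.records)

    # -- persistence ---------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target_id": r.target_id,
                    "dose": r.dose,
                    "dose_units": r.dose_units,
                    "group_role": r.group_role,
                    "survival_pct": r.survival_pct,
                }
                for r in self.records
            ],
            columns=CSV_COLUMNS,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DoseResponseDataset":
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return cls(
            [
                SurvivalRecord(
                    target_id=str(row.target_id),
                    dose=float(row.dose),
                    dose_units=str(row.dose_units),
                    group_role=str(row.group_role),
                    survival_pct=float(row.survival_pct),
                )
                for row in df.itertuples()
            ]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponseDataset":
        return cls.from_dataframe(pd.read_csv(path))


def _as_frame(measurements, group_roles: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.DataFrame(measurements).copy()
    required = {"target_id", "dose", "raw_signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    if group_roles is not None:
        df["group_role"] = df["target_id"].map(dict(group_roles))
    if "group_role" not in df.columns or df["group_role"].isna().any():
        raise ValueError("every measurement needs a group_role")
    if "dose_units" not in df.columns:
        df["dose_units"] = "uM"
    return df


def tumor_survival(
    measurements,
    group_roles: Mapping[str, str] | None = None,
    baseline: Mapping[str, float] | None = None,
) -> DoseResponseDataset:
    """Normalize tumor bioluminescence to the negative-control mean.

    survival_pct_i = 100 * signal_i / mean(negative-control signals), so
    the negative-control group has a defined mean survival of exactly 100%.

    ``baseline`` optionally maps target_id to a pre-treatment (day-1)
    signal; when given, each signal is divided by its own baseline before
    control normalization (per-tumor initial-size correction, off by
    default).
    """
    df = _as_frame(measurements, group_roles)
    if baseline is not None:
        scale = df["target_id"].map(dict(baseline)).astype(float)
        if scale.isna().any() or (scale <= 0).any():
            raise ValueError("baseline must give a positive signal for every target")
        df["raw_signal"] = df["raw_signal"].astype(float) / scale
    neg = df.loc[df["group_role"] == NEGATIVE_CONTROL, "raw_signal"].to_numpy(float)
    if neg.size == 0:
        raise ValueError("no negative-control measurements")
    neg_mean = float(np.mean(neg))
    if neg_mean == 0:
        raise ValueError("negative-control mean signal is zero")
    df["survival_pct"] = 100.0 * df["raw_signal"].astype(float) / neg_mean
    return _records_from_frame(df)


def obsc_survival(
    measurements, group_roles: Mapping[str, str] | None = None
) -> DoseResponseDataset:
    """Normalize slice death-marker fluorescence between the two controls.

    kill_i = 100 * (F_i - mean_neg) / (mean_pos - mean_neg);
    survival_pct_i = 100 - kill_i.  Affine-invariant in F.
    """
    df = _as_frame(measurements, group_roles)
    neg = df.loc[df["group_role"] == NEGATIVE_CONTROL, "raw_signal"].to_numpy(float)
    pos = df.loc[df["group_role"] == POSITIVE_CONTROL, "raw_signal"].to_numpy(float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("OBSC normalization needs both control groups")
    neg_mean, pos_mean = float(np.mean(neg)), float(np.mean(pos))
    if pos_mean == neg_mean:
        raise ValueError("zero dynamic range: positive and negative control means equal")
    kill = 100.0 * (df["raw_signal"].astype(float) - neg_mean) / (pos_mean - neg_mean)
    df["survival_pct"] = 100.0 - kill
    return _records_from_frame(df)


def _records_from_frame(df: pd.DataFrame) -> DoseResponseDataset:
    return DoseResponseDataset(
        [
            SurvivalRecord(
                target_id=str(row.target_id),
                dose=float(row.dose),
                dose_units=str(row.dose_units),
                group_role=str(row.group_role),
                survival_pct=float(row.survival_pct),
                raw_signal=float(row.raw_signal),
            )
            for row in df.itertuples()
        ]
    )


@dataclass
class AgreementSummary:
    """Bland-Altman limits of agreement between two measurement methods."""

    mean_difference: float
    loa_lower: float
    loa_upper: float
    differences: np.ndarray = field(repr=False)
    averages: np.ndarray = field(repr=False)
    agreement_threshold: float | None = None
    fraction_within_threshold: float | None = None

    @property
    def n(self) -> int:
        return int(self.differences.size)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean_difference": self.mean_difference,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "n": self.n,
            "agreement_threshold": self.agreement_threshold,
            "fraction_within_threshold": self.fraction_within_threshold,
            "differences": self.differences.tolist(),
            "averages": self.averages.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def bland_altman(
    auto: Iterable[float],
    manual: Iterable[float],
    agreement_threshold: float | None = 10.0,
) -> AgreementSummary:
    """Bland-Altman agreement: differences (auto - manual) vs their averages.

    Limits of agreement are mean +/- 1.96 * SD of the differences.  When an
    ``agreement_threshold`` (percent survival) is given, the fraction of
    pairs whose absolute difference lies within it is reported as well.
    """
    a = np.asarray(list(auto), dtype=float)
    m = np.asarray(list(manual), dtype=float)
    if a.shape != m.shape:
        raise ValueError("auto and manual must have equal length")
    if a.size < 2:
        raise ValueError("need at least two paired measurements")
    diff = a - m
    avg = (a + m) / 2.0
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    frac = None
    if agreement_threshold is not None:
        frac = float(np.mean(np.abs(diff) <= agreement_threshold))
    return AgreementSummary(
        mean_difference=mean,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        differences=diff,
        averages=avg,
        agreement_threshold=agreement_threshold,
        fraction_within_threshold=frac,
    )


def bland_altman_plot(summary: AgreementSummary, path: str | Path) -> None:
    """Write the standard Bland-Altman scatter with mean and 1.96-SD limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(summary.averages, summary.differences, s=12, alpha=0.6)
    ax.axhline(summary.mean_difference, color="black")
    for y in (summary.loa_lower, summary.loa_upper):
        ax.axhline(y, color="gray", linestyle=":")
    ax.set_xlabel("Average of methods (% survival)")
    ax.set_ylabel("Automated - manual (% survival)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
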