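"""Metadata schema, run configuration, and end-to-end orchestration.

Each row of a metadata CSV describes one *target* - a micro-tumor in a
tumor-toxicity assay or a slice in an OBSC-toxicity assay - carrying its
experimental context (treatment, dose and units, group role, experiment
id).  A documented minimal core schema is validated; unknown columns are
preserved as extension fields.  Up to nine non-control dose groups are
allowed per experiment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dss as dss_mod
from . import fitting, survival
from .fitting import HeuristicThresholds
from .survival import DoseResponseDataset, bland_altman

logger = logging.getLogger("obscpipe")

REQUIRED_METADATA_COLUMNS = [
    "experiment_id", "target_id", "treatment", "dose", "dose_units",
    "group_role", "assay_kind",
]
MAX_DOSE_GROUPS = 9  # non-control dose groups per experiment


@dataclass
class ExperimentMetadata:
    """Validated context of one experiment plus its per-target rows."""

    experiment_id: str
    treatment: str
    assay_kind: str  # tumor_toxicity | obsc_toxicity
    dose_ladder: tuple[float, ...]
    dose_units: str
    targets: pd.DataFrame = field(repr=False)
    start_date: str | None = None
    sample_id: str | None = None
    extra_columns: tuple[str, ...] = ()


def read_metadata(path: str | Path) -> list[ExperimentMetadata]:
    """Read and validate a metadata CSV; one entry per experiment_id."""
    df = pd.read_csv(path)
    missing = set(REQUIRED_METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    if df["target_id"].duplicated().any():
        dupes = df.loc[df["target_id"].duplicated(), "target_id"].tolist()
        raise ValueError(f"duplicate target ids: {dupes}")
    extra = tuple(c for c in df.columns if c not in REQUIRED_METADATA_COLUMNS)

    out = []
    for exp_id, grp in df.groupby("experiment_id", sort=False):
        doses = np.sort(grp["dose"].astype(float).unique())
        non_control = doses[doses > 0]
        if non_control.size > MAX_DOSE_GROUPS:
            raise ValueError(
                f"experiment {exp_id}: {non_control.size} non-control dose groups "
                f"(limit {MAX_DOSE_GROUPS})"
            )
        units = grp["dose_units"].unique()
        if len(units) != 1:
            raise ValueError(f"experiment {exp_id}: mixed dose units {units}")
        out.append(ExperimentMetadata(
            experiment_id=str(exp_id),
            treatment=str(grp["treatment"].iloc[0]),
            assay_kind=str(grp["assay_kind"].iloc[0]),
            dose_ladder=tuple(float(d) for d in doses),
            dose_units=str(units[0]),
            targets=grp.reset_index(drop=True),
            start_date=str(grp["start_date"].iloc[0]) if "start_date" in grp else None,
            sample_id=str(grp["sample_id"].iloc[0]) if "sample_id" in grp else None,
            extra_columns=extra,
        ))
    return out


@dataclass
class RunConfig:
    """All tunables of a pipeline run, serializable to YAML.

    Defaults are the assay's operational constants; overriding any of them
    is recorded in the run log.
    """

    grid_rows: int = 2
    grid_cols: int = 3
    thresholds: HeuristicThresholds = field(default_factory=HeuristicThresholds)
    weights: dict[str, float] = field(
        default_factory=lambda: dict(dss_mod.DEFAULT_WEIGHTS))
    seed: int = 0
    n_starts: int = 5
    normalization_mode: str = "d4_only"  # d4_only | d4_over_d1
    verbosity: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in payload and isinstance(payload["thresholds"], dict):
            payload["thresholds"] = HeuristicThresholds(**payload["thresholds"])
        return cls(**payload)


def run_experiment(
    tumor: DoseResponseDataset,
    obsc: DoseResponseDataset,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Full comparative run: model selection on both arms, then the DSS.

    Returns the result bundle as a dict; when ``out_dir`` is given the
    survival CSVs, selected-model JSONs, DSS JSON, waterfall CSV and run
    log are written there.  Deterministic given the config seed.
    """
    config = config or RunConfig()
    logger.setLevel(config.verbosity)

    stage = "fit_tumor"
    try:
        tumor_fit = fitting.select_model(tumor, config.thresholds,
                                         seed=config.seed, n_starts=config.n_starts)
        stage = "fit_obsc"
        obsc_fit = fitting.select_model(obsc, config.thresholds,
                                        seed=config.seed + 1000,
                                        n_starts=config.n_starts)
        stage = "dss"
        windows = dss_mod.compute_windows(tumor_fit, obsc_fit, tumor,
                                          alpha=config.thresholds.bp_alpha)
        result = dss_mod.compute_dss(windows, config.weights)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    logger.info("tumor: %s (category %s, CC %.3f, plausible %s)",
                tumor_fit.family, tumor_fit.category, tumor_fit.cc,
                tumor_fit.plausible)
    logger.info("obsc: %s (category %s, CC %.3f, plausible %s)",
                obsc_fit.family, obsc_fit.category, obsc_fit.cc,
                obsc_fit.plausible)
    logger.info("DSS total: %.2f", result.total)

    bundle = {
        "tumor_model": tumor_fit.to_dict(),
        "obsc_model": obsc_fit.to_dict(),
        "dss": result.to_dict(),
        "config": {"seed": config.seed, "n_starts": config.n_starts,
                   "weights": dict(config.weights)},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tumor.to_csv(out_dir / "tumor_survival.csv")
        obsc.to_csv(out_dir / "obsc_survival.csv")
        (out_dir / "tumor_model.json").write_text(
            json.dumps(tumor_fit.to_dict(), indent=2, sort_keys=True))
        (out_dir / "obsc_model.json").write_text(
            json.dumps(obsc_fit.to_dict(), indent=2, sort_keys=True))
        result.to_json(out_dir / "dss.json")
        result.waterfall().to_csv(out_dir / "waterfall.csv", index=False)
        (out_dir / "run.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle


def synthetic_image_experiment(seed: int = 0):
    """Build a paired tumor/slice experiment from rendered plate images.

    Exercises the whole measurement path: two synthetic six-well plates are
    rendered (a tumor plate whose per-well spot intensities follow a known
    log-logistic kill curve, and a slice-toxicity plate whose per-well
    death-marker fluorescence follows a known toxicity curve, with negative
    and positive control wells), segmented with the classical fallback
    segmenter, measured, and control-normalized.  Returns
    ``(tumor_dataset, obsc_dataset)`` ready for model selection and DSS
    scoring.  Deterministic given the seed.
    """
    from . import imaging, simulate  # deferred: imaging pulls in scikit-image
    from .models import evaluate
    from .survival import obsc_survival, tumor_survival

    rng = np.random.default_rng(seed)
    doses = (0.0, 5.0, 15.0, 50.0, 150.0)
    wells = [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]

    # tumor plate: two control wells + four treatment wells, four spots each
    tumor_params = {"b": 2.0, "c": 0.05, "d": 1.0, "e": 30.0}
    tumor_dose_of_well = {(0, 0): 0.0, (0, 1): 0.0, (0, 2): 5.0,
                          (1, 0): 15.0, (1, 1): 50.0, (1, 2): 150.0}
    base_intensity = 20000.0
    spots = []
    for well in wells:
        surv = float(evaluate("LL.4", tumor_params, tumor_dose_of_well[well]))
        for pos in ("top", "bottom"):
            for hemi in ("left", "right"):
                jitter = float(rng.lognormal(0.0, 0.05))
                spots.append(simulate.TumorSpot(
                    well, pos, hemi, base_intensity * surv * jitter))
    t_image, _ = simulate.generate_plate_image(simulate.PlateSpec(
        tumor_spots=tuple(spots), noise_sd=0.5, seed=seed))

    # slice-toxicity plate: negative + positive control wells, four doses
    obsc_params = {"b": 1.5, "c": 0.55, "d": 1.0, "e": 120.0}
    neg_f, pos_f = 40.0, 240.0
    obsc_dose_of_well = {(0, 0): 0.0, (0, 1): 5.0, (0, 2): 15.0,
                         (1, 0): 50.0, (1, 1): 150.0}
    pi_levels = {}
    for well, dose in obsc_dose_of_well.items():
        kill = 1.0 - float(evaluate("LL.4", obsc_params, dose))
        pi_levels[well] = neg_f + kill * (pos_f - neg_f)
    pi_levels[(1, 2)] = pos_f  # fully killed positive-control well
    o_image, _ = simulate.generate_plate_image(simulate.PlateSpec(
        pi_mean=pi_levels, noise_sd=2.0, seed=seed + 1))

    grid = (2, 3)

    def measured_frame(image, mode):
        masks = imaging.segment_slices_fallback(image.brightfield)
        masks = imaging.assign_wells(masks, grid, image.shape)
        return imaging.measure_plate(image, masks, mode=mode)

    t_df = measured_frame(t_image, "tumor")
    t_df["dose"] = [tumor_dose_of_well[(r, c)]
                    for r, c in zip(t_df.well_row, t_df.well_col)]
    t_df["group_role"] = np.where(t_df["dose"] == 0, "negative_control",
                                  "treated")
    t_df = t_df.rename(columns={"value": "raw_signal"})
    tumor_ds = tumor_survival(t_df)

    o_df = measured_frame(o_image, "pi")
    roles, o_doses = [], []
    for r, c in zip(o_df.well_row, o_df.well_col):
        if (r, c) == (1, 2):
            roles.append("positive_control")
            o_doses.append(0.0)
        else:
            dose = obsc_dose_of_well[(r, c)]
            roles.append("negative_control" if dose == 0 else "treated")
            o_doses.append(dose)
    o_df["dose"] = o_doses
    o_df["group_role"] = roles
    o_df = o_df.rename(columns={"value": "raw_signal"})
    obsc_ds = obsc_survival(o_df)
    return tumor_ds, obsc_ds


def validate_against_manual(
    auto_csv: str | Path,
    manual_csv: str | Path,
    threshold: float = 10.0,
):
    """Bland-Altman agreement between automated and manual survival CSVs.

    Both files use the survival-record schema and must contain the same
    target ids.  Returns (AgreementSummary, per-target report DataFrame);
    targets differing by more than ``threshold`` percent survival are
    flagged for review.
    """
    auto = pd.read_csv(auto_csv).set_index("target_id")
    manual = pd.read_csv(manual_csv).set_index("target_id")
    if set(auto.index) != set(manual.index):
        raise ValueError("auto and manual files must cover the same target ids")
    manual = manual.loc[auto.index]
    summary = bland_altman(auto["survival_pct"], manual["survival_pct"],
                           agreement_threshold=threshold)
    report = pd.DataFrame({
        "target_id": auto.index,
        "auto_pct": auto["survival_pct"].to_numpy(),
        "manual_pct": manual["survival_pct"].to_numpy(),
        "difference": summary.differences,
        "average": summary.averages,
        "exceeds_threshold": np.abs(summary.differences) > threshold,
    }).reset_index(drop=True)
    return summary, report
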