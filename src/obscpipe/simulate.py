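"""Seeded synthetic plates and dose-response data with exact ground truth.

The plate generator emulates the assay's imaging geometry: a six-well
plate (2 x 3 grid) imaged as one frame, two elliptical brain slices per
well (top and bottom), each hosting up to two Gaussian micro-tumor
signal spots (one per hemisphere, spanning up to a 100-fold intensity
range) and/or a diffuse death-marker fluorescence level.  Optional
reflection artifacts - thin bright arcs along the well walls - exercise
the robustness of the fallback segmenter.

Ground truth records, for every slice and hemisphere, the quantities the
imaging code is supposed to recover: label masks, integrated noiseless
spot signal per hemisphere, and mean noiseless fluorescence per slice.
Every signal is reproducible by summing the noiseless channel under its
ground-truth mask.

The curve generator draws replicate percent-survival values from any
registry model family plus Gaussian noise, for testing the fitting and
scoring stages.  A single integer seed (numpy default_rng, PCG64) drives
all randomness; identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import models
from .survival import (NEGATIVE_CONTROL, TREATED, DoseResponseDataset,
                       SurvivalRecord)

PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class TumorSpot:
    """One synthetic micro-tumor signal spot."""

    well: tuple[int, int]
    position: str  # top | bottom
    hemisphere: str  # left | right
    integrated_intensity: float
    spot_sigma: float = 4.0

    def __post_init__(self):
        if self.position not in ("top", "bottom"):
            raise ValueError("position must be top or bottom")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be left or right")
        if self.integrated_intensity < 0 or self.spot_sigma <= 0:
            raise ValueError("spot intensity must be >= 0 and sigma > 0")


@dataclass
class PlateSpec:
    """Geometry and signal content of one synthetic plate image."""

    n_rows: int = 2
    n_cols: int = 3
    image_size: tuple[int, int] = (400, 600)
    slices_per_well: int = 2
    slice_axes: tuple[float, float] = (55.0, 28.0)  # major, minor semi-axes (px)
    slice_angle: float = 12.0  # max |rotation| of the major axis, degrees
    background_level: float = 10.0
    slice_level: float = 70.0  # brightfield brightness added inside slices
    reflection_artifacts: bool = False
    tumor_spots: tuple[TumorSpot, ...] = ()
    #: diffuse death-marker fluorescence inside slices; a scalar applies
    #: plate-wide, a {(well_row, well_col): level} map varies it per well
    pi_mean: float | dict = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.slices_per_well not in (1, 2):
            raise ValueError("1 or 2 slices per well")
        a, b = self.slice_axes
        if a <= 0 or b <= 0 or b > a:
            raise ValueError("slice_axes must be (major, minor) with major >= minor > 0")
        pi_values = (self.pi_mean.values() if isinstance(self.pi_mean, dict)
                     else [self.pi_mean])
        if self.background_level < 0 or self.noise_sd < 0 or any(
                v < 0 for v in pi_values):
            raise ValueError("intensities must be non-negative")
        self.tumor_spots = tuple(
            s if isinstance(s, TumorSpot) else TumorSpot(*s) for s in self.tumor_spots
        )
        for s in self.tumor_spots:
            r, c = s.well
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"spot well {s.well} outside the grid")


@dataclass
class SliceInfo:
    label: int
    well: tuple[int, int]
    position: str
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]
    angle_deg: float


@dataclass
class GroundTruth:
    """Everything the measurement stages should recover from a plate."""

    label_image: np.ndarray
    slices: dict[int, SliceInfo]
    hemisphere_signal: dict[tuple[int, str], float]
    slice_pi_mean: dict[int, float]

    def label_for(self, well: tuple[int, int], position: str) -> int:
        for info in self.slices.values():
            if info.well == tuple(well) and info.position == position:
                return info.label
        raise KeyError(f"no slice at well {well} position {position}")

    def slice_mask(self, label: int) -> np.ndarray:
        return self.label_image == label

    def hemisphere_mask(self, label: int, side: str) -> np.ndarray:
        """Analytic hemisphere: the slice mask split at its major-axis midline."""
        info = self.slices[label]
        mask = self.slice_mask(label)
        theta = math.radians(info.angle_deg)
        ax = np.array([math.cos(theta), math.sin(theta)])  # (x=col, y=row)
        if ax[0] < 0 or (ax[0] == 0 and ax[1] < 0):
            ax = -ax
        rows, cols = np.nonzero(mask)
        proj = (cols - info.center[1]) * ax[0] + (rows - info.center[0]) * ax[1]
        keep = proj < 0 if side == "left" else proj >= 0
        out = np.zeros_like(mask)
        out[rows[keep], cols[keep]] = True
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slices": [
                {
                    "label": info.label,
                    "well": list(info.well),
                    "position": info.position,
                    "center": list(info.center),
                    "axes": list(info.axes),
                    "angle_deg": info.angle_deg,
                }
                for info in self.slices.values()
            ],
            "hemisphere_signal": {
                f"{lbl}:{side}": v for (lbl, side), v in self.hemisphere_signal.items()
            },
            "slice_pi_mean": {str(k): v for k, v in self.slice_pi_mean.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _ellipse_mask(shape, center, axes, angle_deg) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    theta = math.radians(angle_deg)
    dx = cc - center[1]
    dy = rr - center[0]
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _bbox_half_extents(axes, angle_deg) -> tuple[float, float]:
    """Half height/width of the axis-aligned bounding box of the ellipse."""
    a, b = axes
    t = math.radians(angle_deg)
    half_w = math.hypot(a * math.cos(t), b * math.sin(t))
    half_h = math.hypot(a * math.sin(t), b * math.cos(t))
    return half_h, half_w


def generate_plate_image(spec: PlateSpec):
    """Render one synthetic plate; returns (PlateImage, GroundTruth).

    Slice placement is rejection-sampled inside each slice's sub-cell of
    its well (with a wall margin) and retried up to 100 times if the
    rotated ellipse cannot fit; a spec that cannot be placed is rejected
    rather than silently overlapped.
    """
    from .imaging import PlateImage  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    cell_h, cell_w = H / spec.n_rows, W / spec.n_cols
    sub_h = cell_h / spec.slices_per_well

    label_image = np.zeros((H, W), dtype=np.int32)
    slices: dict[int, SliceInfo] = {}
    label = 0
    positions = ("top", "bottom")[: spec.slices_per_well]
    margin = 4.0
    for wr in range(spec.n_rows):
        for wc in range(spec.n_cols):
            for pi_, pos in enumerate(positions):
                label += 1
                placed = False
                for _ in range(PLACEMENT_RETRIES):
                    angle = float(rng.uniform(-spec.slice_angle, spec.slice_angle))
                    half_h, half_w = _bbox_half_extents(spec.slice_axes, angle)
                    r_lo = wr * cell_h + pi_ * sub_h + half_h + margin
                    r_hi = wr * cell_h + (pi_ + 1) * sub_h - half_h - margin
                    c_lo = wc * cell_w + half_w + margin
                    c_hi = (wc + 1) * cell_w - half_w - margin
                    if r_lo >= r_hi or c_lo >= c_hi:
                        continue
                    center = (float(rng.uniform(r_lo, r_hi)),
                              float(rng.uniform(c_lo, c_hi)))
                    mask = _ellipse_mask((H, W), center, spec.slice_axes, angle)
                    if (label_image[mask] != 0).any():
                        continue
                    label_image[mask] = label
                    slices[label] = SliceInfo(label=label, well=(wr, wc),
                                              position=pos, center=center,
                                              axes=spec.slice_axes, angle_deg=angle)
                    placed = True
                    break
                if not placed:
                    raise ValueError(
                        f"could not place slice {pos} in well ({wr},{wc}) after "
                        f"{PLACEMENT_RETRIES} attempts; slices do not fit the well"
                    )

    gt = GroundTruth(label_image=label_image, slices=slices,
                     hemisphere_signal={}, slice_pi_mean={})

    brightfield = np.full((H, W), spec.background_level, dtype=float)
    brightfield[label_image > 0] += spec.slice_level

    if spec.reflection_artifacts:
        rr, cc = np.mgrid[0:H, 0:W]
        for wr in range(spec.n_rows):
            for wc in range(spec.n_cols):
                cy, cx = (wr + 0.5) * cell_h, (wc + 0.5) * cell_w
                radius = 0.48 * min(cell_h, cell_w)
                d = np.hypot(rr - cy, cc - cx)
                ang = np.arctan2(rr - cy, cc - cx)
                arc = (np.abs(d - radius) < 1.5) & (np.abs(ang - rng.uniform(-math.pi, math.pi)) < 0.9)
                brightfield[arc] = spec.background_level + 2.0 * spec.slice_level

    signal = np.zeros((H, W), dtype=float)
    for spot in spec.tumor_spots:
        lbl = gt.label_for(spot.well, spot.position)
        info = slices[lbl]
        theta = math.radians(info.angle_deg)
        ax = np.array([math.cos(theta), math.sin(theta)])  # (x, y)
        if ax[0] < 0 or (ax[0] == 0 and ax[1] < 0):
            ax = -ax
        sign = -1.0 if spot.hemisphere == "left" else 1.0
        offset = sign * (spec.slice_axes[0] / 2.0)
        cy = info.center[0] + offset * ax[1]
        cx = info.center[1] + offset * ax[0]
        sigma = min(spot.spot_sigma, spec.slice_axes[1] / 3.0)
        win = int(math.ceil(5 * sigma))
        r0, r1 = max(int(cy) - win, 0), min(int(cy) + win + 1, H)
        c0, c1 = max(int(cx) - win, 0), min(int(cx) + win + 1, W)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        g /= g.sum()
        signal[r0:r1, c0:c1] += spot.integrated_intensity * g

    for lbl, info in slices.items():
        level = (spec.pi_mean.get(info.well, 0.0)
                 if isinstance(spec.pi_mean, dict) else spec.pi_mean)
        if level > 0:
            signal[label_image == lbl] += level

    # ground truth from the noiseless channel, as recoverable by summation
    for lbl in slices:
        for side in ("left", "right"):
            hemi = gt.hemisphere_mask(lbl, side)
            gt.hemisphere_signal[(lbl, side)] = float(signal[hemi].sum())
        gt.slice_pi_mean[lbl] = float(signal[gt.slice_mask(lbl)].mean())

    if spec.noise_sd > 0:
        brightfield = brightfield + rng.normal(0.0, spec.noise_sd, (H, W))
        signal = signal + rng.normal(0.0, spec.noise_sd, (H, W))
    brightfield = np.clip(brightfield, 0.0, None)
    signal = np.clip(signal, 0.0, None)

    has_pi = (any(v > 0 for v in spec.pi_mean.values())
              if isinstance(spec.pi_mean, dict) else spec.pi_mean > 0)
    channel = "PI" if has_pi and not spec.tumor_spots else "BLI"
    return PlateImage(brightfield=brightfield, signal=signal,
                      channel_kind=channel), gt


def write_plate(image, gt: GroundTruth, out_dir: str | Path,
                stem: str = "plate") -> dict[str, Path]:
    """Write the channels and label image as 16-bit TIFFs plus a JSON truth file."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("brightfield", image.brightfield), ("signal", image.signal)):
        p = out_dir / f"{stem}_{name}.tif"
        tifffile.imwrite(p, np.clip(np.round(arr), 0, 65535).astype(np.uint16))
        paths[name] = p
    p = out_dir / f"{stem}_labels.tif"
    tifffile.imwrite(p, gt.label_image.astype(np.uint16))
    paths["labels"] = p
    p = out_dir / f"{stem}_truth.json"
    gt.to_json(p)
    paths["truth"] = p
    return paths


# --------------------------------------------------------------------------
# dose-response simulation


@dataclass
class SimCurveSpec:
    """A registry model family sampled with replicate Gaussian noise."""

    family: str
    params: dict[str, float]
    doses: Sequence[float]
    n_reps: int = 4
    noise_sd: float = 0.02  # survival-fraction scale
    seed: int = 0
    dose_units: str = "uM"

    def __post_init__(self):
        if self.family not in models.REGISTRY:
            raise KeyError(f"unknown model family {self.family!r}")
        d = np.asarray(self.doses, dtype=float)
        if d.size < 2 or d[0] != 0 or np.any(np.diff(d) <= 0) or np.any(d < 0):
            raise ValueError("doses must be non-negative, strictly increasing, "
                             "and start at 0 (control)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.doses = tuple(float(x) for x in d)
        self._validate_params()

    def _validate_params(self) -> None:
        spec = models.REGISTRY[self.family]
        p = dict(self.params)
        for name, fixed in spec.fixed_params.items():
            given = p.setdefault(name, fixed)
            if not math.isclose(given, fixed, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"{self.family}: parameter {name} is fixed at {fixed}")
        for name in spec.free_params:
            if name == "M":
                continue
            if name not in p:
                raise ValueError(f"{self.family}: missing parameter {name}")
            lo, hi = spec.lower[name], spec.upper[name]
            if not lo - 1e-9 <= p[name] <= hi + 1e-9:
                raise ValueError(
                    f"{self.family}: parameter {name}={p[name]} outside [{lo}, {hi}]"
                )
        if self.family == "RBC.5" and "M" not in p:
            raise ValueError("RBC.5 simulation needs the peak dose M")
        self.params = p

    def curve(self, dose) -> np.ndarray | float:
        return models.evaluate(self.family, self.params, dose)


def generate_dose_response(spec: SimCurveSpec) -> DoseResponseDataset:
    """Replicate survival values: family curve at each dose + N(0, noise_sd)."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i, dose in enumerate(spec.doses):
        truth = float(spec.curve(dose))
        noise = rng.normal(0.0, spec.noise_sd, spec.n_reps) if spec.noise_sd > 0 \
            else np.zeros(spec.n_reps)
        role = NEGATIVE_CONTROL if dose == 0 else TREATED
        for j, eps in enumerate(noise):
            records.append(SurvivalRecord(
                target_id=f"d{i}r{j}", dose=dose, group_role=role,
                survival_pct=100.0 * (truth + float(eps)),
                dose_units=spec.dose_units,
            ))
    return DoseResponseDataset(records)


def generate_paired_experiment(
    tumor_spec: SimCurveSpec, obsc_spec: SimCurveSpec
) -> tuple[DoseResponseDataset, DoseResponseDataset]:
    """Paired tumor / slice datasets sharing one dose ladder (for DSS runs)."""
    if tuple(tumor_spec.doses) != tuple(obsc_spec.doses):
        raise ValueError("tumor and OBSC specs must share the same dose ladder")
    return generate_dose_response(tumor_spec), generate_dose_response(obsc_spec)
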