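"""Signal measurement from multimodal plate images.

A plate image pairs a grayscale brightfield channel, showing the brain
slices, with a signal channel carrying the biologically relevant marker
(bioluminescence from surviving tumor cells, mCherry from a single
pre-treatment micro-tumor, or propidium-iodide fluorescence marking dead
slice cells).  Slice masks come either from an external segmenter (label
image, ingested verbatim) or from a classical fallback pipeline.

The measurement geometry follows the assay design: masks are sorted into
wells by a fixed grid, each slice is bisected across the long axis of its
minimum-area rotated bounding box into two hemispheres (one engrafted
micro-tumor per hemisphere), and tumor signal is isolated per hemisphere
by triangle thresholding, which is well suited to dim signals against a
large dark background.  Slice death is the mean fluorescence under the
whole-slice mask.

Conventions: row-major 0-based pixel coordinates, origin top-left; masks
are half-open pixel sets (each parent pixel lands in exactly one
hemisphere).  Degenerate inputs (blank images, constant histograms) yield
flagged zero measurements rather than exceptions so a whole-plate run
never aborts on one empty hemisphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

MEASUREMENT_COLUMNS = ["target_id", "well_row", "well_col", "position",
                       "hemisphere", "statistic_kind", "value", "threshold_used"]


@dataclass
class PlateImage:
    """Brightfield + signal channel pair of one plate."""

    brightfield: np.ndarray
    signal: np.ndarray
    channel_kind: str = "BLI"  # BLI | mCherry | PI

    def __post_init__(self):
        self.brightfield = np.asarray(self.brightfield, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.brightfield.shape != self.signal.shape:
            raise ValueError("brightfield and signal channels must share shape")
        if np.any(self.brightfield < 0) or np.any(self.signal < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape


@dataclass
class MaskSet:
    """Labeled slice regions with optional well/position assignment."""

    label_image: np.ndarray
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)
    wells: dict[int, tuple[int, int]] = field(default_factory=dict)
    positions: dict[int, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[int]:
        return sorted(self.centroids)

    def mask(self, label: int) -> np.ndarray:
        return self.label_image == label

    def __len__(self) -> int:
        return len(self.centroids)

    def iter_measurement_order(self) -> Iterator[int]:
        """Labels ordered by well (row-major), top slice before bottom."""
        pos_rank = {"top": 0, "bottom": 1}
        assigned = [l for l in self.labels if l in self.wells]
        yield from sorted(
            assigned,
            key=lambda l: (self.wells[l], pos_rank.get(self.positions.get(l, ""), 2),
                           self.centroids[l]),
        )


@dataclass
class HemispherePair:
    """Two disjoint halves of one slice mask split across its long axis."""

    parent_label: int
    left: np.ndarray
    right: np.ndarray
    line_start: tuple[float, float]  # (row, col)
    line_end: tuple[float, float]

    def __iter__(self):
        yield "left", self.left
        yield "right", self.right


@dataclass
class SignalMeasurement:
    target_id: str
    statistic_kind: str  # integrated_above_threshold | mean
    value: float
    threshold_used: float | None = None
    well: tuple[int, int] | None = None
    position: str | None = None
    hemisphere: str | None = None
    degenerate: bool = False


@dataclass
class ThresholdResult:
    value: float
    degenerate: bool = False
    bin_index: int | None = None

    def __float__(self) -> float:
        return float(self.value)


# --------------------------------------------------------------------------
# triangle thresholding


def triangle_threshold(pixel_values, n_bins: int = 256) -> ThresholdResult:
    """Zack triangle threshold of a 1-D intensity sample.

    A histogram of ``n_bins`` equal bins spans [min, max] of the sample.  A
    line is drawn from the histogram peak to the farthest nonzero tail bin
    (the side with the longer tail); the threshold bin maximizes the
    perpendicular distance from the histogram profile to that line, offset
    by one bin toward the signal tail.  The returned value is that bin's
    center.  Constant samples return the constant with ``degenerate=True``.
    """
    v = np.asarray(pixel_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty pixel sample")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        return ThresholdResult(value=vmin, degenerate=True)

    counts, edges = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = int(np.argmax(counts))
    nonzero = np.nonzero(counts)[0]
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    # longer tail side; ties go to the high side (bright signal convention)
    tail = hi if (hi - peak) >= (peak - lo) else lo
    if tail == peak:
        return ThresholdResult(value=centers[peak], degenerate=True)

    lo_i, hi_i = (peak, tail) if peak < tail else (tail, peak)
    idx = np.arange(lo_i, hi_i + 1)
    # perpendicular distance of each (bin, count) point to the peak->tail line
    px, py = float(peak), float(counts[peak])
    tx, ty = float(tail), float(counts[tail])
    dist = np.abs((tx - px) * (py - counts[idx]) - (px - idx) * (ty - py))
    best = idx[int(np.argmax(dist))]
    step = 1 if tail > peak else -1
    chosen = int(np.clip(best + step, 0, n_bins - 1))
    return ThresholdResult(value=float(centers[chosen]), bin_index=chosen)


# --------------------------------------------------------------------------
# mask geometry


def _long_axis(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center, long-axis unit vector (in (row, col)), and minor extent of the
    minimum-area rotated bounding rectangle of a binary mask."""
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)  # shapely works in (x, y)
    hull = shapely.MultiPoint(pts).convex_hull
    rect = hull.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        # degenerate (collinear) mask: principal axis via PCA
        center = pts.mean(axis=0)
        d = pts - center
        u, _, vt = np.linalg.svd(d, full_matrices=False)
        ax = vt[0]
        minor = 1.0
    else:
        corners = np.asarray(rect.exterior.coords)[:4]
        e1 = corners[1] - corners[0]
        e2 = corners[2] - corners[1]
        l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
        center = corners[:4].mean(axis=0)
        if abs(l1 - l2) <= 1e-6 * max(l1, l2):
            # square box (circle-like mask): tie-break to a vertical split,
            # i.e. the long axis runs along the columns
            ax = np.array([1.0, 0.0])
            minor = l1
        elif l1 >= l2:
            ax, minor = e1 / l1, l2
        else:
            ax, minor = e2 / l2, l1
    # orient deterministically: positive x (col) component, then positive y
    if ax[0] < 0 or (ax[0] == 0 and ax[1] < 0):
        ax = -ax
    return center, ax, float(minor)


def bisect_mask(mask: np.ndarray, parent_label: int = 1,
                axis: str = "across") -> HemispherePair:
    """Split a slice mask into two hemispheres at its rotated bounding box.

    With ``axis='across'`` (default) the dividing line passes through the
    center of the mask's minimum-area rotated bounding rectangle,
    perpendicular to the rectangle's long axis (the anatomical midline);
    ``axis='along'`` divides along the long axis instead.  The halves are
    disjoint and cover the parent exactly; pixels on the line fall in the
    'right' half.  A circle (square box) is split by a vertical line for
    determinism.
    """
    if axis not in ("across", "along"):
        raise ValueError("axis must be 'across' or 'along'")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    center, ax, minor = _long_axis(mask)
    if axis == "along":
        ax = np.array([-ax[1], ax[0]])
        if ax[0] < 0 or (ax[0] == 0 and ax[1] < 0):
            ax = -ax

    rows, cols = np.nonzero(mask)
    proj = (cols - center[0]) * ax[0] + (rows - center[1]) * ax[1]
    left = np.zeros_like(mask)
    right = np.zeros_like(mask)
    neg = proj < 0
    left[rows[neg], cols[neg]] = True
    right[rows[~neg], cols[~neg]] = True

    perp = np.array([-ax[1], ax[0]])
    half = minor / 2.0 + 1.0
    p0 = center - perp * half
    p1 = center + perp * half
    return HemispherePair(
        parent_label=parent_label,
        left=left,
        right=right,
        line_start=(float(p0[1]), float(p0[0])),
        line_end=(float(p1[1]), float(p1[0])),
    )


def ingest_masks(label_image: np.ndarray,
                 image_shape: tuple[int, int] | None = None) -> MaskSet:
    """Wrap an externally produced label image (labels kept verbatim)."""
    label_image = np.asarray(label_image)
    if not np.issubdtype(label_image.dtype, np.integer):
        if not np.all(label_image == np.round(label_image)):
            raise ValueError("label image must contain integer labels")
        label_image = label_image.astype(np.int32)
    if image_shape is not None and tuple(label_image.shape) != tuple(image_shape):
        raise ValueError(
            f"label image shape {label_image.shape} does not match plate "
            f"image shape {tuple(image_shape)}"
        )
    centroids = {}
    for region in measure.regionprops(label_image):
        centroids[int(region.label)] = tuple(map(float, region.centroid))
    return MaskSet(label_image=label_image, centroids=centroids)


def assign_wells(masks: MaskSet, grid: tuple[int, int],
                 image_shape: tuple[int, int] | None = None) -> MaskSet:
    """Assign each slice to the grid cell containing its centroid.

    Cell boundaries sit at equal fractions of the image extent.  A
    centroid exactly on a boundary goes to the lower cell index.  Within
    each well the slice with the smaller centroid row is 'top' (measured
    first), the other 'bottom'; extra slices are flagged.
    """
    n_rows, n_cols = grid
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must be at least 1x1")
    shape = image_shape or masks.label_image.shape
    cell_h = shape[0] / n_rows
    cell_w = shape[1] / n_cols

    def cell_index(coord: float, cell: float, n: int) -> int:
        idx = int(coord // cell)
        if idx > 0 and coord == idx * cell:  # boundary tie-break: lower cell
            idx -= 1
        return min(idx, n - 1)

    wells: dict[int, tuple[int, int]] = {}
    for lbl, (r, c) in masks.centroids.items():
        wells[lbl] = (cell_index(r, cell_h, n_rows), cell_index(c, cell_w, n_cols))

    positions: dict[int, str] = {}
    warn: list[str] = list(masks.warnings)
    by_well: dict[tuple[int, int], list[int]] = {}
    for lbl, well in wells.items():
        by_well.setdefault(well, []).append(lbl)
    for well, labels in by_well.items():
        labels.sort(key=lambda l: masks.centroids[l][0])
        if len(labels) >= 1:
            positions[labels[0]] = "top"
        if len(labels) >= 2:
            positions[labels[1]] = "bottom"
        if len(labels) > 2:
            warn.append(f"well {well} holds {len(labels)} slices; extras unpositioned")

    return MaskSet(label_image=masks.label_image, centroids=dict(masks.centroids),
                   wells=wells, positions=positions, warnings=warn)


# --------------------------------------------------------------------------
# fallback segmentation


def segment_slices_fallback(
    brightfield: np.ndarray,
    min_area: int = 400,
    smoothing_sigma: float = 2.0,
    opening_radius: int = 3,
    peak_min_distance: int = 50,
) -> MaskSet:
    """Classical slice segmentation when no external mask source exists.

    Gaussian smoothing, Otsu thresholding, morphological opening (removes
    thin reflection arcs off the well walls), hole filling and size
    filtering, connected components; a component whose distance transform
    carries two or more well-separated peaks (at least
    ``peak_min_distance`` px apart, roughly two slice minor axes) is split
    by watershed to separate touching slices.  Blank images yield an empty
    MaskSet with a warning.
    """
    img = np.asarray(brightfield, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.max() == img.min():
        return MaskSet(label_image=np.zeros(img.shape, dtype=np.int32),
                       warnings=["blank image: no slices found"])

    smoothed = filters.gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    thresh = filters.threshold_otsu(smoothed)
    mask = smoothed > thresh
    mask = morphology.opening(mask, morphology.disk(opening_radius))
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        return MaskSet(label_image=np.zeros(img.shape, dtype=np.int32),
                       warnings=["no region above minimum area"])

    comp = measure.label(mask)
    out = np.zeros(img.shape, dtype=np.int32)
    next_label = 1
    regions = []
    for region in measure.regionprops(comp):
        blob = comp == region.label
        dist = ndimage.distance_transform_edt(blob)
        peaks = peak_local_max(dist, min_distance=peak_min_distance,
                               labels=blob, exclude_border=False)
        if len(peaks) >= 2:
            markers = np.zeros(img.shape, dtype=np.int32)
            for i, (r, c) in enumerate(peaks, start=1):
                markers[r, c] = i
            split = segmentation.watershed(-dist, markers, mask=blob)
            for sub in measure.regionprops(split):
                if sub.area >= min_area:
                    regions.append((sub.centroid, split == sub.label))
        else:
            regions.append((region.centroid, blob))

    # deterministic labeling order: row-major by centroid
    regions.sort(key=lambda rc: rc[0])
    for _, blob in regions:
        out[blob] = next_label
        next_label += 1
    return ingest_masks(out)


# --------------------------------------------------------------------------
# measurements


def measure_tumor_signal(image: PlateImage, hemi_mask: np.ndarray,
                         target_id: str = "", **ids) -> SignalMeasurement:
    """Integrated tumor signal in one hemisphere.

    The triangle threshold is computed from the signal pixels inside the
    hemisphere only; the value is the sum of pixels strictly above it.  A
    signal-free hemisphere measures the background noise with no special
    casing (constant hemispheres yield a flagged 0).
    """
    hemi_mask = np.asarray(hemi_mask, dtype=bool)
    if not hemi_mask.any():
        raise ValueError("empty hemisphere mask")
    pixels = image.signal[hemi_mask]
    thr = triangle_threshold(pixels)
    value = float(pixels[pixels > thr.value].sum())
    return SignalMeasurement(target_id=target_id,
                             statistic_kind="integrated_above_threshold",
                             value=value, threshold_used=thr.value,
                             degenerate=thr.degenerate, **ids)


def measure_pi(image: PlateImage, slice_mask: np.ndarray,
               target_id: str = "", **ids) -> SignalMeasurement:
    """Mean death-marker fluorescence under the whole-slice mask."""
    slice_mask = np.asarray(slice_mask, dtype=bool)
    if not slice_mask.any():
        raise ValueError("empty slice mask")
    return SignalMeasurement(target_id=target_id, statistic_kind="mean",
                             value=float(image.signal[slice_mask].mean()),
                             threshold_used=None, **ids)


def measure_d1t(image: PlateImage, target_id: str = "") -> SignalMeasurement:
    """Integrated pre-treatment micro-tumor signal over a whole image.

    These single-tumor images show one mCherry spot against a dark
    background; the triangle threshold over the full image isolates it.
    """
    thr = triangle_threshold(image.signal.ravel())
    if thr.degenerate:
        return SignalMeasurement(target_id=target_id,
                                 statistic_kind="integrated_above_threshold",
                                 value=0.0, threshold_used=thr.value,
                                 degenerate=True)
    value = float(image.signal[image.signal > thr.value].sum())
    return SignalMeasurement(target_id=target_id,
                             statistic_kind="integrated_above_threshold",
                             value=value, threshold_used=thr.value)


def measure_plate(image: PlateImage, masks: MaskSet,
                  mode: str = "tumor") -> pd.DataFrame:
    """Measure every assigned slice of a plate in well order.

    ``mode='tumor'``: each slice is bisected and both hemispheres measured
    by thresholded integration (two micro-tumors per slice).
    ``mode='pi'``: whole-slice mean fluorescence (death marker).
    """
    if mode not in ("tumor", "pi"):
        raise ValueError("mode must be 'tumor' or 'pi'")
    rows = []
    for lbl in masks.iter_measurement_order():
        well = masks.wells.get(lbl)
        position = masks.positions.get(lbl)
        if mode == "pi":
            m = measure_pi(image, masks.mask(lbl), target_id=f"slice{lbl}")
            rows.append({"target_id": m.target_id, "well_row": well[0],
                         "well_col": well[1], "position": position,
                         "hemisphere": None, "statistic_kind": m.statistic_kind,
                         "value": m.value, "threshold_used": m.threshold_used})
        else:
            pair = bisect_mask(masks.mask(lbl), parent_label=lbl)
            for hemi_name, hemi in pair:
                m = measure_tumor_signal(image, hemi,
                                         target_id=f"slice{lbl}_{hemi_name}")
                rows.append({"target_id": m.target_id, "well_row": well[0],
                             "well_col": well[1], "position": position,
                             "hemisphere": hemi_name,
                             "statistic_kind": m.statistic_kind,
                             "value": m.value, "threshold_used": m.threshold_used})
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
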