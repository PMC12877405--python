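"""Two-channel focal-adhesion detection, colocalization, and measurement.

A focal adhesion (FA) is defined operationally as the union of a paxillin
(Pxn) spot and a vinculin (Vcl) spot that overlap by at least five pixels.
The chain is: (1) the cell-covered area is segmented from the paxillin
channel (CLAHE, median, Gaussian, then a threshold placed 0.2 FWHM to the
right of the background histogram peak); (2) spots are detected per channel
inside that mask by a local z-score (35 x 35 window, z > 1) after Gaussian
smoothing and CLAHE, keeping components whose area exceeds 100 pixels;
(3) spots without a >= 5 px overlap with a single partner spot in the other
channel are discarded; (4) connected unions of the surviving spots become FA
records carrying per-channel areas, union area (0.183 µm/pixel), and the
fitted-ellipse orientation folded to [0°, 90°] against the stretch axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import savgol_filter
from skimage import exposure, morphology

from stretchquant.orientation import AngularDistribution, cumulative_distribution, fold_to_stretch
from stretchquant.regions import LabeledRegions, filter_area, label_mask, measure_labels

log = logging.getLogger(__name__)

#: Histogram size for the background-peak threshold (bit-depth independent).
_HIST_BINS = 256
#: Savitzky-Golay smoothing of the histogram: window in bins, cubic.
_SAVGOL_WINDOW = 21
_SAVGOL_ORDER = 3


def _clahe(image: np.ndarray, clip_limit: float = 0.02) -> np.ndarray:
    """CLAHE with 2% clip and 1/8-of-image tiles, on a [0, 1] rescaled copy."""
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image, dtype=np.float64)
    scaled = (image - lo) / (hi - lo)
    kernel = (max(image.shape[0] // 8, 1), max(image.shape[1] // 8, 1))
    return exposure.equalize_adapthist(scaled, kernel_size=kernel, clip_limit=clip_limit)


def background_peak_threshold(image: np.ndarray) -> float:
    """Intensity threshold 0.2 FWHM to the right of the background peak.

    The gray-value histogram (256 bins over the image's range) is smoothed
    with a Savitzky-Golay filter (21-bin window, cubic); the first local
    maximum is taken as the background peak, its full width at half maximum is
    measured by linear interpolation of the half-max crossings, and the
    threshold is ``peak + 0.2 * FWHM``. If one flank never reaches half
    maximum, twice the measurable half-width substitutes for the FWHM (logged).
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        raise ValueError("degenerate histogram: image has a single gray level")
    counts, edges = np.histogram(image, bins=_HIST_BINS, range=(lo, hi))
    window = min(_SAVGOL_WINDOW, _HIST_BINS - 1 - (_HIST_BINS % 2 == 0))
    smooth = savgol_filter(counts.astype(float), window, _SAVGOL_ORDER)
    smooth = np.clip(smooth, 0.0, None)
    floor = 0.05 * smooth.max()

    peak = None
    for i in range(_HIST_BINS):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < _HIST_BINS - 1 else -np.inf
        if smooth[i] >= left and smooth[i] > right and smooth[i] >= floor:
            peak = i
            break
    if peak is None:
        raise ValueError("no local maximum found in the smoothed histogram")

    bin_w = (hi - lo) / _HIST_BINS
    centers = lo + (np.arange(_HIST_BINS) + 0.5) * bin_w
    # parabolic refinement of the peak position
    pos = centers[peak]
    if 0 < peak < _HIST_BINS - 1:
        y0, y1, y2 = smooth[peak - 1 : peak + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            pos += 0.5 * (y0 - y2) / denom * bin_w

    half = smooth[peak] / 2.0

    def _crossing(direction: int) -> float | None:
        j = peak
        while 0 <= j + direction < _HIST_BINS:
            j += direction
            if smooth[j] <= half:
                f = (smooth[j - direction] - half) / (smooth[j - direction] - smooth[j])
                return centers[j - direction] + direction * f * bin_w
            if smooth[j] > smooth[peak]:  # climbed into the next peak
                return None
        return None

    left_x = _crossing(-1)
    right_x = _crossing(+1)
    if right_x is not None and left_x is not None:
        fwhm = right_x - left_x
    elif right_x is not None:
        fwhm = 2.0 * (right_x - pos)
        log.warning("left half-max flank unreachable; using 2x right half-width")
    elif left_x is not None:
        fwhm = 2.0 * (pos - left_x)
        log.warning("right half-max flank unreachable; using 2x left half-width")
    else:
        raise ValueError("half maximum never reached on either flank of the peak")
    return float(pos + 0.2 * fwhm)


def cell_mask(pxn_image: np.ndarray) -> np.ndarray:
    """Segment the cell-covered area from the paxillin channel.

    CLAHE (clip 2%) → median filter (disk radius 5) → Gaussian smoothing
    (sigma 5) → binarise at :func:`background_peak_threshold` of the smoothed
    image. Everything downstream is restricted to this mask.
    """
    image = np.asarray(pxn_image, dtype=np.float64)
    if np.ptp(image) == 0:
        if image.max() > 0:  # uniformly bright: one population, all cell
            return np.ones(image.shape, dtype=bool)
        raise ValueError("blank image: degenerate histogram, no cell area")
    enhanced = _clahe(image)
    den = ndi.median_filter(enhanced, footprint=morphology.disk(5))
    sm = ndi.gaussian_filter(den, 5.0)
    return sm > background_peak_threshold(sm)


def local_zscore(image: np.ndarray, window_px: int = 35) -> np.ndarray:
    """Per-pixel z-score over a centred square window, reflective borders.

    Pixels whose window is locally constant (zero standard deviation) get
    z = 0 rather than a division error.
    """
    image = np.asarray(image, dtype=np.float64)
    mean = ndi.uniform_filter(image, size=window_px, mode="reflect")
    meansq = ndi.uniform_filter(image**2, size=window_px, mode="reflect")
    var = np.clip(meansq - mean**2, 0.0, None)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (image - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def spots_from_binary(
    binary: np.ndarray, min_area_px: int = 100, pixel_size_um: float = 0.183
) -> LabeledRegions:
    """Connected components of a spot mask, keeping areas strictly above
    ``min_area_px`` (a 100-pixel component is rejected, a 101-pixel one kept).
    """
    regions = label_mask(np.asarray(binary, dtype=bool), pixel_size_um)
    return filter_area(regions, min_area_px, strict=True)


def channel_spots(
    image: np.ndarray,
    mask: np.ndarray,
    window_px: int = 35,
    z_threshold: float = 1.0,
    min_area_px: int = 100,
    pixel_size_um: float = 0.183,
) -> LabeledRegions:
    """Detect bright spots in one channel inside the cell mask.

    Gaussian smoothing (sigma 3) → CLAHE (clip 2%) → per-pixel z-score in a
    ``window_px`` square → threshold at ``z > z_threshold`` restricted to the
    mask → 8-connected components with area strictly above ``min_area_px``.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask must be congruent with the image")
    sm = ndi.gaussian_filter(image, 3.0)
    enhanced = _clahe(sm)
    z = local_zscore(enhanced, window_px)
    binary = (z > z_threshold) & mask
    return spots_from_binary(binary, min_area_px, pixel_size_um)


def _pair_overlaps(la: np.ndarray, lb: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel intersection counts for every co-occurring (label_a, label_b) pair."""
    both = (la > 0) & (lb > 0)
    if not both.any():
        return {}
    pa, pb = la[both].astype(np.int64), lb[both].astype(np.int64)
    key = pa * (lb.max() + 1) + pb
    uniq, counts = np.unique(key, return_counts=True)
    return {
        (int(k // (lb.max() + 1)), int(k % (lb.max() + 1))): int(c)
        for k, c in zip(uniq, counts)
    }


def mutual_overlap_filter(
    spots_a: LabeledRegions,
    spots_b: LabeledRegions,
    min_overlap_px: int = 5,
) -> tuple[LabeledRegions, LabeledRegions]:
    """Keep only spots overlapping a single partner spot by >= ``min_overlap_px``.

    Overlap is counted per partner spot — two 3-pixel overlaps with different
    partners do not add up to pass a 5-pixel requirement.
    """
    overlaps = _pair_overlaps(spots_a.labels, spots_b.labels)
    keep_a = {a for (a, b), n in overlaps.items() if n >= min_overlap_px}
    keep_b = {b for (a, b), n in overlaps.items() if n >= min_overlap_px}

    def _subset(spots: LabeledRegions, keep: set[int]) -> LabeledRegions:
        kept = np.where(np.isin(spots.labels, sorted(keep)), spots.labels, 0)
        return measure_labels(kept, spots.pixel_size_um)

    return _subset(spots_a, keep_a), _subset(spots_b, keep_b)


@dataclass
class AdhesionTable:
    """Per-adhesion records plus the rasters they were measured on.

    ``adhesions`` columns: ``fa_id``, ``pxn_area_px``, ``vcl_area_px``,
    ``union_area_px``, ``union_area_um2``, ``orientation_deg`` (folded to
    [0°, 90°]), ``centroid_y``, ``centroid_x``, ``n_pxn_spots``,
    ``n_vcl_spots``, ``multi_partner``.
    """

    adhesions: pd.DataFrame
    labels: np.ndarray
    pixel_size_um: float
    stretch_axis: str = "x"

    def __post_init__(self) -> None:
        t = self.adhesions
        if len(t):
            if (t["union_area_px"] < t[["pxn_area_px", "vcl_area_px"]].max(axis=1)).any():
                raise ValueError("union area smaller than a channel area")

    def __len__(self) -> int:
        return len(self.adhesions)


def build_adhesions(
    retained_a: LabeledRegions,
    retained_b: LabeledRegions,
    pixel_size_um: float = 0.183,
    stretch_axis: str = "x",
) -> AdhesionTable:
    """Define focal adhesions as connected unions of retained spot pairs.

    Each 8-connected component of (A-pixels ∪ B-pixels) that contains pixels
    from both channels becomes one FA; a component drawing on more than one
    spot per channel is flagged ``multi_partner``. Orientation is the
    fitted-ellipse major axis of the union, folded against the stretch axis.
    """
    union = retained_a.mask() | retained_b.mask()
    comp = label_mask(union, pixel_size_um)
    rows = []
    fa_labels = np.zeros_like(comp.labels)
    next_id = 1
    for _, reg in comp.regions.iterrows():
        lab = int(reg["label"])
        sel = comp.labels == lab
        a_labels = np.unique(retained_a.labels[sel])
        b_labels = np.unique(retained_b.labels[sel])
        a_labels, b_labels = a_labels[a_labels > 0], b_labels[b_labels > 0]
        if a_labels.size == 0 or b_labels.size == 0:
            continue  # a channel is missing: not an adhesion
        a_px = int((retained_a.labels[sel] > 0).sum())
        b_px = int((retained_b.labels[sel] > 0).sum())
        rows.append(
            {
                "fa_id": next_id,
                "pxn_area_px": a_px,
                "vcl_area_px": b_px,
                "union_area_px": int(reg["area_px"]),
                "union_area_um2": float(reg["area_um2"]),
                "orientation_deg": fold_to_stretch(reg["orientation_deg"], stretch_axis),
                "centroid_y": float(reg["centroid_y"]),
                "centroid_x": float(reg["centroid_x"]),
                "n_pxn_spots": int(a_labels.size),
                "n_vcl_spots": int(b_labels.size),
                "multi_partner": bool(a_labels.size > 1 or b_labels.size > 1),
            }
        )
        fa_labels[sel] = next_id
        next_id += 1
    table = pd.DataFrame(
        rows,
        columns=[
            "fa_id",
            "pxn_area_px",
            "vcl_area_px",
            "union_area_px",
            "union_area_um2",
            "orientation_deg",
            "centroid_y",
            "centroid_x",
            "n_pxn_spots",
            "n_vcl_spots",
            "multi_partner",
        ],
    )
    return AdhesionTable(
        adhesions=table,
        labels=fa_labels,
        pixel_size_um=pixel_size_um,
        stretch_axis=stretch_axis,
    )


def adhesion_metrics(
    table: AdhesionTable, n_cells: int
) -> tuple[dict, AngularDistribution]:
    """Per-image FA summaries and the FA orientation distribution.

    Summaries (all per-FA means): mean Pxn / Vcl spot area (µm²), Pxn / Vcl
    coverage fractions (total channel area over total FA area), mean FA area
    (µm²), and FAs per cell. The orientation distribution carries one folded
    angle per FA for the condition-level statistics.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    t = table.adhesions
    if len(t) == 0:
        raise ValueError("no adhesions to summarise")
    px2 = table.pixel_size_um**2
    union_total = float(t["union_area_px"].sum())
    summary = {
        "mean_pxn_spot_area_um2": float(t["pxn_area_px"].mean()) * px2,
        "mean_vcl_spot_area_um2": float(t["vcl_area_px"].mean()) * px2,
        "pxn_coverage_fraction": float(t["pxn_area_px"].sum()) / union_total,
        "vcl_coverage_fraction": float(t["vcl_area_px"].sum()) / union_total,
        "mean_fa_area_um2": float(t["union_area_um2"].mean()),
        "fa_per_cell": len(t) / n_cells,
        "n_fa": len(t),
        "n_cells": int(n_cells),
    }
    for key in ("pxn_coverage_fraction", "vcl_coverage_fraction"):
        if not 0 < summary[key] <= 1:
            raise AssertionError(f"{key}={summary[key]} outside (0, 1]")
    angles = t["orientation_deg"].to_numpy(dtype=float)
    return summary, cumulative_distribution(angles[~np.isnan(angles)])
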