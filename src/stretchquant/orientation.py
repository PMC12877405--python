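"""Actin-fiber orientation analysis from gray-value gradients.

The orientation of stress fibers in a confluent monolayer is estimated
per pixel from the local intensity gradient (a fiber runs orthogonal to its
gradient), weighted by gradient energy. Because single cells cannot be
segmented in a monolayer, the image is divided into a grid of "cell
equivalents" (default 5 x 3, matching the mean number of cells per field);
each grid square contributes one main orientation — the mode of its weighted
angular histogram — and the per-image mean of these main orientations is the
independent unit of statistical analysis. Angles are folded to [0°, 90°]
relative to the stretch axis: 0° = parallel to strain, 90° = perpendicular;
under a uniform (unstretched, isotropic) orientation law the mean folded
angle is 45°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

#: Histogram bin width in degrees for per-square angle histograms.
_BIN_DEG = 1.0
#: Circular moving-average window (bins) applied to histograms before argmax.
_SMOOTH_BINS = 5


@dataclass
class OrientationField:
    """Per-pixel fiber orientation (degrees in [0, 180)) and gradient energy."""

    angle: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        if self.angle.shape != self.weight.shape:
            raise ValueError("angle and weight rasters must be congruent")
        if np.any(self.weight < 0):
            raise ValueError("weights must be >= 0")


@dataclass
class AngularDistribution:
    """Folded orientations in [0°, 90°] with their empirical CDF.

    ``grid`` holds the sorted support of the cumulative curve and ``cumulative``
    the nondecreasing frequencies reaching 1 at 90°; ``mean_deg`` is the plain
    mean of the folded angles (the per-condition summary statistic).
    """

    angles: np.ndarray
    grid: np.ndarray
    cumulative: np.ndarray
    n_units: int

    @property
    def mean_deg(self) -> float:
        return float(np.mean(self.angles))

    def cdf(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Empirical CDF evaluated at ``theta`` degrees."""
        return np.searchsorted(np.sort(self.angles), theta, side="right") / len(
            self.angles
        )


def orientation_field(
    image: np.ndarray, smoothing_sigma: float = 1.0, operator: str = "sobel"
) -> OrientationField:
    """Per-pixel structure orientation from gray-value gradients.

    The image is lightly Gaussian-smoothed (``smoothing_sigma``), gradients
    are taken (Sobel by default, or Gaussian derivatives with
    ``operator="gaussian"``), and the fiber direction at each pixel is the
    direction orthogonal to the local gradient, as an angle in [0°, 180°) from
    the x-axis. The weight is the squared gradient magnitude, so flat regions
    (including a constant image) carry no orientation signal.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got {image.shape}")
    if operator == "sobel":
        sm = ndi.gaussian_filter(image, smoothing_sigma) if smoothing_sigma > 0 else image
        gy = ndi.sobel(sm, axis=0)
        gx = ndi.sobel(sm, axis=1)
    elif operator == "gaussian":
        gy = ndi.gaussian_filter(image, smoothing_sigma, order=(1, 0))
        gx = ndi.gaussian_filter(image, smoothing_sigma, order=(0, 1))
    else:
        raise ValueError(f"unknown gradient operator {operator!r}")
    # fiber direction is orthogonal to the gradient direction
    angle = (np.degrees(np.arctan2(gy, gx)) + 90.0) % 180.0
    weight = gx**2 + gy**2
    return OrientationField(angle=angle, weight=weight)


def _histogram_mode(angles: np.ndarray, weights: np.ndarray) -> float:
    """Mode of a weighted 1°-binned angular histogram with circular smoothing.

    A 5-bin circular moving average regularises the histogram before the
    argmax; ties break toward the smaller angle (np.argmax takes the first
    maximum). Returns the bin centre in degrees.
    """
    n_bins = int(round(180.0 / _BIN_DEG))
    hist, _ = np.histogram(
        angles, bins=n_bins, range=(0.0, 180.0), weights=weights
    )
    kernel = np.ones(_SMOOTH_BINS) / _SMOOTH_BINS
    pad = _SMOOTH_BINS // 2
    wrapped = np.concatenate([hist[-pad:], hist, hist[:pad]])
    smooth = np.convolve(wrapped, kernel, mode="valid")
    return (np.argmax(smooth) + 0.5) * _BIN_DEG


def grid_main_orientations(
    field: OrientationField,
    grid: tuple[int, int] = (5, 3),
    min_weight_fraction: float = 0.05,
) -> list[float]:
    """Main orientation of each grid square, in [0°, 180°).

    The image is tiled into ``grid = (n_cols, n_rows)`` squares (remainder
    pixels join the last row/column); each square is treated as a cell
    equivalent and contributes the mode of its weight-weighted angle
    histogram. Squares whose total gradient energy falls below
    ``min_weight_fraction`` of the mean per-square energy are omitted — they
    contain no fibers to orient.
    """
    n_cols, n_rows = grid
    h, w = field.angle.shape
    y_edges = [int(round(i * h / n_rows)) for i in range(n_rows)] + [h]
    x_edges = [int(round(j * w / n_cols)) for j in range(n_cols)] + [w]
    total_weight = float(field.weight.sum())
    mean_square_weight = total_weight / (n_rows * n_cols)
    out: list[float] = []
    for i in range(n_rows):
        for j in range(n_cols):
            sl = (slice(y_edges[i], y_edges[i + 1]), slice(x_edges[j], x_edges[j + 1]))
            wts = field.weight[sl].ravel()
            if wts.sum() < min_weight_fraction * mean_square_weight or wts.sum() == 0:
                continue
            out.append(_histogram_mode(field.angle[sl].ravel(), wts))
    return out


def fold_to_stretch(angle, stretch_axis: str = "x"):
    """Fold an orientation in [0°, 180°) to the acute angle from the stretch axis.

    Returns degrees in [0°, 90°]: 0° parallel to the stretch direction, 90°
    perpendicular. Accepts scalars or arrays.
    """
    if stretch_axis not in ("x", "y"):
        raise ValueError(f"stretch_axis must be 'x' or 'y', got {stretch_axis!r}")
    a = np.asarray(angle, dtype=np.float64) % 180.0
    if stretch_axis == "y":
        a = np.abs(90.0 - a)
    folded = np.minimum(a, 180.0 - a)
    return float(folded) if np.isscalar(angle) else folded


def cumulative_distribution(angles) -> AngularDistribution:
    """Empirical cumulative distribution of folded angles over [0°, 90°]."""
    angles = np.asarray(angles, dtype=np.float64)
    if angles.size == 0:
        raise ValueError("cannot build a cumulative distribution from no angles")
    if np.any(angles < 0) or np.any(angles > 90):
        raise ValueError("angles must already be folded to [0, 90] degrees")
    srt = np.sort(angles)
    grid = np.concatenate([[0.0], srt, [90.0]])
    cum = np.concatenate([[0.0], np.arange(1, srt.size + 1) / srt.size, [1.0]])
    return AngularDistribution(
        angles=angles, grid=grid, cumulative=cum, n_units=int(angles.size)
    )


def image_mean_orientation(
    image: np.ndarray,
    grid: tuple[int, int] = (5, 3),
    stretch_axis: str = "x",
    min_weight_fraction: float = 0.05,
    smoothing_sigma: float = 1.0,
) -> tuple[float, list[float]]:
    """Convenience chain: field → per-square main orientations → folded mean.

    Returns the per-image mean folded orientation (the independent statistical
    unit) and the folded per-square angles it averages.
    """
    field = orientation_field(image, smoothing_sigma=smoothing_sigma)
    mains = grid_main_orientations(field, grid, min_weight_fraction)
    folded = [fold_to_stretch(a, stretch_axis) for a in mains]
    if not folded:
        raise ValueError("no grid square carried orientation signal")
    return float(np.mean(folded)), folded
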