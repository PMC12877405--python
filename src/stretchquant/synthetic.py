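"""Synthetic fluorescence scenes with ground truth for every assay.

Each ``make_*_scene`` function renders a noiseless scene emulating one imaging
assay (oriented actin fibers, LC3B/DAPI puncta fields, paired paxillin/vinculin
adhesions, curvilinear mitochondrial networks, dual-channel JC-1 cells) and
returns the raster together with a :class:`SceneTruth` listing every rendered
object and the generative parameters. Photon (Poisson) plus read (Gaussian)
noise is applied separately via :func:`apply_noise` so tests can compare
noiseless and noisy behaviour on the same geometry.

All generators are deterministic under a fixed seed. Object placement uses
rejection sampling with a bounded retry count and fails loudly when packing is
infeasible, so ground-truth counts are never silently corrupted by overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.special import gamma as _gamma
from skimage import morphology

from stretchquant.imgio import ImageStack

#: Retry cap for rejection-sampling placement.
MAX_PACK_TRIES = 1000

#: Default noise model used when a test asks for "noisy" scenes: shot noise at
#: one detected photon per intensity unit, 2-unit read noise, 10-unit offset.
DEFAULT_NOISE = {"photon_scale": 1.0, "read_noise_sd": 2.0, "background_offset": 10.0}


class PackingError(RuntimeError):
    """Raised when objects cannot be placed without violating separation."""


@dataclass
class SceneTruth:
    """Ground truth for a generated scene.

    ``objects`` is a list of per-object records (dicts) with at least ``kind``
    and geometry/intensity fields; ``generative_params`` are the named
    distribution parameters the scene was drawn from; regenerating with the
    same seed and parameters yields an identical raster.
    """

    objects: list[dict]
    generative_params: dict
    seed: int
    pixel_size_um: float

    def of_kind(self, kind: str) -> list[dict]:
        return [o for o in self.objects if o["kind"] == kind]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.objects)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _draw_orientation(rng: np.random.Generator, law) -> float:
    """Sample one orientation in [0, 180) degrees from a named law.

    Laws: ``"uniform"``; ``("fixed", theta)``; ``("vonmises", mu, kappa)``
    (axial von Mises: 2*theta is von Mises distributed with mean 2*mu, so the
    orientation concentrates around ``mu`` with sharpness ``kappa``).
    """
    if law == "uniform" or law == ("uniform",):
        return float(rng.uniform(0.0, 180.0))
    if isinstance(law, (tuple, list)):
        name = law[0]
        if name == "fixed":
            return float(law[1]) % 180.0
        if name in ("vonmises", "von-mises", "von_mises"):
            mu, kappa = float(law[1]), float(law[2])
            phi = rng.vonmises(0.0, kappa)  # in (-pi, pi]
            return float((mu + math.degrees(phi) / 2.0) % 180.0)
    raise ValueError(f"unknown orientation law {law!r}")


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_sep: float,
) -> np.ndarray:
    """Place n points with pairwise separation >= min_sep, margin from borders."""
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PackingError(f"margin {margin} infeasible for shape {shape}")
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        if tries > MAX_PACK_TRIES * max(n, 1):
            raise PackingError(
                f"could not place {n} objects with separation {min_sep} "
                f"in {shape} after {tries} tries"
            )
        tries += 1
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for py, px in pts):
            pts.append((y, x))
    return np.asarray(pts, dtype=float)


def _add_gaussian_spot(
    canvas: np.ndarray, cy: float, cx: float, sigma: float, amplitude: float
) -> None:
    """Add a 2-D Gaussian truncated at 3 sigma, in place."""
    h, w = canvas.shape
    r = int(math.ceil(3 * sigma))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    patch = amplitude * np.exp(-d2 / (2 * sigma**2))
    patch[d2 > (3 * sigma) ** 2] = 0.0
    canvas[y0:y1, x0:x1] += patch


def _add_segment(
    canvas: np.ndarray,
    cy: float,
    cx: float,
    theta_deg: float,
    length: float,
    width: float,
    amplitude: float,
) -> None:
    """Add an anti-aliased line segment with Gaussian cross-section, in place.

    ``theta_deg`` is measured from the x-axis toward the y-axis; ``width`` is
    the full width at half maximum of the cross-section.
    """
    h, w = canvas.shape
    t = math.radians(theta_deg)
    dy, dx = math.sin(t), math.cos(t)
    sigma = width / 2.355
    half = length / 2.0
    pad = int(math.ceil(half + 3 * sigma)) + 1
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ry, rx = yy - cy, xx - cx
    along = ry * dy + rx * dx
    across = -ry * dx + rx * dy
    along_clip = np.clip(along, -half, half)
    d2 = (along - along_clip) ** 2 + across**2
    patch = amplitude * np.exp(-d2 / (2 * sigma**2))
    patch[d2 > (3 * sigma) ** 2] = 0.0
    canvas[y0:y1, x0:x1] += patch


def _stack(
    channels: dict[str, np.ndarray],
    pixel_size_um: float,
    stretch_axis: str = "x",
    n_z: int | None = None,
) -> ImageStack:
    labels = tuple(channels)
    arrs = []
    for lab in labels:
        a = np.asarray(channels[lab], dtype=np.float64)
        if a.ndim == 2:
            a = a[np.newaxis]
        arrs.append(a)
    planes = np.stack(arrs, axis=0)
    return ImageStack(
        planes=planes,
        channels=labels,
        pixel_size_um=pixel_size_um,
        stretch_axis=stretch_axis,
    )


def _fold(theta_deg: float, stretch_axis: str = "x") -> float:
    a = theta_deg % 180.0
    if stretch_axis == "y":
        a = abs(90.0 - a)
    return min(a, 180.0 - a)


# ---------------------------------------------------------------------------
# fiber scenes (actin orientation assay)
# ---------------------------------------------------------------------------


def make_fiber_scene(
    n_fibers: int,
    orientation_law="uniform",
    fiber_length: float = 60.0,
    fiber_width: float = 3.0,
    image_shape: tuple[int, int] = (270, 360),
    seed: int = 0,
    pixel_size_um: float = 1.0,
    amplitude: float = 200.0,
    stretch_axis: str = "x",
) -> tuple[ImageStack, SceneTruth]:
    """Render bright anti-aliased actin-like fibers on a dark background.

    Fiber orientations are drawn from ``orientation_law``; truth records each
    fiber's orientation both raw (in [0°, 180°)) and folded to [0°, 90°]
    against the stretch axis.
    """
    if n_fibers < 0:
        raise ValueError("n_fibers must be >= 0")
    if fiber_length <= 0 or fiber_width <= 0:
        raise ValueError("fiber length and width must be positive")
    if min(image_shape) < fiber_width:
        raise ValueError(
            f"degenerate shape {image_shape}: smaller than fiber width {fiber_width}"
        )
    rng = np.random.default_rng(seed)
    canvas = np.zeros(image_shape, dtype=np.float64)
    objects: list[dict] = []
    h, w = image_shape
    margin = fiber_width  # fibers may run off the border, like real monolayers
    for _ in range(n_fibers):
        theta = _draw_orientation(rng, orientation_law)
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        _add_segment(canvas, cy, cx, theta, fiber_length, fiber_width, amplitude)
        objects.append(
            {
                "kind": "fiber",
                "y": cy,
                "x": cx,
                "theta_deg": theta,
                "angle_folded_deg": _fold(theta, stretch_axis),
                "length_px": fiber_length,
                "width_px": fiber_width,
                "amplitude": amplitude,
            }
        )
    truth = SceneTruth(
        objects=objects,
        generative_params={
            "orientation_law": orientation_law,
            "n_fibers": n_fibers,
            "fiber_length": fiber_length,
            "fiber_width": fiber_width,
            "amplitude": amplitude,
        },
        seed=seed,
        pixel_size_um=pixel_size_um,
    )
    stack = _stack({"actin": canvas}, pixel_size_um, stretch_axis)
    return stack, truth


# ---------------------------------------------------------------------------
# puncta scenes (LC3B assay)
# ---------------------------------------------------------------------------


def make_puncta_scene(
    n_spots: int,
    spot_radius_px: float = 5.0,
    n_nuclei: int = 4,
    min_separation_px: float = 20.0,
    cluster_pairs: int = 0,
    n_small_spots: int = 0,
    small_radius_px: float = 2.5,
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    pixel_size_um: float = 0.071,
    amplitude: float = 150.0,
) -> tuple[ImageStack, SceneTruth]:
    """Render Gaussian LC3B puncta plus elliptical DAPI nuclei.

    ``spot_radius_px`` is the half-maximum radius of each punctum, so the
    rendered area above the half-amplitude reference threshold is close to
    ``pi * r**2``; the exact per-spot pixel count at that threshold is stored
    in truth (``area_at_threshold_px``), making pixel-area filters testable
    exactly. ``cluster_pairs`` pairs are rendered touching (centres 2.25 radii
    apart) to exercise watershed splitting; ``n_small_spots`` adds puncta of
    radius ``small_radius_px`` meant to fall below area filters.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    lc3b = np.zeros(image_shape, dtype=np.float64)
    dapi = np.zeros(image_shape, dtype=np.float64)
    objects: list[dict] = []

    n_singles = n_spots - 2 * cluster_pairs
    if n_singles < 0:
        raise ValueError("n_spots must cover 2 puncta per cluster pair")
    n_sites = n_singles + cluster_pairs + n_small_spots + n_nuclei
    margin = max(4 * spot_radius_px, 14.0)
    sites = _place_points(rng, n_sites, image_shape, margin, min_separation_px)
    site_iter = iter(sites)

    def render_spot(cy: float, cx: float, radius: float) -> None:
        sigma = radius / math.sqrt(2 * math.log(2))
        before = lc3b.copy()
        _add_gaussian_spot(lc3b, cy, cx, sigma, amplitude)
        rendered = lc3b - before
        objects.append(
            {
                "kind": "punctum",
                "y": cy,
                "x": cx,
                "radius_px": radius,
                "amplitude": amplitude,
                "area_at_threshold_px": int(np.count_nonzero(rendered > amplitude / 2)),
            }
        )

    for _ in range(n_singles):
        cy, cx = next(site_iter)
        render_spot(cy, cx, spot_radius_px)
    # close enough that the additive tails keep the pair connected above the
    # half-max threshold, far enough that the union has a waist with two
    # distance-transform maxima (a true dumbbell)
    pair_sep = 2.25 * spot_radius_px
    for _ in range(cluster_pairs):
        cy, cx = next(site_iter)
        ang = rng.uniform(0, 2 * math.pi)
        dy, dx = pair_sep / 2 * math.sin(ang), pair_sep / 2 * math.cos(ang)
        render_spot(cy - dy, cx - dx, spot_radius_px)
        render_spot(cy + dy, cx + dx, spot_radius_px)
    for _ in range(n_small_spots):
        cy, cx = next(site_iter)
        render_spot(cy, cx, small_radius_px)
    for _ in range(n_nuclei):
        cy, cx = next(site_iter)
        ax_a = rng.uniform(9, 13)
        ax_b = rng.uniform(6, 9)
        th = rng.uniform(0, math.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        u = (yy - cy) * math.sin(th) + (xx - cx) * math.cos(th)
        v = -(yy - cy) * math.cos(th) + (xx - cx) * math.sin(th)
        mask = (u / ax_a) ** 2 + (v / ax_b) ** 2 <= 1.0
        dapi[mask] = np.maximum(dapi[mask], 120.0)
        objects.append(
            {
                "kind": "nucleus",
                "y": cy,
                "x": cx,
                "axis_a_px": ax_a,
                "axis_b_px": ax_b,
                "area_px": int(mask.sum()),
            }
        )
    truth = SceneTruth(
        objects=objects,
        generative_params={
            "n_spots": n_spots,
            "spot_radius_px": spot_radius_px,
            "cluster_pairs": cluster_pairs,
            "n_small_spots": n_small_spots,
            "n_nuclei": n_nuclei,
            "amplitude": amplitude,
            "reference_threshold": amplitude / 2,
        },
        seed=seed,
        pixel_size_um=pixel_size_um,
    )
    stack = _stack({"lc3b": lc3b, "dapi": dapi}, pixel_size_um)
    return stack, truth


# ---------------------------------------------------------------------------
# adhesion scenes (paxillin/vinculin colocalization assay)
# ---------------------------------------------------------------------------

_SUPERELLIPSE_P = 2.5  # edge exponent: boxier than an ellipse, still smooth
_ASPECT = 3.5  # major/minor axis ratio of adhesion blobs


def _superellipse_mask(
    shape: tuple[int, int],
    cy: float,
    cx: float,
    a: float,
    b: float,
    theta_deg: float,
    p: float = _SUPERELLIPSE_P,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    t = math.radians(theta_deg)
    u = (yy - cy) * math.sin(t) + (xx - cx) * math.cos(t)
    v = -(yy - cy) * math.cos(t) + (xx - cx) * math.sin(t)
    return (np.abs(u) / a) ** p + (np.abs(v) / b) ** p <= 1.0


def _superellipse_axes(area_px: float, aspect: float = _ASPECT, p: float = _SUPERELLIPSE_P):
    # area of |u/a|^p + |v/b|^p <= 1 is 4ab * Gamma(1+1/p)^2 / Gamma(1+2/p)
    c = 4.0 * _gamma(1 + 1 / p) ** 2 / _gamma(1 + 2 / p)
    b = math.sqrt(area_px / (c * aspect))
    return aspect * b, b


def _pair_masks(
    patch_shape: tuple[int, int],
    theta_deg: float,
    a: float,
    b: float,
    overlap_px: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two superellipse masks sharing exactly ``overlap_px`` pixels.

    Mask B slides along the shared major axis toward mask A until the pixel
    intersection first reaches the target; any excess intersection pixels are
    then carved out of B (the farthest from B's centre), which leaves the
    shapes visually intact while making the overlap count exact.
    """
    cy, cx = (patch_shape[0] - 1) / 2.0, (patch_shape[1] - 1) / 2.0
    t = math.radians(theta_deg)
    dy, dx = math.sin(t), math.cos(t)
    mask_a = _superellipse_mask(patch_shape, cy, cx, a, b, theta_deg)
    d = 2.0 * a + 1.0
    step = 0.2
    while d > 0:
        by, bx = cy + d * dy, cx + d * dx
        mask_b = _superellipse_mask(patch_shape, by, bx, a, b, theta_deg)
        inter = mask_a & mask_b
        n = int(inter.sum())
        if n >= overlap_px:
            if n > overlap_px:
                yy, xx = np.nonzero(inter)
                dist2 = (yy - by) ** 2 + (xx - bx) ** 2
                order = np.argsort(dist2)[::-1]  # farthest from B centre first
                drop = order[: n - overlap_px]
                mask_b[yy[drop], xx[drop]] = False
            return mask_a, mask_b
        d -= step
    raise PackingError(
        f"cannot reach overlap of {overlap_px} px for blob axes ({a:.1f}, {b:.1f})"
    )


def make_adhesion_scene(
    n_pairs: int,
    overlap_px: int = 5,
    spot_area_px: int = 250,
    orientation_law="uniform",
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    pixel_size_um: float = 0.183,
    n_lone_pxn: int = 0,
    n_lone_vcl: int = 0,
    amplitude: float = 180.0,
    background: float = 20.0,
    stretch_axis: str = "x",
) -> tuple[ImageStack, SceneTruth]:
    """Render paired elongated adhesion blobs in ``pxn`` and ``vcl`` channels.

    Each pair consists of two rotated super-ellipses of nominal area
    ``spot_area_px`` sharing exactly ``overlap_px`` foreground pixels at the
    render threshold, at an orientation drawn from ``orientation_law``. Lone
    spots (present in only one channel) exercise the mutual-overlap rejection.
    Around every site the paxillin channel additionally carries a moderate
    cytoplasmic plateau (the diffuse paxillin pool of the cell body), so the
    pxn-derived cell mask covers the vinculin spots as it does in real fields.
    """
    if overlap_px > spot_area_px:
        raise ValueError("overlap_px cannot exceed spot_area_px")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    a, b = _superellipse_axes(spot_area_px)
    patch = int(math.ceil(4 * a + 6 * b))
    patch += patch % 2 == 0  # odd patch so the centre is a pixel
    half = patch // 2
    margin = half + 2
    min_sep = patch + 4.0
    pxn = np.full(image_shape, background, dtype=np.float64)
    vcl = np.full(image_shape, background, dtype=np.float64)
    centers = _place_points(
        rng, n_pairs + n_lone_pxn + n_lone_vcl, image_shape, margin, min_sep
    )
    # diffuse cytoplasmic paxillin plateau around every adhesion site
    cyto = np.zeros(image_shape, dtype=bool)
    patch_r = half + 10
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx in centers:
        cyto |= (yy - cy) ** 2 + (xx - cx) ** 2 <= patch_r**2
    pxn[cyto] = background + 0.2 * amplitude
    objects: list[dict] = []
    idx = 0
    for _ in range(n_pairs):
        cy, cx = centers[idx]
        idx += 1
        theta = _draw_orientation(rng, orientation_law)
        mask_a, mask_b = _pair_masks((patch, patch), theta, a, b, overlap_px)
        y0, x0 = int(round(cy)) - half, int(round(cx)) - half
        sl = (slice(y0, y0 + patch), slice(x0, x0 + patch))
        pxn[sl][mask_a] = background + amplitude
        vcl[sl][mask_b] = background + amplitude
        objects.append(
            {
                "kind": "adhesion_pair",
                "y": cy,
                "x": cx,
                "theta_deg": theta,
                "angle_folded_deg": _fold(theta, stretch_axis),
                "pxn_area_px": int(mask_a.sum()),
                "vcl_area_px": int(mask_b.sum()),
                "union_area_px": int((mask_a | mask_b).sum()),
                "overlap_px": int((mask_a & mask_b).sum()),
            }
        )
    for kind, canvas, n in (
        ("lone_pxn", pxn, n_lone_pxn),
        ("lone_vcl", vcl, n_lone_vcl),
    ):
        for _ in range(n):
            cy, cx = centers[idx]
            idx += 1
            theta = _draw_orientation(rng, orientation_law)
            mask = _superellipse_mask(image_shape, cy, cx, a, b, theta)
            canvas[mask] = background + amplitude
            objects.append(
                {
                    "kind": kind,
                    "y": cy,
                    "x": cx,
                    "theta_deg": theta,
                    "area_px": int(mask.sum()),
                }
            )
    truth = SceneTruth(
        objects=objects,
        generative_params={
            "n_pairs": n_pairs,
            "overlap_px": overlap_px,
            "spot_area_px": spot_area_px,
            "orientation_law": orientation_law,
            "amplitude": amplitude,
            "background": background,
            "render_threshold": background + amplitude / 2,
        },
        seed=seed,
        pixel_size_um=pixel_size_um,
    )
    stack = _stack({"pxn": pxn, "vcl": vcl}, pixel_size_um, stretch_axis)
    return stack, truth


# ---------------------------------------------------------------------------
# mitochondrial network scenes (Tomm20 / MitoTracker assays)
# ---------------------------------------------------------------------------


def make_mito_scene(
    n_branches: int,
    branch_length_law=("uniform", 25.0, 60.0),
    intensity_scale: float = 150.0,
    image_shape: tuple[int, int] = (320, 320),
    n_planes: int = 1,
    seed: int = 0,
    pixel_size_um: float = 0.183,
    branch_width_px: int = 5,
    curliness: float = 0.15,
    heading: float | None = None,
) -> tuple[ImageStack, SceneTruth]:
    """Render curvilinear mitochondrial branches plus an actin cell region.

    Branches are random-walk polylines (heading noise ``curliness`` radians
    per 2-px step, reflecting off image borders) dilated to ``branch_width_px``
    (default 5 px, ~0.9 µm at the Tomm20 pixel size), distributed round-robin
    across ``n_planes``. Placement keeps a >= 5 px clearance between rendered
    branches so ground-truth counts survive segmentation-time smoothing. The
    ``actin`` channel carries a large smooth cell region for masking. Truth
    records each branch's plane, exact polyline path length, and rendered
    foreground area. ``heading`` fixes the initial direction (radians from the
    x-axis) for all branches; with ``curliness=0`` this yields straight
    branches of known length.
    """
    from skimage.draw import line

    if branch_length_law[0] != "uniform":
        raise ValueError(f"unknown branch length law {branch_length_law!r}")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    planes = np.zeros((n_planes, h, w), dtype=np.float64)
    objects: list[dict] = []
    rad = max(branch_width_px // 2, 1)
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    selem = yy**2 + xx**2 <= rad**2
    clear = morphology.disk(rad + 5)
    occupied = np.zeros((h, w), dtype=bool)
    step = 2.0
    margin = rad + 3
    for i in range(n_branches):
        placed = False
        for _ in range(MAX_PACK_TRIES):
            length = float(rng.uniform(branch_length_law[1], branch_length_law[2]))
            cy = float(rng.uniform(margin, h - margin))
            cx = float(rng.uniform(margin, w - margin))
            hd = float(rng.uniform(0, 2 * math.pi)) if heading is None else heading
            n_steps = max(int(round(length / step)), 1)
            ys, xs = [cy], [cx]
            y, x = cy, cx
            for _ in range(n_steps):
                hd += rng.normal(0.0, curliness) if curliness > 0 else 0.0
                ny, nx = y + step * math.sin(hd), x + step * math.cos(hd)
                if not margin <= ny <= h - margin:  # bounce off top/bottom
                    hd = -hd
                    ny = y + step * math.sin(hd)
                if not margin <= nx <= w - margin:  # bounce off left/right
                    hd = math.pi - hd
                    nx = x + step * math.cos(hd)
                y = float(np.clip(ny, margin, h - margin))
                x = float(np.clip(nx, margin, w - margin))
                ys.append(y)
                xs.append(x)
            path = np.zeros((h, w), dtype=bool)
            for (y0, x0), (y1, x1) in zip(zip(ys, xs), zip(ys[1:], xs[1:])):
                rr, cc = line(
                    int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
                )
                path[rr, cc] = True
            branch = ndi.binary_dilation(path, structure=selem)
            if (ndi.binary_dilation(branch, structure=clear) & occupied).any():
                continue
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place branch {i + 1}/{n_branches} without contact"
            )
        occupied |= branch
        z = i % n_planes
        planes[z][branch] = intensity_scale
        objects.append(
            {
                "kind": "mito_branch",
                "plane": z,
                "y": cy,
                "x": cx,
                "path_length_px": float(np.hypot(np.diff(ys), np.diff(xs)).sum()),
                "area_px": int(branch.sum()),
            }
        )
    # large soft-edged cell region in the actin channel, used as analysis mask
    actin = np.zeros((h, w), dtype=np.float64)
    cell = _superellipse_mask((h, w), h / 2, w / 2, h * 0.48, w * 0.48, 0.0, p=4.0)
    actin[cell] = 120.0
    objects.append({"kind": "cell_region", "area_px": int(cell.sum())})
    truth = SceneTruth(
        objects=objects,
        generative_params={
            "n_branches": n_branches,
            "branch_length_law": branch_length_law,
            "branch_width_px": branch_width_px,
            "intensity_scale": intensity_scale,
            "n_planes": n_planes,
            "total_foreground_px": int((planes > 0).sum()),
        },
        seed=seed,
        pixel_size_um=pixel_size_um,
    )
    stack = _stack(
        {"tomm20": planes, "actin": np.broadcast_to(actin, (n_planes, h, w)).copy()},
        pixel_size_um,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cell / JC-1 scenes (intensity-ratio assays)
# ---------------------------------------------------------------------------


def _render_cells(
    rng: np.random.Generator,
    n_cells: int,
    image_shape: tuple[int, int],
    amplitude: float,
    radius_range: tuple[float, float] = (18.0, 26.0),
    edge_sigma: float = 2.0,
) -> tuple[np.ndarray, list[dict]]:
    """Soft-edged elliptical cell bodies on a zero background."""
    h, w = image_shape
    radii = rng.uniform(*radius_range, size=n_cells) if n_cells else np.empty(0)
    margin = (float(radii.max()) if n_cells else 0.0) + 3 * edge_sigma + 2
    min_sep = 2 * margin
    centers = _place_points(rng, n_cells, image_shape, margin, min_sep)
    canvas = np.zeros(image_shape, dtype=np.float64)
    records = []
    for (cy, cx), r in zip(centers, radii):
        ecc = rng.uniform(0.7, 1.0)
        th = rng.uniform(0, math.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        u = (yy - cy) * math.sin(th) + (xx - cx) * math.cos(th)
        v = -(yy - cy) * math.cos(th) + (xx - cx) * math.sin(th)
        mask = (u / r) ** 2 + (v / (r * ecc)) ** 2 <= 1.0
        canvas[mask] = amplitude
        records.append(
            {"kind": "cell", "y": float(cy), "x": float(cx), "radius_px": float(r),
             "area_px": int(mask.sum())}
        )
    if edge_sigma > 0:
        canvas = ndi.gaussian_filter(canvas, edge_sigma)
    return canvas, records


def make_jc1_scene(
    red_green_ratio: float,
    n_cells: int = 5,
    image_shape: tuple[int, int] = (256, 256),
    n_planes: int = 3,
    seed: int = 0,
    pixel_size_um: float = 0.721,
    green_amplitude: float = 100.0,
) -> tuple[ImageStack, SceneTruth]:
    """Render dual-channel JC-1 cells with a prescribed red/green ratio.

    The red channel is exactly ``red_green_ratio`` times the green channel
    pixel for pixel (background zero), so before noise the foreground mean
    ratio equals ``red_green_ratio`` under any mask. Cells span ``n_planes``
    z-planes with varying per-plane brightness so maximum projection matters.
    """
    if red_green_ratio <= 0:
        raise ValueError("red_green_ratio must be positive")
    rng = np.random.default_rng(seed)
    # at 0.721 um/px a cell body is only ~10 px in radius; keeping bright
    # regions smaller than the segmentation's opening element is what lets the
    # opening act as a background estimate
    green2d, records = _render_cells(
        rng, n_cells, image_shape, green_amplitude, radius_range=(9.0, 13.0)
    )
    # per-plane attenuation peaking mid-stack: MIP recovers the full profile
    weights = 1.0 - 0.4 * np.abs(np.linspace(-1, 1, n_planes))
    green = np.stack([w * green2d for w in weights], axis=0)
    red = red_green_ratio * green
    for rec in records:
        rec["kind"] = "jc1_region"
        rec["red_green_ratio"] = red_green_ratio
    truth = SceneTruth(
        objects=records,
        generative_params={
            "red_green_ratio": red_green_ratio,
            "n_cells": n_cells,
            "green_amplitude": green_amplitude,
        },
        seed=seed,
        pixel_size_um=pixel_size_um,
    )
    stack = _stack({"jc1_red": red, "jc1_green": green}, pixel_size_um)
    return stack, truth


def make_cell_scene(
    n_cells: int = 4,
    amplitude: float = 300.0,
    background: float = 50.0,
    image_shape: tuple[int, int] = (512, 512),
    n_planes: int = 3,
    seed: int = 0,
    pixel_size_um: float = 0.18,
    channel: str = "mitotracker",
    radius_range: tuple[float, float] = (25.0, 35.0),
) -> tuple[ImageStack, SceneTruth]:
    """Render plateau-intensity cells over a constant background.

    Used for intensity readouts (MitoTracker-style): cells sit at the absolute
    plateau level ``amplitude`` over a constant ``background``, so the
    background-corrected intensity has the exact reference value
    ``amplitude - background``.
    """
    if amplitude <= background:
        raise ValueError("cell plateau must exceed the background level")
    rng = np.random.default_rng(seed)
    cells, records = _render_cells(
        rng, n_cells, image_shape, amplitude - background,
        radius_range=radius_range, edge_sigma=0.0,
    )
    weights = 1.0 - 0.3 * np.abs(np.linspace(-1, 1, n_planes))
    planes = np.stack([background + w * cells for w in weights], axis=0)
    truth = SceneTruth(
        objects=records,
        generative_params={
            "amplitude": amplitude,
            "background": background,
            "n_cells": n_cells,
        },
        seed=seed,
        pixel_size_um=pixel_size_um,
    )
    stack = _stack({channel: planes}, pixel_size_um)
    return stack, truth


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------


def apply_noise(
    stack: ImageStack,
    photon_scale: float = 1.0,
    read_noise_sd: float = 2.0,
    background_offset: float = 10.0,
    seed: int = 0,
) -> ImageStack:
    """Apply Poisson shot noise plus Gaussian read noise and an offset.

    Per pixel: ``Poisson(photon_scale * I) / photon_scale
    + Normal(0, read_noise_sd) + background_offset``, clipped at zero. Large
    ``photon_scale`` with zero read noise approaches the identity.
    """
    if photon_scale <= 0:
        raise ValueError("photon_scale must be positive")
    if read_noise_sd < 0 or background_offset < 0:
        raise ValueError("read_noise_sd and background_offset must be >= 0")
    rng = np.random.default_rng(seed)
    shot = rng.poisson(photon_scale * stack.planes) / photon_scale
    out = shot + rng.normal(0.0, read_noise_sd, size=stack.planes.shape) if read_noise_sd > 0 else shot
    out = np.clip(out + background_offset, 0.0, None)
    return stack.with_planes(out)
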