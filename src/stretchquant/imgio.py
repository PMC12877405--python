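"""Microscopy raster I/O and the geometric conventions shared by all pipelines.

Conventions
-----------
* Rasters are indexed ``(z, y, x)`` per channel, origin at the top-left pixel.
* Orientations are measured in degrees from the image x-axis, increasing
  toward the positive y-axis, and are reported after folding to [0°, 90°]
  relative to the declared stretch axis (0° = parallel to stretch,
  90° = perpendicular).
* Intensities are converted to float64 on load; the original dtype is kept so
  integer rasters round-trip bit-exactly through :func:`save_image` /
  :func:`load_image`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

#: Channel labels with a defined role somewhere in the package.
KNOWN_CHANNELS = frozenset(
    {
        "actin",
        "pxn",
        "vcl",
        "lc3b",
        "dapi",
        "tomm20",
        "mitotracker",
        "jc1_red",
        "jc1_green",
        "gfp",
    }
)

#: Supported multi-page TIFF layouts.
Z_LAYOUTS = ("pages_are_z", "pages_are_channels")


@dataclass
class ImageStack:
    """A multichannel, multi-plane fluorescence image with physical metadata.

    Parameters
    ----------
    planes
        Intensity raster of shape ``(n_channels, n_z, n_y, n_x)``, float64,
        finite and non-negative.
    channels
        Ordered channel labels, one per leading axis entry.
    pixel_size_um
        Physical edge length of one pixel in micrometres (> 0).
    stretch_axis
        Image axis (``"x"`` or ``"y"``) parallel to the 0° strain direction.
    dtype
        Dtype used when writing to disk (defaults to the loaded file's dtype,
        or float32 for in-memory stacks).
    """

    planes: np.ndarray
    channels: tuple[str, ...]
    pixel_size_um: float
    stretch_axis: str = "x"
    dtype: np.dtype = field(default_factory=lambda: np.dtype("float32"))

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 4:
            raise ValueError(
                f"planes must be 4-D (channel, z, y, x); got shape {self.planes.shape}"
            )
        self.channels = tuple(self.channels)
        if len(self.channels) != self.planes.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.planes.shape[0]} channel planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channel labels: {self.channels}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.stretch_axis not in ("x", "y"):
            raise ValueError(f"stretch_axis must be 'x' or 'y', got {self.stretch_axis!r}")
        if not np.all(np.isfinite(self.planes)) or np.any(self.planes < 0):
            raise ValueError("intensities must be finite and >= 0")
        self.dtype = np.dtype(self.dtype)

    # -- accessors ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_z, n_y, n_x) shared by all channels."""
        return self.planes.shape[1:]

    @property
    def n_z(self) -> int:
        return self.planes.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return the (z, y, x) raster of one channel."""
        try:
            i = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; stack has {self.channels}"
            ) from None
        return self.planes[i]

    def plane(self, label: str, z: int = 0) -> np.ndarray:
        """Return a single (y, x) plane of one channel."""
        return self.channel(label)[z]

    def with_planes(self, planes: np.ndarray) -> "ImageStack":
        """Copy of this stack with a new raster but identical metadata."""
        return replace(self, planes=np.asarray(planes, dtype=np.float64))


def load_image(
    path: str | Path,
    pixel_size_um: float,
    channel_map: Sequence[str],
    stretch_axis: str = "x",
    z_layout: str = "pages_are_channels",
) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    ``channel_map`` binds labels to channels in file order. For 3-D files the
    page axis is ambiguous, so ``z_layout`` declares whether pages are z-planes
    of a single channel (``"pages_are_z"``) or one page per channel
    (``"pages_are_channels"``). 4-D files are read as ``(z, channel, y, x)``.
    """
    if z_layout not in Z_LAYOUTS:
        raise ValueError(f"z_layout must be one of {Z_LAYOUTS}, got {z_layout!r}")
    arr = tifffile.imread(str(path))
    dtype = arr.dtype
    if arr.ndim == 2:
        planes = arr[np.newaxis, np.newaxis]
    elif arr.ndim == 3:
        if z_layout == "pages_are_channels":
            planes = arr[:, np.newaxis]  # (c, 1, y, x)
        else:
            planes = arr[np.newaxis]  # (1, z, y, x)
    elif arr.ndim == 4:  # (z, c, y, x) on disk
        planes = np.moveaxis(arr, 1, 0)
    else:
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")
    if len(channel_map) != planes.shape[0]:
        raise ValueError(
            f"channel_map has {len(channel_map)} labels but file holds "
            f"{planes.shape[0]} channels"
        )
    return ImageStack(
        planes=planes.astype(np.float64),
        channels=tuple(channel_map),
        pixel_size_um=float(pixel_size_um),
        stretch_axis=stretch_axis,
        dtype=dtype,
    )


def save_image(stack: ImageStack, path: str | Path) -> None:
    """Write a stack to TIFF in the layout :func:`load_image` reads back.

    Single-plane stacks are written with one page per channel (2-D file for a
    single channel); single-channel z-stacks with one page per z; general
    stacks as a 4-D ``(z, channel, y, x)`` series. Integer dtypes are restored
    by rounding, making integer round trips bit-exact.
    """
    data = stack.planes
    if np.issubdtype(stack.dtype, np.integer):
        info = np.iinfo(stack.dtype)
        data = np.clip(np.rint(data), info.min, info.max)
    data = data.astype(stack.dtype)
    n_c, n_z = data.shape[:2]
    if n_z == 1 and n_c == 1:
        out = data[0, 0]
    elif n_z == 1:
        out = data[:, 0]
    elif n_c == 1:
        out = data[0]
    else:
        out = np.moveaxis(data, 0, 1)  # (z, c, y, x)
    tifffile.imwrite(str(path), out, photometric="minisblack")


def max_project(stack: ImageStack, channel: str) -> np.ndarray:
    """Maximum-intensity projection of one channel along z.

    ``output[y, x] = max_z input[z, y, x]``; a single-plane channel projects
    to itself.
    """
    return stack.channel(channel).max(axis=0)


def load_config(path: str | Path) -> Mapping:
    """Read a YAML run/acquisition config (pixel_size_um, channel_map, ...)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg
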