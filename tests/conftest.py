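"""Shared fixtures and exact-geometry helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def exact_area_blob(shape: tuple[int, int], center: tuple[int, int], n_px: int) -> np.ndarray:
    """Boolean mask of a compact, connected blob with exactly ``n_px`` pixels.

    Pixels are taken in order of distance from the centre (ties broken by
    array order), which yields a quasi-disk; used to probe pixel-exact area
    filters (< 70 px rejected, > 100 px retained, >= 1000 px kept, ...).
    """
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:n_px]
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[order] = True
    return mask


@pytest.fixture
def blob():
    return exact_area_blob


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
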