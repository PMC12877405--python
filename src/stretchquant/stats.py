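"""Condition-level statistics for the imaging readouts.

Conditions (stretched vs. unstretched, treated vs. untreated) are compared on
per-unit values — per-image mean orientations, per-FA angles, per-image spot
counts or intensities. Angular distributions use the two-sample
Kolmogorov–Smirnov test on folded angles; scalar readouts use the
Mann–Whitney U test; uncertainty bands are percentile-bootstrap 95% intervals
over the independent units; intensity-type readouts are reported relative to
the unstretched-control mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from stretchquant.orientation import AngularDistribution


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class CIBand:
    """Pointwise percentile-bootstrap confidence band (or scalar interval)."""

    lower: np.ndarray | float
    upper: np.ndarray | float
    level: float
    n_boot: int
    seed: int
    grid: np.ndarray | None = None


def ks_two_sample(a, b) -> ComparisonResult:
    """Two-sample Kolmogorov–Smirnov test.

    ``D = sup |ECDF_a - ECDF_b|``; the p-value uses the exact two-sample null
    distribution when ``n1 * n2 <= 10_000`` and the asymptotic Kolmogorov
    distribution otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if a.size * b.size <= 10_000 else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        method=f"ks_{method}",
    )


def mann_whitney(a, b) -> ComparisonResult:
    """Two-sided Mann–Whitney U test.

    Uses the exact U distribution for small samples (both n <= 8, no ties)
    and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        method=f"mwu_{method}",
    )


def bootstrap_ci95(
    per_unit_values,
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    grid: np.ndarray | None = None,
) -> CIBand:
    """Percentile bootstrap CI over independent units (images or cells).

    For a list of scalars, resamples units and returns the percentile interval
    of the mean. For a list of :class:`AngularDistribution` objects, resamples
    whole distributions (the independent unit) and returns pointwise
    percentile bands of the cumulative frequency over ``grid`` (default: 0–90°
    in 1° steps).
    """
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    vals = list(per_unit_values)
    if not vals:
        raise ValueError("need at least one unit to bootstrap")
    if isinstance(vals[0], AngularDistribution):
        if grid is None:
            grid = np.arange(0.0, 90.5, 1.0)
        curves = np.stack([np.asarray(d.cdf(grid), dtype=float) for d in vals])
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        boot = curves[idx].mean(axis=1)  # (n_boot, n_grid)
        lower = np.quantile(boot, alpha, axis=0)
        upper = np.quantile(boot, 1 - alpha, axis=0)
        return CIBand(lower=lower, upper=upper, level=level, n_boot=n_boot, seed=seed, grid=grid)
    arr = np.asarray(vals, dtype=np.float64)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    boot = arr[idx].mean(axis=1)
    return CIBand(
        lower=float(np.quantile(boot, alpha)),
        upper=float(np.quantile(boot, 1 - alpha)),
        level=level,
        n_boot=n_boot,
        seed=seed,
    )


def normalize_to_control(values, control_values) -> np.ndarray:
    """Scale values so the control mean maps to 1."""
    values = np.asarray(values, dtype=np.float64)
    control = np.asarray(control_values, dtype=np.float64)
    if control.size == 0:
        raise ValueError("control sample is empty")
    m = control.mean()
    if m == 0:
        raise ValueError("control mean is zero; cannot normalise")
    return values / m


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional, off by default upstream)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=np.float64)
    return multipletests(p, method="fdr_bh")[1]
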