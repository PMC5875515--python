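"""Per-plaque-type statistics over calibration factors and the deviation histogram.

Calibration factors for each plaque type are averaged to establish the
reference factor for that type; the sample standard deviation measures the
repeatability of the process and the coefficient of variation (CV = 100*sd/mean)
lets types of different magnitude be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GroupStats",
    "PooledStats",
    "group_statistics",
    "pooled_statistics",
    "deviation_histogram",
]


@dataclass(frozen=True)
class GroupStats:
    """Summary of the calibration factors measured for one plaque type."""

    plaque_type: str
    n: int
    mean_factor: float
    sd_factor: float | None   # sample (n-1) sd; absent for n = 1
    cv_pct: float | None      # 100 * sd / mean; absent for n = 1


@dataclass(frozen=True)
class PooledStats:
    """Cohort-level summary across plaque types.

    ``pooled_mean`` weights each type's mean by its plaque count (the mean a
    single pooled cohort would give); ``unweighted_mean`` averages the type
    means directly.  ``average_cv_pct`` is the unweighted mean of the per-type
    CVs — the precision achievable when each type keeps its own reference
    factor — with the plaque-count-weighted variant alongside.
    """

    n_types: int
    n_plaques: int
    pooled_mean: float
    unweighted_mean: float
    average_cv_pct: float | None
    weighted_cv_pct: float | None


def group_statistics(factors: Sequence[float], plaque_type: str) -> GroupStats:
    """Mean, sample sd, and CV of one plaque type's calibration factors."""
    arr = np.asarray(list(factors), dtype=float)
    if arr.size == 0:
        raise ValueError(f"no calibration factors for {plaque_type}")
    if not np.all(arr > 0):
        raise ValueError(f"nonpositive calibration factor for {plaque_type}")
    mean = float(arr.mean())
    if arr.size == 1:
        return GroupStats(plaque_type, 1, mean, None, None)
    sd = float(arr.std(ddof=1))
    return GroupStats(plaque_type, int(arr.size), mean, sd, 100.0 * sd / mean)


def pooled_statistics(per_type: Sequence[GroupStats]) -> PooledStats:
    """Combine per-type statistics into cohort-level numbers."""
    if not per_type:
        raise ValueError("no groups to pool")
    ns = np.array([g.n for g in per_type], dtype=float)
    means = np.array([g.mean_factor for g in per_type], dtype=float)
    cvs = np.array([g.cv_pct if g.cv_pct is not None else np.nan
                    for g in per_type], dtype=float)
    have_cv = ~np.isnan(cvs)
    return PooledStats(
        n_types=len(per_type),
        n_plaques=int(ns.sum()),
        pooled_mean=float((ns * means).sum() / ns.sum()),
        unweighted_mean=float(means.mean()),
        average_cv_pct=float(cvs[have_cv].mean()) if have_cv.any() else None,
        weighted_cv_pct=(float((ns[have_cv] * cvs[have_cv]).sum()
                               / ns[have_cv].sum()) if have_cv.any() else None),
    )


def deviation_histogram(
    deviations: Sequence[float], bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Bin percent deviations into half-open bins aligned to multiples of width.

    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1`` and bins
    ``[edges[i], edges[i+1])``; edges are integer multiples of ``bin_width`` so
    zero always falls on an edge.  The counts sum to the number of inputs.
    An empty input yields a single empty bin around zero.
    """
    if not bin_width > 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    arr = np.asarray(list(deviations), dtype=float)
    if arr.size == 0:
        return np.array([0.0, bin_width]), np.array([0])
    lo = np.floor(arr.min() / bin_width)
    hi = np.floor(arr.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    idx = np.floor(arr / bin_width).astype(int) - int(lo)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return edges, counts
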