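"""Per-position seed contributions for slotted plaques.

The EP917's 17 collimating slots could in principle shield positions
unequally, which would break the single-calibration-factor assumption for
partially loaded plaques.  Two measurement designs quantify each position's
share of the total plaque activity:

* *placement*: a single seed is measured in each position in turn; the
  fraction is that activity over the sum across positions;
* *removal*: one seed at a time is removed from a fully loaded plaque; the
  fraction is the drop in total activity over the fully loaded total.

If every position contributes ~1/17th, the plaque calibration factor carries
over to partially loaded plaques regardless of which slots are filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SeedContributionTable",
    "UniformitySummary",
    "contributions_from_placements",
    "contributions_from_removals",
    "uniformity_summary",
]


def contributions_from_placements(activities_mci: Sequence[float]) -> np.ndarray:
    """Per-position activity fractions from single-seed placement readings.

    ``fraction[i] = activity[i] / sum(activities)``; the fractions sum to
    exactly 1 before any rounding.
    """
    arr = np.asarray(list(activities_mci), dtype=float)
    if arr.size == 0:
        raise ValueError("no activities")
    if not np.all(arr > 0):
        bad = int(np.argmin(arr))
        raise ValueError(
            f"nonpositive activity {arr[bad]} mCi at position {bad + 1}"
        )
    return arr / arr.sum()


def contributions_from_removals(
    full_total_mci: float,
    totals_with_one_removed_mci: Sequence[float],
    *,
    renormalize: bool = False,
) -> np.ndarray:
    """Per-position fractions from one-seed-at-a-time removal readings.

    ``fraction[i] = (full_total - total_without_seed_i) / full_total``.  Each
    removed total must be strictly below the fully loaded total: a removal
    that does not lower the reading signals a measurement error.  Measurement
    noise makes the raw fractions sum to slightly off 1; ``renormalize=True``
    rescales them to unit sum (the choice is the caller's and is recorded in
    the returned array only through its values).
    """
    if not full_total_mci > 0:
        raise ValueError(f"full total must be > 0, got {full_total_mci}")
    arr = np.asarray(list(totals_with_one_removed_mci), dtype=float)
    if arr.size == 0:
        raise ValueError("no removal totals")
    if np.any(arr >= full_total_mci):
        bad = int(np.argmax(arr))
        raise ValueError(
            f"removal total {arr[bad]} mCi at position {bad + 1} is not below "
            f"the fully loaded total {full_total_mci} mCi (measurement error?)"
        )
    fractions = (full_total_mci - arr) / full_total_mci
    if renormalize:
        fractions = fractions / fractions.sum()
    return fractions


@dataclass
class SeedContributionTable:
    """Per-position contribution fractions for one or more plaques.

    ``fractions`` is positions x plaques with plaque ids as columns and
    1-based seed positions as the index; each column sums to 1 within the
    method's rounding.
    """

    fractions: pd.DataFrame
    method: str  # "placement" or "removal"

    @classmethod
    def from_placements(
        cls, activities: Mapping[str, Sequence[float]]
    ) -> "SeedContributionTable":
        """Build from per-plaque single-seed placement activities (mCi)."""
        cols = {pid: contributions_from_placements(act)
                for pid, act in activities.items()}
        return cls(_frame(cols), "placement")

    @classmethod
    def from_removals(
        cls,
        full_totals: Mapping[str, float],
        removed_totals: Mapping[str, Sequence[float]],
        *,
        renormalize: bool = False,
    ) -> "SeedContributionTable":
        """Build from per-plaque full totals and one-removed totals (mCi)."""
        cols = {
            pid: contributions_from_removals(full_totals[pid], removed,
                                             renormalize=renormalize)
            for pid, removed in removed_totals.items()
        }
        return cls(_frame(cols), "removal")


def _frame(cols: Mapping[str, np.ndarray]) -> pd.DataFrame:
    lengths = {len(v) for v in cols.values()}
    if len(lengths) > 1:
        raise ValueError(f"plaques have mismatched position counts: {lengths}")
    n = lengths.pop()
    return pd.DataFrame(cols, index=pd.RangeIndex(1, n + 1, name="position"))


@dataclass(frozen=True)
class UniformitySummary:
    """How evenly the seed positions share the total activity.

    ``per_position_mean_pct[i]`` averages position i's percentage across
    plaques; ``grand_mean_pct`` and ``grand_sd_pct`` are the mean and sample
    sd of those per-position averages.  A perfectly uniform n-slot plaque has
    grand mean 100/n and sd 0.
    """

    per_position_mean_pct: pd.Series
    grand_mean_pct: float
    grand_sd_pct: float


def uniformity_summary(table: SeedContributionTable) -> UniformitySummary:
    """Summarize position-to-position uniformity across plaques.

    Per-position averages are plain means of the per-plaque percentages (not
    activity-weighted); the grand sd is taken over the per-position averages,
    not over all raw fractions.
    """
    pct = table.fractions * 100.0
    per_position = pct.mean(axis=1)
    grand_sd = float(per_position.std(ddof=1)) if len(per_position) > 1 else 0.0
    return UniformitySummary(
        per_position_mean_pct=per_position,
        grand_mean_pct=float(per_position.mean()),
        grand_sd_pct=grand_sd,
    )
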