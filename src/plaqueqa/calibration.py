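"""Plaque calibration factors: the core verification statistic.

For each plaque the four dose-calibrator readings are averaged, converted to
air kerma strength, and divided by the certificate strength decayed to the
measurement date, giving a dimensionless *plaque calibration factor*.  The
factor is well below 1 because the gold shell (and, for the EP917, the
collimating slots) shields laterally directed primary radiation from the well
chamber.  Deviations of a plaque's factor from the established mean for its
plaque type beyond the 5% action limit flag the plaque for investigation,
following AAPM low-energy source-calibration guidance for batch assays.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .quantities import PhysicsConstants, activity_to_air_kerma_strength, decay_correct
from .records import AngleReadings, PlaqueRecord, SeedAssay

__all__ = [
    "Flag",
    "QALimits",
    "CalibrationResult",
    "average_readings",
    "calibration_factor",
    "deviation_from_mean",
    "evaluate_record",
    "cross_check",
]


class Flag(enum.Enum):
    """QA flags a record can raise."""

    READING_SPREAD = "reading_spread"   # four-angle spread > 4%: reposition and remeasure
    ACTION_LIMIT = "action_limit"       # |deviation from type mean| > 5%
    CROSS_CHECK = "cross_check"         # plan vs assay disagreement > 5%


@dataclass(frozen=True)
class QALimits:
    """Action thresholds, all in percent.

    reading_spread_limit
        Maximum acceptable spread of the four angle readings; a larger spread
        means the plaque was off-center and should be repositioned and
        remeasured (default 4).
    action_limit
        Maximum |deviation| of a calibration factor from its type mean before
        the plaque requires investigation (default 5, the Delta-S_K limit).
    cross_check_limit
        Maximum plan-vs-assay disagreement, in strength or in factor
        (default 5).
    spread_metric
        "mean" computes spread as 100*(max-min)/mean (default);
        "min" uses 100*(max-min)/min.
    """

    reading_spread_limit: float = 4.0
    action_limit: float = 5.0
    cross_check_limit: float = 5.0
    spread_metric: str = "mean"

    def __post_init__(self) -> None:
        for name in ("reading_spread_limit", "action_limit", "cross_check_limit"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.spread_metric not in ("mean", "min"):
            raise ValueError(f"spread_metric must be 'mean' or 'min', got "
                             f"{self.spread_metric!r}")


@dataclass
class CalibrationResult:
    """Evaluated quantities for one plaque."""

    plaque_id: str
    mean_activity_mci: float
    spread_pct: float | None
    measured_strength_u: float
    decayed_assay_strength_u: float
    cal_factor: float
    deviation_pct: float | None = None
    flags: set[Flag] = field(default_factory=set)


def average_readings(
    readings: AngleReadings, limits: QALimits = QALimits()
) -> tuple[float, float, bool]:
    """Average the four angle readings and check their spread.

    Returns ``(mean_activity_mci, spread_pct, spread_ok)``.  The spread is
    100*(max-min)/mean (or /min, per ``limits.spread_metric``); when it
    exceeds the limit the plaque should be repositioned and the four
    measurements repeated, so ``spread_ok`` is False.
    """
    values = readings.readings_mci
    mean = sum(values) / 4.0
    if mean == 0:
        raise ValueError("all four readings are zero; spread undefined")
    denom = mean if limits.spread_metric == "mean" else min(values)
    if denom == 0:
        raise ValueError("zero reading; spread undefined under 'min' metric")
    spread = 100.0 * (max(values) - min(values)) / denom
    return mean, spread, spread <= limits.reading_spread_limit


def calibration_factor(measured_strength_u: float,
                       decayed_assay_strength_u: float) -> float:
    """Measured air kerma strength divided by the decayed assay strength."""
    if not decayed_assay_strength_u > 0:
        raise ValueError(
            f"decayed assay strength must be > 0, got {decayed_assay_strength_u}"
        )
    if not measured_strength_u > 0:
        raise ValueError(
            f"measured strength must be > 0, got {measured_strength_u}"
        )
    return measured_strength_u / decayed_assay_strength_u


def deviation_from_mean(cal_factor: float, group_mean_factor: float) -> float:
    """Percent deviation of a factor from its plaque-type mean."""
    if not group_mean_factor > 0:
        raise ValueError(f"group mean must be > 0, got {group_mean_factor}")
    return 100.0 * (cal_factor / group_mean_factor - 1.0)


def evaluate_record(
    record: PlaqueRecord,
    group_mean_factor: float | None = None,
    constants: PhysicsConstants = PhysicsConstants(),
    limits: QALimits = QALimits(),
) -> CalibrationResult:
    """Run the full worksheet chain for one plaque.

    Averages the readings (or uses the stored pre-averaged activity), converts
    to air kerma strength, decays the assay strength to the measurement date,
    forms the calibration factor, and — when a group mean is supplied — the
    percent deviation with the action-limit flag.  The group mean is an
    explicit input, never inferred here: its provenance (which cohort it was
    averaged over) is the caller's responsibility.
    """
    flags: set[Flag] = set()
    spread_pct: float | None = None
    if record.readings is not None:
        mean_activity, spread_pct, spread_ok = average_readings(record.readings,
                                                                limits)
        if not spread_ok:
            flags.add(Flag.READING_SPREAD)
    else:
        mean_activity = float(record.activity_mci)

    measured = activity_to_air_kerma_strength(mean_activity, constants,
                                              context=f"plaque {record.plaque_id}")
    decayed = decay_correct(record.assay.total_strength_u,
                            record.assay.assay_date,
                            record.measurement_date, constants)
    try:
        factor = calibration_factor(measured, decayed)
    except ValueError as exc:
        raise ValueError(f"plaque {record.plaque_id}: {exc}") from exc

    deviation: float | None = None
    if group_mean_factor is not None:
        deviation = deviation_from_mean(factor, group_mean_factor)
        if abs(deviation) > limits.action_limit:
            flags.add(Flag.ACTION_LIMIT)

    if record.plan is not None:
        decayed_plan = decay_correct(record.plan.total_strength_u,
                                     record.plan.assay_date,
                                     record.measurement_date, constants)
        factor_vs_plan = calibration_factor(measured, decayed_plan)
        flags |= cross_check(record.plan, record.assay, factor_vs_plan, factor,
                             limits, constants=constants)

    return CalibrationResult(
        plaque_id=record.plaque_id,
        mean_activity_mci=mean_activity,
        spread_pct=spread_pct,
        measured_strength_u=measured,
        decayed_assay_strength_u=decayed,
        cal_factor=factor,
        deviation_pct=deviation,
        flags=flags,
    )


def cross_check(
    plan: SeedAssay | None,
    assay: SeedAssay,
    measured_factor_vs_plan: float | None,
    measured_factor_vs_assay: float,
    limits: QALimits = QALimits(),
    *,
    constants: PhysicsConstants = PhysicsConstants(),
) -> set[Flag]:
    """Compare the treatment-plan seed data against the assay certificate.

    Two comparisons are made: the plan strength decay-aligned to the assay
    date versus the assay strength, and the calibration factor computed
    against the plan versus the one computed against the assay.  Either
    disagreement beyond ``limits.cross_check_limit`` percent raises the
    CROSS_CHECK flag.  With no plan the check is skipped.
    """
    if plan is None:
        return set()
    flags: set[Flag] = set()
    plan_at_assay = decay_correct(plan.total_strength_u, plan.assay_date,
                                  assay.assay_date, constants)
    strength_diff = 100.0 * abs(plan_at_assay / assay.total_strength_u - 1.0)
    if strength_diff > limits.cross_check_limit:
        flags.add(Flag.CROSS_CHECK)
    if measured_factor_vs_plan is not None:
        factor_diff = 100.0 * abs(
            measured_factor_vs_plan / measured_factor_vs_assay - 1.0
        )
        if factor_diff > limits.cross_check_limit:
            flags.add(Flag.CROSS_CHECK)
    return flags
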