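"""Synthetic plaque records and error injection for validating the QA flags.

The simulator emulates the measurement process: a plaque of a given type has
a true calibration factor drawn from that type's distribution (normal, with
the type's mean and CV), an assay certificate with a realistic strength and
date, and four dose-calibrator readings whose mean equals
``factor x decayed_strength / u_per_mci`` with independent multiplicative
lognormal angle noise.  With the noise turned off, evaluating a simulated
record recovers the drawn factor to machine precision.

``inject_error`` corrupts a clean record with one of the failure modes seen
in clinical practice — unit confusion between U and mCi on the certificate,
digit-transposition transcription errors, shipment of a wrong plaque, and a
mismatch between ordered and delivered seed activity — and
``sensitivity_study`` measures how often the 5% action limit catches each.
"""

from __future__ import annotations

import copy
import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import Flag, QALimits, evaluate_record
from .datasets import EP917_CV_PCT, EP917_MEAN_CAL_FACTOR, coms_group_stats
from .quantities import PhysicsConstants, decay_correct
from .records import (
    DEFAULT_PLAQUE_TYPES,
    AngleReadings,
    PlaqueRecord,
    SeedAssay,
)

__all__ = [
    "ERROR_KINDS",
    "SimulationConfig",
    "SimulatedRecord",
    "simulate_record",
    "simulate_cohort",
    "inject_error",
    "sensitivity_study",
]

#: Failure modes the injector knows.
ERROR_KINDS = ("unit_confusion", "transcription", "wrong_plaque",
               "activity_mismatch")


def _default_type_factors() -> dict[str, tuple[float, float]]:
    factors = {"EP917": (EP917_MEAN_CAL_FACTOR, EP917_CV_PCT)}
    for g in coms_group_stats():
        factors[g.plaque_type] = (g.mean_factor, g.cv_pct)
    return factors


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    type_factors
        Per-type ``(mean calibration factor, CV percent)``; defaults are the
        clinical cohort values (EP917 0.353 / 3.29%, COMS types per their
        group statistics).
    angle_noise_sigma
        Log-scale sigma of the multiplicative lognormal noise on each of the
        four angle readings.  The default 0.015 keeps the four-reading spread
        typically below the 4% repositioning limit (expected range of four
        draws ~ 2.06 sigma ~ 3.1%).
    strength_range_u
        Uniform range for the assayed total strength (default 30-120 U,
        spanning typical loaded-plaque certificates).
    assay_lead_days
        Uniform range of days between assay and measurement (negative values
        allowed; measurements a few days before assay occur in practice).
    error_rates
        Probability per record of each failure mode in a mixed cohort; the
        rates must sum to at most 1.
    activity_mismatch_pct
        Rescaling applied by the ``activity_mismatch`` mode (default -6.8%,
        the worst case observed clinically).
    """

    type_factors: dict[str, tuple[float, float]] = field(
        default_factory=_default_type_factors)
    angle_noise_sigma: float = 0.015
    strength_range_u: tuple[float, float] = (30.0, 120.0)
    assay_lead_days: tuple[int, int] = (-3, 40)
    base_date: dt.date = dt.date(2012, 1, 1)
    error_rates: dict[str, float] = field(default_factory=dict)
    activity_mismatch_pct: float = -6.8

    def __post_init__(self) -> None:
        for kind, rate in self.error_rates.items():
            if kind not in ERROR_KINDS:
                raise ValueError(f"unknown error kind {kind!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {kind} must be in [0, 1]")
        if sum(self.error_rates.values()) > 1.0:
            raise ValueError("error rates sum to more than 1")
        for label, (mean, cv) in self.type_factors.items():
            if not mean > 0 or cv < 0:
                raise ValueError(f"bad factor spec for {label}: ({mean}, {cv})")


@dataclass
class SimulatedRecord:
    """A synthetic record with its ground truth attached."""

    record: PlaqueRecord
    true_factor: float
    error_kind: str | None = None


def simulate_record(
    config: SimulationConfig,
    plaque_type: str,
    rng: np.random.Generator,
    constants: PhysicsConstants = PhysicsConstants(),
) -> SimulatedRecord:
    """Draw one synthetic plaque record of the given type.

    The four readings are ``mean_activity x exp(sigma * z_i)`` with
    ``mean_activity = factor x decayed_strength / u_per_mci``; with
    ``angle_noise_sigma = 0`` the record evaluates back to ``factor`` exactly.
    Deterministic for a given generator state.
    """
    if plaque_type not in config.type_factors:
        raise ValueError(f"unknown plaque type {plaque_type!r}")
    ptype = DEFAULT_PLAQUE_TYPES.get(plaque_type)
    if ptype is None:
        raise ValueError(f"unknown plaque type {plaque_type!r}")
    mean_factor, cv_pct = config.type_factors[plaque_type]
    factor = float(rng.normal(mean_factor, mean_factor * cv_pct / 100.0))
    factor = max(factor, 1e-6)

    lo, hi = config.strength_range_u
    strength = float(rng.uniform(lo, hi))
    assay_date = config.base_date + dt.timedelta(days=int(rng.integers(0, 365)))
    lead = int(rng.integers(config.assay_lead_days[0],
                            config.assay_lead_days[1] + 1))
    meas_date = assay_date + dt.timedelta(days=lead)

    decayed = decay_correct(strength, assay_date, meas_date, constants)
    mean_activity = factor * decayed / constants.u_per_mci
    if config.angle_noise_sigma > 0:
        noise = np.exp(config.angle_noise_sigma * rng.standard_normal(4))
    else:
        noise = np.ones(4)
    readings = AngleReadings(tuple(float(mean_activity * n) for n in noise))

    record = PlaqueRecord(
        plaque_id=f"sim-{plaque_type}-{rng.integers(0, 10**9)}",
        plaque_type=ptype,
        assay=SeedAssay(ptype.capacity, assay_date, strength),
        measurement_date=meas_date,
        readings=readings,
    )
    return SimulatedRecord(record=record, true_factor=factor)


def simulate_cohort(
    config: SimulationConfig,
    plaque_type: str,
    n_records: int,
    rng: np.random.Generator,
    constants: PhysicsConstants = PhysicsConstants(),
) -> list[SimulatedRecord]:
    """Draw a cohort, applying the configured error mix record by record."""
    cohort = []
    kinds = list(config.error_rates)
    probs = [config.error_rates[k] for k in kinds]
    for _ in range(n_records):
        sim = simulate_record(config, plaque_type, rng, constants)
        u = float(rng.uniform())
        acc = 0.0
        for kind, p in zip(kinds, probs):
            acc += p
            if u < acc:
                sim = inject_error(sim, kind, rng, config=config)
                break
        cohort.append(sim)
    return cohort


def _swap_adjacent_digits(text: str, rng: np.random.Generator) -> str:
    digits = [i for i, c in enumerate(text) if c.isdigit()]
    pairs = [(i, j) for i, j in zip(digits, digits[1:])
             if j == i + 1 or text[i + 1:j] == "."]
    swappable = [(i, j) for i, j in pairs if text[i] != text[j]]
    if not swappable:
        return text
    i, j = swappable[int(rng.integers(0, len(swappable)))]
    chars = list(text)
    chars[i], chars[j] = chars[j], chars[i]
    return "".join(chars)


def inject_error(
    sim: SimulatedRecord,
    error_kind: str,
    rng: np.random.Generator,
    *,
    config: SimulationConfig | None = None,
    constants: PhysicsConstants = PhysicsConstants(),
) -> SimulatedRecord:
    """Corrupt a clean simulated record with one failure mode.

    unit_confusion
        The certificate's apparent-activity number (mCi) is entered in the
        strength field: assay strength x mci_per_u, shifting the factor by
        +27% (100 x (1/0.787 - 1)).
    transcription
        Two adjacent differing digits of the assay strength are swapped.
    wrong_plaque
        Readings rescaled by another type's factor over this type's — the
        delivered plaque is not the one on the certificate.
    activity_mismatch
        Readings rescaled by ``config.activity_mismatch_pct`` percent.
    """
    if error_kind not in ERROR_KINDS:
        raise ValueError(f"unknown error kind {error_kind!r}")
    config = config or SimulationConfig()
    record = copy.deepcopy(sim.record)
    assay = record.assay

    if error_kind == "unit_confusion":
        record.assay = replace(
            assay, total_strength_u=assay.total_strength_u * constants.mci_per_u)
    elif error_kind == "transcription":
        text = f"{assay.total_strength_u:.2f}"
        record.assay = replace(assay,
                               total_strength_u=float(_swap_adjacent_digits(text, rng)))
    elif error_kind == "wrong_plaque":
        own = config.type_factors[record.plaque_type.label][0]
        others = [m for label, (m, _) in config.type_factors.items()
                  if label != record.plaque_type.label]
        if not others:
            # the delivered plaque can be of any known type, whether or not
            # the study config tracks it
            others = [m for label, (m, _) in _default_type_factors().items()
                      if label != record.plaque_type.label]
        other = others[int(rng.integers(0, len(others)))]
        record.readings = _scale_readings(record.readings, other / own)
    elif error_kind == "activity_mismatch":
        scale = 1.0 + config.activity_mismatch_pct / 100.0
        record.readings = _scale_readings(record.readings, scale)
    return SimulatedRecord(record=record, true_factor=sim.true_factor,
                           error_kind=error_kind)


def _scale_readings(readings: AngleReadings | None, scale: float) -> AngleReadings:
    if readings is None:
        raise ValueError("record stores no angle readings to rescale")
    return AngleReadings(tuple(r * scale for r in readings.readings_mci))


def sensitivity_study(
    config: SimulationConfig,
    n_records: int,
    seed: int | np.random.Generator = 0,
    *,
    plaque_type: str = "EP917",
    error_kinds: tuple[str, ...] = ERROR_KINDS,
    constants: PhysicsConstants = PhysicsConstants(),
    limits: QALimits = QALimits(),
):
    """Detection and false-positive rates of the action limit, per error kind.

    For each kind, ``n_records`` clean records and ``n_records`` corrupted
    ones are evaluated against the type's configured mean factor; detection
    is the fraction of corrupted records raising ACTION_LIMIT, and the
    false-positive rate is the fraction of clean records raising it.
    Returns a pandas DataFrame indexed by error kind with columns
    ``detection_rate_pct``, ``false_positive_rate_pct`` and ``n``.
    """
    import pandas as pd

    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    group_mean = config.type_factors[plaque_type][0]

    def flagged(sim: SimulatedRecord) -> bool:
        result = evaluate_record(sim.record, group_mean, constants, limits)
        return Flag.ACTION_LIMIT in result.flags

    rows = {}
    clean = [simulate_record(config, plaque_type, rng, constants)
             for _ in range(n_records)]
    fp = 100.0 * sum(flagged(s) for s in clean) / n_records
    for kind in error_kinds:
        corrupted = [inject_error(s, kind, rng, config=config,
                                  constants=constants) for s in clean]
        detect = 100.0 * sum(flagged(s) for s in corrupted) / n_records
        rows[kind] = {"detection_rate_pct": detect,
                      "false_positive_rate_pct": fp, "n": n_records}
    return pd.DataFrame.from_dict(rows, orient="index")
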