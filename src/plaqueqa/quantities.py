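"""Physical constants, unit conversion, and radioactive decay for I-125 plaque QA.

A well-type dose calibrator reads out *apparent activity* in mCi; seed
certificates state *air kerma strength* S_K in U (1 U = 1 uGy m^2 / h).
For I-125 the two are related by the equivalence 1 U = 0.787 mCi, i.e.
1 mCi = 1.270 U.  Certificate strengths refer to the assay date and must be
decayed (or grown, for a measurement that precedes the assay) to the plaque
measurement date before any comparison.

All arithmetic here is carried in full precision; rounding to the worksheet's
printed precision (2 dp for strengths, 3 dp for calibration factors, 1 dp for
percentages) happens only at the presentation layer in :mod:`plaqueqa.records`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

__all__ = [
    "I125_HALF_LIFE_DAYS",
    "U_PER_MCI",
    "MCI_PER_U",
    "PhysicsConstants",
    "parse_date",
    "format_date",
    "elapsed_days",
    "activity_to_air_kerma_strength",
    "air_kerma_strength_to_activity",
    "decay_correct",
]

#: I-125 half-life in days used for all decay corrections.
I125_HALF_LIFE_DAYS = 59.4

#: Air kerma strength (U) per unit apparent activity (mCi) for I-125.
U_PER_MCI = 1.270

#: Apparent activity (mCi) per unit air kerma strength (U) for I-125.
MCI_PER_U = 0.787


@dataclass(frozen=True)
class PhysicsConstants:
    """Nuclide constants for converting and decaying source strengths.

    Parameters
    ----------
    half_life_days
        Radioactive half-life in days (default: I-125, 59.4 d).
    u_per_mci
        Conversion from apparent activity in mCi to air kerma strength in U.
    mci_per_u
        The stated inverse conversion.  ``u_per_mci * mci_per_u`` must agree
        with 1 to within 0.3% (1.270 x 0.787 = 0.99949).
    """

    half_life_days: float = I125_HALF_LIFE_DAYS
    u_per_mci: float = U_PER_MCI
    mci_per_u: float = MCI_PER_U

    def __post_init__(self) -> None:
        if not self.half_life_days > 0:
            raise ValueError(f"half_life_days must be > 0, got {self.half_life_days}")
        if not self.u_per_mci > 0:
            raise ValueError(f"u_per_mci must be > 0, got {self.u_per_mci}")
        if not self.mci_per_u > 0:
            raise ValueError(f"mci_per_u must be > 0, got {self.mci_per_u}")
        product = self.u_per_mci * self.mci_per_u
        if abs(product - 1.0) > 3e-3:
            raise ValueError(
                "u_per_mci and mci_per_u are not inverse to within 0.3%: "
                f"{self.u_per_mci} x {self.mci_per_u} = {product:.5f}"
            )


def parse_date(text: str | dt.date, *, month_first: bool = True) -> dt.date:
    """Parse a calendar date from worksheet text.

    Accepts ISO-8601 (``2011-09-16``) and slash-separated dates.  Slash dates
    are read month-first (``9/16/2011``) by default, matching US worksheet
    convention; pass ``month_first=False`` for day-first.
    """
    if isinstance(text, dt.date):
        return text
    s = str(text).strip()
    if not s:
        raise ValueError("empty date")
    try:
        return dt.date.fromisoformat(s)
    except ValueError:
        pass
    fmt = "%m/%d/%Y" if month_first else "%d/%m/%Y"
    try:
        return dt.datetime.strptime(s, fmt).date()
    except ValueError as exc:
        raise ValueError(f"unparseable date {s!r}") from exc


def format_date(date: dt.date, *, month_first: bool = True) -> str:
    """Render a date the way the worksheet prints it (``9/16/2011``)."""
    if month_first:
        return f"{date.month}/{date.day}/{date.year}"
    return f"{date.day}/{date.month}/{date.year}"


def elapsed_days(from_date: dt.date, to_date: dt.date) -> int:
    """Signed whole-day count ``to_date - from_date``.

    Negative when the measurement precedes the assay, which occurs in practice
    when a plaque is checked a few days before its certificate's assay date.
    """
    return (to_date - from_date).days


def activity_to_air_kerma_strength(
    activity_mci: float,
    constants: PhysicsConstants = PhysicsConstants(),
    *,
    context: str = "",
) -> float:
    """Convert apparent activity (mCi) to air kerma strength (U).

    ``context`` names the record in error messages when validation fails.
    """
    if activity_mci < 0:
        where = f" for {context}" if context else ""
        raise ValueError(f"negative activity {activity_mci} mCi{where}")
    return activity_mci * constants.u_per_mci


def air_kerma_strength_to_activity(
    strength_u: float, constants: PhysicsConstants = PhysicsConstants()
) -> float:
    """Convert air kerma strength (U) to apparent activity (mCi)."""
    if strength_u < 0:
        raise ValueError(f"negative strength {strength_u} U")
    return strength_u * constants.mci_per_u


def decay_correct(
    strength_u: float,
    from_date: dt.date,
    to_date: dt.date,
    constants: PhysicsConstants = PhysicsConstants(),
) -> float:
    """Decay a source strength from one calendar date to another.

    Returns ``strength * 2**(-elapsed_days / half_life)``.  The identity holds
    exactly for zero elapsed days, and strength grows for negative intervals
    (measurement before assay).
    """
    if strength_u < 0:
        raise ValueError(f"negative strength {strength_u} U")
    days = elapsed_days(from_date, to_date)
    return strength_u * 2.0 ** (-days / constants.half_life_days)
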