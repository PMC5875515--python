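"""Plaque record data model and worksheet CSV/HTML readers and writers.

The worksheet mirrors the spreadsheet a physicist keeps for plaque QA: one row
per plaque with the assay certificate (seed count, assay date, total air kerma
strength), the measurement session (date plus either four dose-calibrator
readings at 0/90/180/270 degrees or a single pre-averaged activity), and
optionally the treatment-plan counterpart of the assay for cross-checking.
"""

from __future__ import annotations

import csv
import datetime as dt
import html
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .quantities import elapsed_days, format_date, parse_date

__all__ = [
    "PlaqueType",
    "SeedAssay",
    "AngleReadings",
    "PlaqueRecord",
    "Diagnostic",
    "Worksheet",
    "WorksheetError",
    "DEFAULT_PLAQUE_TYPES",
    "DEFAULT_SCHEMA",
    "read_worksheet",
    "write_worksheet",
]


class WorksheetError(ValueError):
    """File-level failure reading or writing a worksheet."""


@dataclass(frozen=True)
class PlaqueType:
    """An eye-plaque model and its seed capacity.

    ``label`` follows clinical naming: COMS plaques by diameter in mm with an
    ``N`` suffix for notched variants, and the Eye Physics EP917.  ``capacity``
    is the number of seed positions; the EP917 has 17 collimating slots, and
    fully loaded COMS plaques hold from 5 seeds (10 mm) to 24 (22 mm).
    """

    label: str
    capacity: int

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError(f"capacity must be >= 1, got {self.capacity}")


def _default_types() -> dict[str, PlaqueType]:
    # COMS capacities are editable defaults spanning the 5-24 seed range of
    # fully loaded 10-22 mm plaques; notched variants share the base capacity.
    coms = {10: 5, 12: 8, 14: 13, 16: 17, 18: 21, 20: 24, 22: 24}
    types: dict[str, PlaqueType] = {}
    for diameter, capacity in coms.items():
        types[f"COMS{diameter}"] = PlaqueType(f"COMS{diameter}", capacity)
        if diameter != 22:
            types[f"COMS{diameter}N"] = PlaqueType(f"COMS{diameter}N", capacity)
    types["EP917"] = PlaqueType("EP917", 17)
    return types


#: Known plaque types keyed by label.  Copy and edit to change capacities.
DEFAULT_PLAQUE_TYPES: dict[str, PlaqueType] = _default_types()


@dataclass(frozen=True)
class SeedAssay:
    """A seed lot's certificate: seed count, assay date, total strength in U."""

    n_seeds: int
    assay_date: dt.date
    total_strength_u: float

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError(f"n_seeds must be >= 1, got {self.n_seeds}")
        if not self.total_strength_u > 0:
            raise ValueError(
                f"total_strength_u must be > 0, got {self.total_strength_u}"
            )


@dataclass(frozen=True)
class AngleReadings:
    """Four dose-calibrator activities (mCi) at 0, 90, 180 and 270 degrees."""

    readings_mci: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.readings_mci) != 4:
            raise ValueError(
                f"expected exactly four readings, got {len(self.readings_mci)}"
            )
        for r in self.readings_mci:
            if r < 0:
                raise ValueError(f"negative reading {r} mCi")


@dataclass
class PlaqueRecord:
    """One plaque's assay certificate, measurement session, and optional plan.

    Exactly one of ``readings`` (four raw angles) or ``activity_mci`` (the
    pre-averaged value, as archived worksheets store) must be present;
    ``provenance`` records which ("four_angle" or "pre_averaged").
    """

    plaque_id: str
    plaque_type: PlaqueType
    assay: SeedAssay
    measurement_date: dt.date
    readings: AngleReadings | None = None
    activity_mci: float | None = None
    plan: SeedAssay | None = None
    source_row: int | None = None

    def __post_init__(self) -> None:
        if (self.readings is None) == (self.activity_mci is None):
            raise ValueError(
                f"record {self.plaque_id}: provide either four angle readings "
                "or one pre-averaged activity, not both or neither"
            )
        if self.activity_mci is not None and self.activity_mci < 0:
            raise ValueError(
                f"record {self.plaque_id}: negative activity {self.activity_mci}"
            )

    @property
    def provenance(self) -> str:
        return "four_angle" if self.readings is not None else "pre_averaged"


@dataclass(frozen=True)
class Diagnostic:
    """A per-row validation message; every diagnostic names a row and column."""

    row: int
    column: str
    message: str
    level: str = "error"  # "error" drops the row, "warning" keeps it

    def __str__(self) -> str:
        return f"row {self.row}, column {self.column}: {self.message} [{self.level}]"


class Worksheet(list):
    """A list of :class:`PlaqueRecord` carrying per-row diagnostics."""

    def __init__(self, records: Iterable[PlaqueRecord] = (),
                 diagnostics: Sequence[Diagnostic] = ()) -> None:
        super().__init__(records)
        self.diagnostics: list[Diagnostic] = list(diagnostics)

    @property
    def errors(self) -> list[Diagnostic]:
        return [d for d in self.diagnostics if d.level == "error"]

    @property
    def warnings(self) -> list[Diagnostic]:
        return [d for d in self.diagnostics if d.level == "warning"]


# Canonical column names; a schema config maps these onto the file's headers.
DEFAULT_SCHEMA: dict[str, str] = {
    "plaque_id": "plaque_id",
    "plaque_type": "plaque_type",
    "n_seeds": "n_seeds",
    "assay_date": "assay_date",
    "assay_strength_u": "assay_strength_u",
    "measurement_date": "measurement_date",
    "reading_0_mci": "reading_0_mci",
    "reading_90_mci": "reading_90_mci",
    "reading_180_mci": "reading_180_mci",
    "reading_270_mci": "reading_270_mci",
    "activity_mci": "activity_mci",
    "plan_date": "plan_date",
    "plan_strength_u": "plan_strength_u",
}

_REQUIRED = ("plaque_id", "plaque_type", "n_seeds", "assay_date",
             "assay_strength_u", "measurement_date")
_READING_COLS = ("reading_0_mci", "reading_90_mci", "reading_180_mci",
                 "reading_270_mci")


def _get(row: Mapping[str, str], schema: Mapping[str, str], key: str) -> str:
    return (row.get(schema.get(key, key), "") or "").strip()


def read_worksheet(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    plaque_types: Mapping[str, PlaqueType] = DEFAULT_PLAQUE_TYPES,
    month_first: bool = True,
    date_window_days: int = 365,
) -> Worksheet:
    """Read a worksheet CSV into validated :class:`PlaqueRecord` objects.

    Invalid rows are dropped with an error diagnostic naming the row and
    column; soft violations (seed count above the type's capacity, assay and
    measurement dates more than ``date_window_days`` apart) keep the row and
    add a warning.  An empty file raises :class:`WorksheetError`.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise WorksheetError(f"{path}: no records (empty file)")
        header = set(reader.fieldnames)
        missing = [schema[k] for k in _REQUIRED if schema[k] not in header]
        if missing:
            raise WorksheetError(f"{path}: missing required columns {missing}")
        rows = list(reader)
    if not rows:
        raise WorksheetError(f"{path}: no records")

    sheet = Worksheet()
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        record = _parse_row(row, i, schema, plaque_types, month_first,
                            date_window_days, sheet.diagnostics)
        if record is not None:
            sheet.append(record)
    return sheet


def _parse_row(row, rownum, schema, plaque_types, month_first,
               date_window_days, diagnostics) -> PlaqueRecord | None:
    def fail(key: str, message: str) -> None:
        diagnostics.append(Diagnostic(rownum, schema.get(key, key), message))

    def warn(key: str, message: str) -> None:
        diagnostics.append(Diagnostic(rownum, schema.get(key, key), message,
                                      level="warning"))

    plaque_id = _get(row, schema, "plaque_id")
    if not plaque_id:
        fail("plaque_id", "missing plaque id")
        return None

    label = _get(row, schema, "plaque_type")
    ptype = plaque_types.get(label)
    if ptype is None:
        fail("plaque_type", f"unknown plaque type {label!r} (plaque {plaque_id})")
        return None

    try:
        n_seeds = int(_get(row, schema, "n_seeds"))
        strength = float(_get(row, schema, "assay_strength_u"))
    except ValueError as exc:
        fail("n_seeds", f"unparseable number for plaque {plaque_id}: {exc}")
        return None
    try:
        assay_date = parse_date(_get(row, schema, "assay_date"),
                                month_first=month_first)
        meas_date = parse_date(_get(row, schema, "measurement_date"),
                               month_first=month_first)
    except ValueError as exc:
        fail("assay_date", f"plaque {plaque_id}: {exc}")
        return None

    readings = None
    activity = None
    raw = [_get(row, schema, c) for c in _READING_COLS]
    if all(raw):
        try:
            readings = AngleReadings(tuple(float(v) for v in raw))
        except ValueError as exc:
            fail("reading_0_mci", f"plaque {plaque_id}: {exc}")
            return None
    else:
        text = _get(row, schema, "activity_mci")
        if not text:
            fail("activity_mci",
                 f"plaque {plaque_id}: need four angle readings or an activity")
            return None
        try:
            activity = float(text)
        except ValueError:
            fail("activity_mci", f"plaque {plaque_id}: unparseable activity {text!r}")
            return None

    plan = None
    plan_strength = _get(row, schema, "plan_strength_u")
    if plan_strength:
        try:
            plan_date_text = _get(row, schema, "plan_date") or \
                _get(row, schema, "assay_date")
            plan = SeedAssay(n_seeds, parse_date(plan_date_text,
                                                 month_first=month_first),
                             float(plan_strength))
        except ValueError as exc:
            fail("plan_strength_u", f"plaque {plaque_id}: {exc}")
            return None

    try:
        record = PlaqueRecord(
            plaque_id=plaque_id,
            plaque_type=ptype,
            assay=SeedAssay(n_seeds, assay_date, strength),
            measurement_date=meas_date,
            readings=readings,
            activity_mci=activity,
            plan=plan,
            source_row=rownum,
        )
    except ValueError as exc:
        fail("plaque_id", str(exc))
        return None

    if n_seeds > ptype.capacity:
        warn("n_seeds",
             f"plaque {plaque_id}: {n_seeds} seeds exceeds {label} "
             f"capacity {ptype.capacity}")
    if abs(elapsed_days(assay_date, meas_date)) > date_window_days:
        warn("measurement_date",
             f"plaque {plaque_id}: measurement more than {date_window_days} "
             "days from assay")
    return record


# ---------------------------------------------------------------------------
# Writing

_OUTPUT_COLUMNS = [
    "plaque_id", "plaque_type", "n_seeds", "assay_date", "assay_strength_u",
    "measurement_date", "activity_mci", "measured_strength_u",
    "decayed_strength_u", "cal_factor", "deviation_pct", "flags", "flagged",
]


def _fmt(value, digits: int | None, presentation: bool) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if presentation and digits is not None:
        return f"{value:.{digits}f}"
    return repr(float(value))


def worksheet_rows(
    records: Sequence[PlaqueRecord],
    results: Sequence | None = None,
    *,
    presentation: bool = False,
    month_first: bool = True,
) -> list[dict[str, str]]:
    """Render records (and optional :class:`CalibrationResult`s) as rows.

    With ``presentation=True`` values are rounded the way the worksheet prints
    them: strengths to 2 dp, calibration factors to 3 dp, percentages to 1 dp.
    Otherwise full-precision ``repr`` values are written so that a read/write
    cycle round-trips bit-identically.
    """
    if results is not None and len(results) != len(records):
        raise ValueError(
            f"{len(results)} results for {len(records)} records"
        )
    rows = []
    for i, record in enumerate(records):
        activity = record.activity_mci
        if record.readings is not None and not presentation:
            activity = None
        row = {
            "plaque_id": record.plaque_id,
            "plaque_type": record.plaque_type.label,
            "n_seeds": str(record.assay.n_seeds),
            "assay_date": format_date(record.assay.assay_date,
                                      month_first=month_first),
            "assay_strength_u": _fmt(record.assay.total_strength_u, 2,
                                     presentation),
            "measurement_date": format_date(record.measurement_date,
                                            month_first=month_first),
            "activity_mci": _fmt(activity, 2, presentation),
            "measured_strength_u": "",
            "decayed_strength_u": "",
            "cal_factor": "",
            "deviation_pct": "",
            "flags": "",
            "flagged": "",
        }
        if record.readings is not None:
            for col, val in zip(_READING_COLS, record.readings.readings_mci):
                row[col] = _fmt(val, 2, presentation)
        if record.plan is not None:
            row["plan_date"] = format_date(record.plan.assay_date,
                                           month_first=month_first)
            row["plan_strength_u"] = _fmt(record.plan.total_strength_u, 2,
                                          presentation)
        if results is not None:
            result = results[i]
            row["activity_mci"] = _fmt(result.mean_activity_mci, 2, presentation)
            row["measured_strength_u"] = _fmt(result.measured_strength_u, 2,
                                              presentation)
            row["decayed_strength_u"] = _fmt(result.decayed_assay_strength_u, 2,
                                             presentation)
            row["cal_factor"] = _fmt(result.cal_factor, 3, presentation)
            row["deviation_pct"] = _fmt(result.deviation_pct, 1, presentation)
            row["flags"] = ";".join(sorted(f.name for f in result.flags))
            row["flagged"] = "*" if result.flags else ""
        rows.append(row)
    return rows


def write_worksheet(
    records: Sequence[PlaqueRecord],
    results: Sequence | None,
    path: str | Path,
    *,
    presentation: bool = False,
    fmt: str | None = None,
    month_first: bool = True,
) -> Path:
    """Write records (and optional results) to CSV or HTML.

    Columns follow the worksheet order (assay data, measured data, comparison);
    rows whose result carries any flag get a ``*`` marker in the ``flagged``
    column (highlighted red in HTML output, mirroring the spreadsheet).
    ``fmt`` defaults from the file extension ("csv" unless ".html").
    """
    path = Path(path)
    if fmt is None:
        fmt = "html" if path.suffix.lower() in (".html", ".htm") else "csv"
    rows = worksheet_rows(records, results, presentation=presentation,
                          month_first=month_first)
    columns = list(_OUTPUT_COLUMNS)
    extras = sorted({k for row in rows for k in row} - set(columns))
    columns += extras
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns, restval="")
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "html":
        path.write_text(_render_html(columns, rows), encoding="utf-8")
    else:
        raise ValueError(f"unknown worksheet format {fmt!r}")
    return path


def _render_html(columns: Sequence[str], rows: Sequence[Mapping[str, str]]) -> str:
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 6px}tr.flagged{color:#b00;font-weight:bold}</style>",
        "</head><body><table><thead><tr>",
    ]
    parts += [f"<th>{html.escape(c)}</th>" for c in columns]
    parts.append("</tr></thead><tbody>")
    for row in rows:
        cls = " class='flagged'" if row.get("flagged") else ""
        parts.append(f"<tr{cls}>")
        parts += [f"<td>{html.escape(str(row.get(c, '')))}</td>" for c in columns]
        parts.append("</tr>")
    parts.append("</tbody></table></body></html>")
    return "".join(parts)
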