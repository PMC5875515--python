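"""The QA pipeline: configuration, logging, and rendered reports.

``run_qa`` ties the whole worksheet procedure together: read the records,
evaluate each against its plaque type's reference calibration factor, write
the evaluated worksheet (CSV and optionally HTML), the per-type statistics,
the deviation histogram, and a flag summary.  The exit status is nonzero
exactly when any plaque raises an ACTION_LIMIT or CROSS_CHECK flag, so the
tool can gate a clinical workflow from a shell script.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .aggregation import GroupStats, deviation_histogram, group_statistics
from .calibration import CalibrationResult, Flag, QALimits, evaluate_record
from .quantities import PhysicsConstants
from .records import Worksheet, read_worksheet, write_worksheet

__all__ = [
    "RunConfig",
    "RunResult",
    "ConstancyEntry",
    "constancy_log",
    "load_config",
    "read_type_factors",
    "write_type_factors",
    "run_qa",
]

logger = logging.getLogger("plaqueqa")


def setup_logging(verbosity: int = 0, log_file: str | Path | None = None) -> None:
    """Route log output to stderr and optionally a run log file."""
    level = logging.WARNING - 10 * min(verbosity, 2)
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(levelname)s %(name)s: %(message)s")


@dataclass
class RunConfig:
    """Declarative run configuration (constants, limits, schema, outputs)."""

    constants: PhysicsConstants = field(default_factory=PhysicsConstants)
    limits: QALimits = field(default_factory=QALimits)
    schema: dict[str, str] = field(default_factory=dict)
    month_first: bool = True
    histogram_bin_width_pct: float = 1.0
    output_dir: Path = Path(".")
    html_report: bool = False
    verbosity: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a flat YAML file.

    Recognized keys: half_life_days, u_per_mci, mci_per_u,
    reading_spread_limit, action_limit, cross_check_limit, spread_metric,
    schema (mapping), month_first, histogram_bin_width_pct, output_dir,
    html_report.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    const_keys = {"half_life_days", "u_per_mci", "mci_per_u"}
    limit_keys = {"reading_spread_limit", "action_limit", "cross_check_limit",
                  "spread_metric"}
    constants = PhysicsConstants(**{k: raw[k] for k in const_keys if k in raw})
    limits = QALimits(**{k: raw[k] for k in limit_keys if k in raw})
    return RunConfig(
        constants=constants,
        limits=limits,
        schema=dict(raw.get("schema", {})),
        month_first=bool(raw.get("month_first", True)),
        histogram_bin_width_pct=float(raw.get("histogram_bin_width_pct", 1.0)),
        output_dir=Path(raw.get("output_dir", ".")),
        html_report=bool(raw.get("html_report", False)),
    )


def read_type_factors(path: str | Path) -> dict[str, float]:
    """Read per-type reference calibration factors (plaque_type, mean_factor)."""
    factors: dict[str, float] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            factors[row["plaque_type"].strip()] = float(row["mean_factor"])
    if not factors:
        raise ValueError(f"{path}: no reference factors")
    return factors


def write_type_factors(stats: Sequence[GroupStats], path: str | Path) -> Path:
    """Write per-type statistics in the format ``read_type_factors`` accepts."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plaque_type", "n", "mean_factor", "sd_factor",
                         "cv_pct"])
        for g in stats:
            writer.writerow([
                g.plaque_type, g.n, repr(g.mean_factor),
                "" if g.sd_factor is None else repr(g.sd_factor),
                "" if g.cv_pct is None else repr(g.cv_pct),
            ])
    return path


@dataclass
class RunResult:
    """Everything ``run_qa`` produced."""

    records: Worksheet
    results: list[CalibrationResult]
    group_stats: list[GroupStats]
    flagged: list[CalibrationResult]
    output_paths: dict[str, Path]
    exit_status: int


def run_qa(
    worksheet_path: str | Path,
    type_factors: Mapping[str, float] | str | Path | None = None,
    config: RunConfig = RunConfig(),
) -> RunResult:
    """Run the full worksheet QA procedure.

    ``type_factors`` maps plaque-type labels to the reference calibration
    factor each record's deviation is measured against; a path to a factors
    CSV is also accepted.  When absent for a type (or entirely), that type's
    mean over the *current* worksheet is used, and the provenance is logged —
    deviations are then internal-consistency checks, not comparisons against
    an established reference.

    Outputs an evaluated worksheet (presentation precision), per-type group
    statistics, deviation-histogram counts and a flag summary under
    ``config.output_dir``.  ``exit_status`` is 1 iff any ACTION_LIMIT or
    CROSS_CHECK flag was raised, else 0.
    """
    if isinstance(type_factors, (str, Path)):
        type_factors = read_type_factors(type_factors)

    records = read_worksheet(worksheet_path, config.schema or None,
                             month_first=config.month_first)
    for diag in records.diagnostics:
        (logger.error if diag.level == "error" else logger.warning)("%s", diag)
    if not records:
        raise ValueError(f"{worksheet_path}: no valid records")

    # First pass without a group mean to obtain each record's factor.
    first_pass = [evaluate_record(r, None, config.constants, config.limits)
                  for r in records]
    by_type: dict[str, list[float]] = {}
    for record, result in zip(records, first_pass):
        by_type.setdefault(record.plaque_type.label, []).append(result.cal_factor)
    group_stats = [group_statistics(fs, label)
                   for label, fs in sorted(by_type.items())]

    means: dict[str, float] = {g.plaque_type: g.mean_factor for g in group_stats}
    if type_factors:
        means.update(type_factors)
    for label in sorted(by_type):
        if not type_factors or label not in type_factors:
            logger.warning(
                "no reference factor for %s; using this worksheet's own mean "
                "%.4f (internal-consistency check only)", label, means[label])

    results = [evaluate_record(r, means[r.plaque_type.label], config.constants,
                               config.limits)
               for r in records]

    flagged = [res for res in results
               if res.flags & {Flag.ACTION_LIMIT, Flag.CROSS_CHECK}]
    for res in results:
        for flag in sorted(res.flags, key=lambda f: f.name):
            logger.warning("plaque %s: %s (deviation %s, spread %s)",
                           res.plaque_id, flag.name,
                           "n/a" if res.deviation_pct is None
                           else f"{res.deviation_pct:+.1f}%",
                           "n/a" if res.spread_pct is None
                           else f"{res.spread_pct:.1f}%")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["worksheet"] = write_worksheet(records, results,
                                         out / "evaluated_worksheet.csv",
                                         presentation=True,
                                         month_first=config.month_first)
    if config.html_report:
        paths["worksheet_html"] = write_worksheet(
            records, results, out / "evaluated_worksheet.html",
            presentation=True, month_first=config.month_first)
    paths["factors"] = write_type_factors(group_stats, out / "type_factors.csv")

    deviations = [r.deviation_pct for r in results if r.deviation_pct is not None]
    edges, counts = deviation_histogram(deviations,
                                        config.histogram_bin_width_pct)
    paths["histogram"] = out / "deviation_histogram.csv"
    with paths["histogram"].open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_lo_pct", "bin_hi_pct", "count"])
        for lo, hi, count in zip(edges[:-1], edges[1:], counts):
            writer.writerow([f"{lo:g}", f"{hi:g}", int(count)])

    paths["flags"] = out / "flag_summary.csv"
    with paths["flags"].open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plaque_id", "flag", "deviation_pct", "spread_pct"])
        for res in results:
            for flag in sorted(res.flags, key=lambda f: f.name):
                writer.writerow([
                    res.plaque_id, flag.name,
                    "" if res.deviation_pct is None
                    else f"{res.deviation_pct:.1f}",
                    "" if res.spread_pct is None else f"{res.spread_pct:.1f}",
                ])

    return RunResult(records=records, results=results, group_stats=group_stats,
                     flagged=flagged, output_paths=paths,
                     exit_status=1 if flagged else 0)


@dataclass(frozen=True)
class ConstancyEntry:
    """One dose-calibrator constancy check against the long-lived source."""

    reading: float
    expected: float
    diff_pct: float
    passed: bool


def constancy_log(
    check_source_reading: float,
    expected: float,
    tolerance_pct: float = 5.0,
) -> ConstancyEntry:
    """Record a constancy check of the dose calibrator.

    The calibrator is verified against a long-lived check source (typically a
    Cs-137 vial) before each plaque measurement; the entry passes when the
    reading is within ``tolerance_pct`` of the expected value.  The entry is
    informational — a failure is logged but does not block evaluation.
    """
    if not expected > 0:
        raise ValueError(f"expected reading must be > 0, got {expected}")
    diff = 100.0 * (check_source_reading / expected - 1.0)
    passed = abs(diff) <= tolerance_pct
    (logger.info if passed else logger.warning)(
        "constancy check: reading %.4g vs expected %.4g (%+.1f%%) -> %s",
        check_source_reading, expected, diff, "pass" if passed else "FAIL")
    return ConstancyEntry(check_source_reading, expected, diff, passed)
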