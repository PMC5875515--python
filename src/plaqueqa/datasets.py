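"""Bundled example measurement data for eye-plaque QA.

Three small datasets ship with the package so the full pipeline can be run
and checked without access to a dose calibrator:

* a ten-plaque EP917 verification worksheet (assay certificates plus measured
  mean activities) from a clinical QA program, with the program's established
  EP917 mean calibration factor and its coefficient of variation;
* single-seed placement activities for all 17 positions of three fully loaded
  EP917 plaques, for the seed-contribution analysis;
* per-type calibration-factor statistics for eleven COMS plaque types.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

from .aggregation import GroupStats
from .records import DEFAULT_PLAQUE_TYPES, PlaqueRecord, SeedAssay, Worksheet
from .seed_contribution import SeedContributionTable

__all__ = [
    "EP917_MEAN_CAL_FACTOR",
    "EP917_CV_PCT",
    "ep917_worksheet",
    "ep917_seed_activities",
    "ep917_seed_contribution_table",
    "coms_group_stats",
]

#: Established mean EP917 calibration factor (56-plaque clinical cohort).
EP917_MEAN_CAL_FACTOR = 0.353

#: Coefficient of variation of the EP917 cohort's calibration factors, percent.
EP917_CV_PCT = 3.29

# (plaque_id, n_seeds, assay date, assay strength U, measurement date,
#  mean measured activity mCi)
_WORKSHEET = [
    ("1", 17, dt.date(2011, 9, 16), 115.60, dt.date(2011, 10, 23), 20.30),
    ("2", 17, dt.date(2011, 12, 2), 51.19, dt.date(2011, 12, 8), 14.05),
    ("3", 15, dt.date(2011, 12, 2), 40.62, dt.date(2011, 12, 8), 10.58),
    ("4", 15, dt.date(2011, 12, 2), 36.86, dt.date(2011, 12, 8), 9.24),
    ("5", 6, dt.date(2011, 12, 2), 43.18, dt.date(2011, 12, 8), 11.19),
    ("6", 17, dt.date(2012, 1, 6), 65.35, dt.date(2012, 1, 10), 16.90),
    ("7", 17, dt.date(2012, 1, 20), 70.94, dt.date(2012, 1, 23), 18.21),
    ("8", 17, dt.date(2012, 3, 9), 59.13, dt.date(2012, 3, 8), 17.23),
    ("9", 17, dt.date(2012, 3, 23), 53.55, dt.date(2012, 3, 22), 15.57),
    ("10", 17, dt.date(2012, 4, 2), 47.52, dt.date(2012, 3, 30), 13.10),
]


def ep917_worksheet() -> Worksheet:
    """The ten-plaque EP917 example worksheet as validated records.

    Plaques 8-10 were measured a few days *before* their assay dates, so the
    decay correction runs backwards for them.  Activities are stored
    pre-averaged, as the archived worksheet keeps only the four-angle mean.
    """
    ep917 = DEFAULT_PLAQUE_TYPES["EP917"]
    records = [
        PlaqueRecord(
            plaque_id=pid,
            plaque_type=ep917,
            assay=SeedAssay(n_seeds, assay_date, strength),
            measurement_date=meas_date,
            activity_mci=activity,
        )
        for pid, n_seeds, assay_date, strength, meas_date, activity in _WORKSHEET
    ]
    return Worksheet(records)


# Single-seed activities (mCi) by position 1..17 for three EP917 plaques.
_SEED_ACTIVITIES = {
    "plaque_1": [1.340, 1.590, 1.540, 1.520, 1.270, 1.300, 1.240, 1.210,
                 1.290, 1.310, 1.220, 1.410, 1.400, 1.510, 1.610, 1.450,
                 1.600],
    "plaque_2": [0.813, 0.754, 0.784, 0.628, 0.878, 0.820, 0.790, 0.835,
                 0.920, 0.770, 0.765, 0.708, 0.785, 0.840, 0.780, 0.803,
                 0.780],
    "plaque_3": [0.925, 1.065, 0.920, 1.125, 1.150, 0.825, 1.000, 1.013,
                 0.885, 0.905, 1.115, 0.765, 1.120, 0.943, 0.970, 1.045,
                 1.130],
}


def ep917_seed_activities() -> pd.DataFrame:
    """Single-seed placement activities (mCi), positions x plaques."""
    return pd.DataFrame(_SEED_ACTIVITIES,
                        index=pd.RangeIndex(1, 18, name="position"))


def ep917_seed_contribution_table() -> SeedContributionTable:
    """The three-plaque placement-method contribution table."""
    return SeedContributionTable.from_placements(_SEED_ACTIVITIES)


# (plaque type, mean factor, sd, cv %, number of plaques)
_COMS_GROUPS = [
    ("COMS10", 0.264, 0.007, 2.6, 8),
    ("COMS12", 0.256, 0.007, 2.6, 6),
    ("COMS12N", 0.252, 0.006, 2.4, 6),
    ("COMS14", 0.264, 0.008, 3.2, 5),
    ("COMS14N", 0.254, 0.010, 4.1, 9),
    ("COMS16", 0.262, 0.010, 3.8, 2),
    ("COMS16N", 0.245, 0.007, 2.7, 4),
    ("COMS18", 0.250, 0.004, 1.5, 3),
    ("COMS18N", 0.254, 0.008, 3.3, 2),
    ("COMS20", 0.234, 0.004, 1.9, 11),
    ("COMS20N", 0.243, 0.005, 2.0, 3),
]


def coms_group_stats() -> list[GroupStats]:
    """Per-type calibration-factor statistics for the eleven COMS types."""
    return [
        GroupStats(plaque_type=t, n=n, mean_factor=mean, sd_factor=sd,
                   cv_pct=cv)
        for t, mean, sd, cv, n in _COMS_GROUPS
    ]
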