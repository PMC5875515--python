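import csv

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from plaqueqa import datasets  # noqa: E402
from plaqueqa.quantities import format_date  # noqa: E402


# The ten-plaque EP917 worked example: printed worksheet values
# (plaque_id, measured strength U, decayed strength U, cal factor,
#  deviation % vs the 0.353 cohort mean, flagged)
WORKED_EXAMPLE = [
    ("1", 25.78, 75.07, 0.343, -2.8, False),
    ("2", 17.84, 47.73, 0.374, 5.9, True),
    ("3", 13.43, 37.87, 0.355, 0.4, False),
    ("4", 11.73, 34.37, 0.341, -3.3, False),
    ("5", 14.21, 40.26, 0.353, 0.0, False),
    ("6", 21.46, 62.37, 0.344, -2.6, False),
    ("7", 23.12, 68.50, 0.338, -4.4, False),
    ("8", 21.88, 59.82, 0.366, 3.6, False),
    ("9", 19.78, 54.18, 0.365, 3.4, False),
    ("10", 16.64, 49.21, 0.338, -4.3, False),
]


@pytest.fixture
def worksheet():
    return datasets.ep917_worksheet()


@pytest.fixture
def worksheet_csv(tmp_path, worksheet):
    """The worked-example worksheet written out as a CSV file."""
    path = tmp_path / "worksheet.csv"
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plaque_id", "plaque_type", "n_seeds", "assay_date",
                         "assay_strength_u", "measurement_date",
                         "activity_mci"])
        for r in worksheet:
            writer.writerow([
                r.plaque_id, r.plaque_type.label, r.assay.n_seeds,
                format_date(r.assay.assay_date),
                r.assay.total_strength_u,
                format_date(r.measurement_date), r.activity_mci,
            ])
    return path


@pytest.fixture
def factors_csv(tmp_path):
    """Reference-factor file holding the established EP917 cohort mean."""
    path = tmp_path / "factors.csv"
    path.write_text("plaque_type,mean_factor\n"
                    f"EP917,{datasets.EP917_MEAN_CAL_FACTOR}\n")
    return path
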