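import datetime as dt

import pytest

from plaqueqa.calibration import evaluate_record
from plaqueqa.records import (
    DEFAULT_PLAQUE_TYPES,
    AngleReadings,
    PlaqueRecord,
    SeedAssay,
    WorksheetError,
    read_worksheet,
    write_worksheet,
)

EP917 = DEFAULT_PLAQUE_TYPES["EP917"]


def make_record(**overrides):
    fields = dict(
        plaque_id="A",
        plaque_type=EP917,
        assay=SeedAssay(17, dt.date(2011, 9, 16), 115.60),
        measurement_date=dt.date(2011, 10, 23),
        readings=AngleReadings((20.1, 20.3, 20.4, 20.4)),
    )
    fields.update(overrides)
    return PlaqueRecord(**fields)


class TestModel:
    def test_readings_and_activity_are_mutually_exclusive(self):
        with pytest.raises(ValueError, match="not both"):
            make_record(activity_mci=20.3)
        with pytest.raises(ValueError, match="not both"):
            make_record(readings=None)

    def test_provenance_tracks_storage_form(self):
        assert make_record().provenance == "four_angle"
        pre = make_record(readings=None, activity_mci=20.3)
        assert pre.provenance == "pre_averaged"

    def test_angle_readings_require_exactly_four(self):
        with pytest.raises(ValueError, match="four"):
            AngleReadings((1.0, 2.0, 3.0))

    def test_assay_validation(self):
        with pytest.raises(ValueError):
            SeedAssay(0, dt.date(2011, 1, 1), 10.0)
        with pytest.raises(ValueError):
            SeedAssay(17, dt.date(2011, 1, 1), 0.0)


class TestReadWrite:
    def test_round_trip_preserves_all_fields(self, tmp_path):
        records = [
            make_record(),
            make_record(plaque_id="B", readings=None, activity_mci=14.05,
                        plan=SeedAssay(17, dt.date(2011, 12, 1), 51.0)),
        ]
        path = tmp_path / "ws.csv"
        write_worksheet(records, None, path)
        back = read_worksheet(path)
        assert not back.diagnostics
        assert [r.plaque_id for r in back] == ["A", "B"]
        for orig, rt in zip(records, back):
            assert rt.plaque_type == orig.plaque_type
            assert rt.assay == orig.assay
            assert rt.measurement_date == orig.measurement_date
            assert rt.readings == orig.readings
            assert rt.activity_mci == orig.activity_mci
            assert rt.plan == orig.plan

    def test_worked_example_csv_reads_ten_valid_records(self, worksheet_csv):
        sheet = read_worksheet(worksheet_csv)
        assert len(sheet) == 10
        assert not sheet.errors

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(WorksheetError, match="no records"):
            read_worksheet(path)
        path.write_text("plaque_id,plaque_type,n_seeds,assay_date,"
                        "assay_strength_u,measurement_date\n")
        with pytest.raises(WorksheetError, match="no records"):
            read_worksheet(path)

    def test_missing_required_column_is_file_level(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plaque_id,n_seeds\n1,17\n")
        with pytest.raises(WorksheetError, match="missing required columns"):
            read_worksheet(path)

    @pytest.mark.parametrize("row, column", [
        ("1,NOSUCH,17,9/16/2011,115.6,10/23/2011,20.3", "plaque_type"),
        ("1,EP917,17,9/99/2011,115.6,10/23/2011,20.3", "assay_date"),
        ("1,EP917,seventeen,9/16/2011,115.6,10/23/2011,20.3", "n_seeds"),
        ("1,EP917,17,9/16/2011,115.6,10/23/2011,", "activity_mci"),
    ])
    def test_bad_rows_get_row_and_column_diagnostics(self, tmp_path, row,
                                                     column):
        path = tmp_path / "ws.csv"
        path.write_text(
            "plaque_id,plaque_type,n_seeds,assay_date,assay_strength_u,"
            f"measurement_date,activity_mci\n{row}\n"
            "2,EP917,17,9/16/2011,115.6,10/23/2011,20.3\n")
        sheet = read_worksheet(path)
        assert len(sheet) == 1  # the bad row is dropped, the good one kept
        assert len(sheet.errors) == 1
        diag = sheet.errors[0]
        assert diag.row == 2
        assert diag.column == column

    def test_seed_count_above_capacity_warns_but_keeps_row(self, tmp_path):
        path = tmp_path / "ws.csv"
        path.write_text(
            "plaque_id,plaque_type,n_seeds,assay_date,assay_strength_u,"
            "measurement_date,activity_mci\n"
            "1,EP917,18,9/16/2011,115.6,10/23/2011,20.3\n")
        sheet = read_worksheet(path)
        assert len(sheet) == 1
        assert len(sheet.warnings) == 1
        assert "capacity 17" in sheet.warnings[0].message

    def test_distant_measurement_date_warns(self, tmp_path):
        path = tmp_path / "ws.csv"
        path.write_text(
            "plaque_id,plaque_type,n_seeds,assay_date,assay_strength_u,"
            "measurement_date,activity_mci\n"
            "1,EP917,17,9/16/2011,115.6,10/23/2013,20.3\n")
        sheet = read_worksheet(path)
        assert len(sheet) == 1
        assert any("days from assay" in w.message for w in sheet.warnings)

    def test_schema_mapping_renames_columns(self, tmp_path):
        path = tmp_path / "ws.csv"
        path.write_text("ID,Type,Seeds,Assayed,SK,Measured,Act\n"
                        "1,EP917,17,9/16/2011,115.6,10/23/2011,20.3\n")
        schema = {"plaque_id": "ID", "plaque_type": "Type", "n_seeds": "Seeds",
                  "assay_date": "Assayed", "assay_strength_u": "SK",
                  "measurement_date": "Measured", "activity_mci": "Act"}
        sheet = read_worksheet(path, schema)
        assert len(sheet) == 1 and not sheet.diagnostics


class TestPresentation:
    def test_result_length_mismatch_rejected(self, tmp_path, worksheet):
        with pytest.raises(ValueError, match="results"):
            write_worksheet(list(worksheet), [], tmp_path / "out.csv")

    def test_presentation_rounds_like_the_printed_worksheet(
            self, tmp_path, worksheet):
        results = [evaluate_record(r, 0.353) for r in worksheet]
        path = write_worksheet(list(worksheet), results, tmp_path / "out.csv",
                               presentation=True)
        lines = path.read_text().splitlines()
        header = lines[0].split(",")
        cf = header.index("cal_factor")
        flagged = header.index("flagged")
        first, last = lines[1].split(","), lines[-1].split(",")
        assert first[cf] == "0.343"
        assert last[cf] == "0.338"
        # the one plaque past the action limit carries the marker
        markers = [line.split(",")[flagged] for line in lines[1:]]
        assert markers == ["", "*", "", "", "", "", "", "", "", ""]

    def test_html_report_highlights_flagged_rows(self, tmp_path, worksheet):
        results = [evaluate_record(r, 0.353) for r in worksheet]
        path = write_worksheet(list(worksheet), results,
                               tmp_path / "out.html", presentation=True)
        text = path.read_text()
        assert text.count("class='flagged'") == 1
        assert "0.374" in text

    def test_empty_record_list_writes_header_only(self, tmp_path):
        path = write_worksheet([], None, tmp_path / "out.csv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("plaque_id,")
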