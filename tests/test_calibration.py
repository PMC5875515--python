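import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from plaqueqa.calibration import (
    Flag,
    QALimits,
    average_readings,
    calibration_factor,
    cross_check,
    deviation_from_mean,
    evaluate_record,
)
from plaqueqa.quantities import PhysicsConstants
from plaqueqa.records import (
    DEFAULT_PLAQUE_TYPES,
    AngleReadings,
    PlaqueRecord,
    SeedAssay,
)

LIMITS = QALimits()


class TestAverageReadings:
    @pytest.mark.parametrize("readings, mean, spread, ok", [
        ((20.30, 20.30, 20.30, 20.30), 20.30, 0.0, True),
        ((20.0, 20.4, 20.2, 20.6), 20.30, 2.956, True),
        ((19.0, 20.0, 20.5, 21.0), 20.125, 9.938, False),
    ])
    def test_mean_spread_and_repositioning_signal(self, readings, mean,
                                                  spread, ok):
        got_mean, got_spread, got_ok = average_readings(
            AngleReadings(readings), LIMITS)
        assert got_mean == pytest.approx(mean)
        assert got_spread == pytest.approx(spread, abs=1e-3)
        assert got_ok is ok

    def test_all_zero_readings_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            average_readings(AngleReadings((0.0, 0.0, 0.0, 0.0)), LIMITS)

    def test_min_based_spread_metric(self):
        limits = QALimits(spread_metric="min")
        _, spread, _ = average_readings(AngleReadings((19.0, 20.0, 20.5, 21.0)),
                                        limits)
        assert spread == pytest.approx(100 * 2.0 / 19.0)


class TestFactorAndDeviation:
    @pytest.mark.parametrize("measured, decayed, factor", [
        (25.78, 75.07, 0.343),
        (17.84, 47.73, 0.374),
    ])
    def test_worked_example_factors(self, measured, decayed, factor):
        assert round(calibration_factor(measured, decayed), 3) == factor

    def test_equal_inputs_give_unity(self):
        assert calibration_factor(42.0, 42.0) == 1.0

    @pytest.mark.parametrize("measured, decayed", [(10.0, 0.0), (0.0, 10.0)])
    def test_nonpositive_inputs_rejected(self, measured, decayed):
        with pytest.raises(ValueError):
            calibration_factor(measured, decayed)

    @pytest.mark.parametrize("factor, mean, expected", [
        (0.374, 0.353, 5.9),
        (0.343, 0.353, -2.8),
        (0.353, 0.353, 0.0),
    ])
    def test_deviation_from_group_mean(self, factor, mean, expected):
        assert round(deviation_from_mean(factor, mean), 1) == \
            pytest.approx(expected, abs=0.051)

    def test_deviation_at_mean_is_exactly_zero(self):
        assert deviation_from_mean(0.353, 0.353) == 0.0

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_factor_is_scale_invariant(self, measured, decayed, scale):
        base = calibration_factor(measured, decayed)
        scaled = calibration_factor(measured * scale, decayed * scale)
        assert scaled == pytest.approx(base, rel=1e-12)

    @given(st.floats(min_value=-30, max_value=30),
           st.floats(min_value=-30, max_value=30))
    def test_flag_monotone_in_deviation_magnitude(self, dev1, dev2):
        # if the smaller deviation trips the action limit, so does the larger
        small, large = sorted((dev1, dev2), key=abs)
        mean = 0.353
        flag = [abs(deviation_from_mean(mean * (1 + d / 100), mean))
                > LIMITS.action_limit for d in (small, large)]
        assert not flag[0] or flag[1]


class TestEvaluateRecord:
    def test_worked_example_first_row(self, worksheet):
        result = evaluate_record(worksheet[0], 0.353)
        assert round(result.measured_strength_u, 2) == pytest.approx(25.78,
                                                                     abs=0.011)
        assert round(result.decayed_assay_strength_u, 2) == pytest.approx(
            75.07, abs=0.011)
        assert round(result.cal_factor, 3) == 0.343
        assert round(result.deviation_pct, 1) == pytest.approx(-2.8, abs=0.11)
        assert not result.flags

    def test_worked_example_flagged_row(self, worksheet):
        result = evaluate_record(worksheet[1], 0.353)
        assert round(result.cal_factor, 3) == 0.374
        assert round(result.deviation_pct, 1) == 5.9
        assert result.flags == {Flag.ACTION_LIMIT}

    def test_constructed_identity_record_gives_unit_factor(self):
        # activity chosen so measured strength equals the (undecayed) assay
        const = PhysicsConstants()
        date = dt.date(2012, 1, 1)
        strength = 50.0
        record = PlaqueRecord(
            plaque_id="id", plaque_type=DEFAULT_PLAQUE_TYPES["EP917"],
            assay=SeedAssay(17, date, strength), measurement_date=date,
            activity_mci=strength / const.u_per_mci)
        result = evaluate_record(record, 1.0, const)
        assert result.cal_factor == pytest.approx(1.0, rel=1e-12)
        assert result.deviation_pct == pytest.approx(0.0, abs=1e-9)

    def test_wide_reading_spread_raises_repositioning_flag(self):
        record = PlaqueRecord(
            plaque_id="id", plaque_type=DEFAULT_PLAQUE_TYPES["EP917"],
            assay=SeedAssay(17, dt.date(2012, 1, 1), 50.0),
            measurement_date=dt.date(2012, 1, 5),
            readings=AngleReadings((19.0, 20.0, 20.5, 21.0)))
        result = evaluate_record(record, None)
        assert Flag.READING_SPREAD in result.flags
        assert result.spread_pct > 4.0

    def test_without_group_mean_no_deviation_or_action_flag(self, worksheet):
        result = evaluate_record(worksheet[1], None)
        assert result.deviation_pct is None
        assert Flag.ACTION_LIMIT not in result.flags


class TestCrossCheck:
    ASSAY = SeedAssay(17, dt.date(2012, 1, 1), 50.0)

    def plan(self, strength, date=dt.date(2012, 1, 1)):
        return SeedAssay(17, date, strength)

    def test_identical_plan_and_assay_pass(self):
        flags = cross_check(self.plan(50.0), self.ASSAY, 0.353, 0.353, LIMITS)
        assert flags == set()

    def test_unit_confusion_magnitude_is_flagged(self):
        # plan strength off by 1/0.787 (27.1%) against the assay
        flags = cross_check(self.plan(50.0 / 0.787), self.ASSAY, None, 0.353,
                            LIMITS)
        assert flags == {Flag.CROSS_CHECK}

    def test_three_percent_disagreement_passes(self):
        flags = cross_check(self.plan(50.0 * 1.03), self.ASSAY, None, 0.353,
                            LIMITS)
        assert flags == set()

    def test_plan_decay_aligned_before_comparison(self):
        # same physical lot assayed 10 days earlier: strengths agree once
        # decayed onto the assay date, so no flag
        const = PhysicsConstants()
        earlier = dt.date(2011, 12, 22)
        plan_strength = 50.0 * 2 ** (10 / const.half_life_days)
        flags = cross_check(self.plan(plan_strength, earlier), self.ASSAY,
                            None, 0.353, LIMITS, constants=const)
        assert flags == set()

    def test_discrepant_factors_flagged(self):
        flags = cross_check(self.plan(50.0), self.ASSAY,
                            measured_factor_vs_plan=0.40,
                            measured_factor_vs_assay=0.353, limits=LIMITS)
        assert flags == {Flag.CROSS_CHECK}

    def test_missing_plan_skips_check(self):
        assert cross_check(None, self.ASSAY, None, 0.353, LIMITS) == set()

    def test_record_level_cross_check_flows_through_evaluate(self, worksheet):
        record = worksheet[0]
        record.plan = SeedAssay(17, record.assay.assay_date,
                                record.assay.total_strength_u / 0.787)
        result = evaluate_record(record, 0.353)
        assert Flag.CROSS_CHECK in result.flags
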