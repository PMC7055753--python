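"""Standards grading, detection rates, and failure accounting."""

from __future__ import annotations

import numpy as np
import pytest

from vitalval import (
    ClinicalCutoffs,
    MeasurementRecord,
    Role,
    Vital,
    detection_rate,
    failure_summary,
    grade_bp_aami,
    grade_bp_bhs,
    grade_hr,
    grade_spo2,
)
from vitalval.grading import bhs_grade_from_percentages
from vitalval.records import records_to_frame
from vitalval.stats import AccuracySummary


def _summary(vital, mad, sd=None, pct=None, rmse_value=0.0) -> AccuracySummary:
    return AccuracySummary(
        device="dev",
        vital=vital,
        n_pairs=10,
        mean_signed_diff=0.0,
        mad=mad,
        sd_abs_diff=sd,
        mean_abs_pct_diff=pct,
        sd_abs_pct_diff=None,
        rmse=rmse_value,
        loa_low=None,
        loa_high=None,
    )


class TestBpGuideline:
    @pytest.mark.parametrize(
        "mad,sd,expected",
        [
            (5.3, 4.7, False),   # tight SD cannot rescue a 5.3 mm Hg MAD
            (16.9, 13.5, False),
            (5.0, 8.0, True),    # boundary inclusive
            (4.0, 8.1, False),
        ],
    )
    def test_pass_fail(self, mad, sd, expected):
        assert grade_bp_aami(_summary(Vital.SBP, mad, sd)) is expected

    def test_wrong_vital_rejected(self):
        with pytest.raises(ValueError):
            grade_bp_aami(_summary(Vital.HR, 1.0, 1.0))


class TestBhs:
    def test_all_zero_differences_grade_a(self):
        assert grade_bp_bhs([0.0] * 10).grade == "A"

    def test_all_large_differences_grade_d(self):
        assert grade_bp_bhs([20.0] * 10).grade == "D"

    def test_mid_table_multiset_grades_b(self):
        # 55 of 100 within 5, 80 within 10, 92 within 15: B thresholds hold,
        # the A row fails on the within-5 percentage.
        d = [3.0] * 55 + [8.0] * 25 + [13.0] * 12 + [30.0] * 8
        g = grade_bp_bhs(d)
        assert (g.p5, g.p10, g.p15) == pytest.approx((55.0, 80.0, 92.0))
        assert g.grade == "B"

    def test_grade_table_against_rule_oracle_on_grid(self):
        # Exhaustive oracle over a coarse monotone grid of percentages.
        def oracle(p5, p10, p15):
            if p5 >= 60 and p10 >= 85 and p15 >= 95:
                return "A"
            if p5 >= 50 and p10 >= 75 and p15 >= 90:
                return "B"
            if p5 >= 40 and p10 >= 65 and p15 >= 85:
                return "C"
            return "D"

        grid = range(0, 101, 5)
        for p5 in grid:
            for p10 in grid:
                if p10 < p5:
                    continue
                for p15 in grid:
                    if p15 < p10:
                        continue
                    assert bhs_grade_from_percentages(p5, p10, p15) == oracle(p5, p10, p15)

    def test_monotone_in_differences(self):
        rng = np.random.default_rng(23)
        order = {"A": 0, "B": 1, "C": 2, "D": 3}
        for _ in range(200):
            d = rng.uniform(0, 25, size=rng.integers(5, 40))
            g0 = grade_bp_bhs(d).grade
            i = rng.integers(0, d.size)
            d2 = d.copy()
            d2[i] = d2[i] * rng.uniform(0, 1)
            assert order[grade_bp_bhs(d2).grade] <= order[g0]


class TestHr:
    @pytest.mark.parametrize(
        "mad,pct,expected",
        [
            (1.8, 2.5, True),
            (6.5, 9.9, True),    # fails the bpm prong, passes the percent prong
            (6.0, 11.0, False),  # both prongs exceeded
            (5.0, 10.0, True),   # boundaries inclusive
        ],
    )
    def test_either_prong_suffices(self, mad, pct, expected):
        assert grade_hr(_summary(Vital.HR, mad, pct=pct)) is expected

    def test_wrong_vital_rejected(self):
        with pytest.raises(ValueError):
            grade_hr(_summary(Vital.SBP, 1.0, pct=1.0))


class TestSpo2:
    @pytest.mark.parametrize("value,expected", [(3.1, False), (3.0, True), (0.0, True)])
    def test_rmse_threshold(self, value, expected):
        assert grade_spo2(value) is expected

    def test_negative_rmse_rejected(self):
        with pytest.raises(ValueError):
            grade_spo2(-0.1)


class TestDetection:
    def test_partial_detection_of_hypertensive_references(self):
        ref = [145, 150, 160, 142, 141, 120, 118]
        inv = [150, 148, 139, 144, 143, 125, 150]  # 4 of the 5 abnormal detected
        d = detection_rate(inv, ref, Vital.SBP)
        assert (d.n_abnormal, d.n_detected) == (5, 4)
        assert d.rate == pytest.approx(0.8)

    def test_no_abnormal_references_is_undefined_not_zero(self):
        d = detection_rate([150, 150], [120, 125], Vital.SBP)
        assert d.n_abnormal == 0 and d.rate is None

    def test_perfect_device_detects_everything(self):
        ref = np.array([55.0, 58.0, 70.0, 45.0])
        d = detection_rate(ref, ref, Vital.HR)
        assert d.rate == 1.0

    def test_invariant_to_normal_range_pairs(self):
        ref = [145.0, 150.0]
        inv = [150.0, 139.0]
        base = detection_rate(inv, ref, Vital.SBP)
        padded = detection_rate(inv + [130.0, 100.0], ref + [120.0, 110.0], Vital.SBP)
        assert (padded.n_abnormal, padded.n_detected) == (base.n_abnormal, base.n_detected)

    def test_custom_cutoffs(self):
        d = detection_rate([85.0], [88.0], Vital.SPO2, ClinicalCutoffs(spo2_low=92.0))
        assert d.n_abnormal == 1 and d.n_detected == 1


class TestFailureSummary:
    def _records_with_failures(self, n_subjects, failed_slots):
        """failed_slots: {subject_index: [slots]} with final attempt failed."""
        recs = []
        for i in range(n_subjects):
            sid = f"s{i:03d}"
            for slot in (2, 4, 6):
                if slot in failed_slots.get(i, []):
                    recs.append(
                        MeasurementRecord(sid, Vital.SBP, Role.INVESTIGATIONAL, "dev", slot, failed=True)
                    )
                else:
                    recs.append(
                        MeasurementRecord(sid, Vital.SBP, Role.INVESTIGATIONAL, "dev", slot, value=120.0)
                    )
        return records_to_frame(recs)

    def test_participant_and_measurement_rates(self):
        # 13 failed slots spread over 6 of 85 subjects.
        failed = {0: [2, 4, 6], 1: [2, 4, 6], 2: [2, 4, 6], 3: [2], 4: [4, 6], 5: [2]}
        df = self._records_with_failures(85, failed)
        kept = sorted(df["subject_id"].unique())
        fs = failure_summary(df, kept, "dev", Vital.SBP)
        assert fs.participants_with_failure == 6
        assert fs.failed_measurements == 13
        assert fs.max_measurements == 255
        assert fs.participant_rate == pytest.approx(6 / 85)
        assert fs.measurement_rate == pytest.approx(13 / 255)

    def test_zero_failures(self):
        df = self._records_with_failures(10, {})
        fs = failure_summary(df, sorted(df["subject_id"].unique()), "dev", Vital.SBP)
        assert fs.failed_measurements == 0
        assert fs.participants_with_failure == 0
        assert fs.max_measurements == 30

    def test_successful_retry_does_not_count_as_failed_slot(self):
        recs = [
            MeasurementRecord("s0", Vital.SBP, Role.INVESTIGATIONAL, "dev", 2, attempt=1, failed=True),
            MeasurementRecord("s0", Vital.SBP, Role.INVESTIGATIONAL, "dev", 2, attempt=2, value=118.0),
            MeasurementRecord("s0", Vital.SBP, Role.INVESTIGATIONAL, "dev", 4, attempt=1, value=120.0),
            MeasurementRecord("s0", Vital.SBP, Role.INVESTIGATIONAL, "dev", 6, attempt=1, value=121.0),
        ]
        fs = failure_summary(records_to_frame(recs), ["s0"], "dev", Vital.SBP)
        assert fs.failed_measurements == 0

    def test_participant_counting_bound(self):
        failed = {0: [2, 4, 6], 1: [2]}
        df = self._records_with_failures(20, failed)
        fs = failure_summary(df, sorted(df["subject_id"].unique()), "dev", Vital.SBP)
        # Each failing participant contributes at most 3 failed measurements.
        assert fs.participant_rate >= fs.measurement_rate / 3 - 1e-12
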