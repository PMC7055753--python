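"""Grading against the accuracy standards for consumer vital-sign monitors.

Four standards are implemented, thresholds boundary-inclusive and
overridable:

* blood pressure, sphygmomanometer guideline: mean absolute difference
  <= 5 mm Hg with SD of the absolute differences <= 8 mm Hg;
* blood pressure, British Hypertension Society letter grade A-D from the
  cumulative percentages of absolute differences within 5/10/15 mm Hg;
* heart rate: mean absolute difference within 5 bpm OR mean absolute
  percent difference within 10% (the larger tolerance applies);
* pulse oximetry: RMSE <= 3.0%.

The module also computes clinical detection rates (how often the device
flags a reading the reference flags as abnormal) and the failure
bookkeeping: per-participant and per-measurement failure rates out of the
3-per-subject maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .protocol import AnalysisSet
from .records import StudyDataset
from .stats import AccuracySummary
from .vitals import PAIRS_PER_SUBJECT, Role, Vital

# ---------------------------------------------------------------------------
# Blood pressure


@dataclass(frozen=True)
class AamiThresholds:
    mad_max: float = 5.0  # mm Hg
    sd_max: float = 8.0   # mm Hg


def grade_bp_aami(summary: AccuracySummary, thresholds: AamiThresholds = AamiThresholds()) -> bool:
    """Pass/fail under the sphygmomanometer guideline criterion."""
    if summary.vital not in (Vital.SBP, Vital.DBP):
        raise ValueError(f"guideline BP criterion applies to SBP/DBP, not {summary.vital.value}")
    if summary.sd_abs_diff is None:
        raise ValueError("SD of absolute differences undefined (need >= 2 pairs)")
    return summary.mad <= thresholds.mad_max and summary.sd_abs_diff <= thresholds.sd_max


#: BHS protocol table: grade -> minimum cumulative % of absolute differences
#: within 5, 10 and 15 mm Hg.  All three must hold; the best grade wins.
BHS_TABLE: dict[str, tuple[float, float, float]] = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

BHS_BANDS = (5.0, 10.0, 15.0)  # mm Hg


@dataclass(frozen=True)
class BhsGrade:
    grade: str  # "A".."D"
    p5: float   # % of |d| <= 5 mm Hg
    p10: float
    p15: float


def bhs_cumulative_percentages(abs_diffs) -> tuple[float, float, float]:
    d = np.abs(np.asarray(abs_diffs, dtype=float))
    if d.size == 0:
        raise EmptyInputError("no differences to grade")
    return tuple(float(100.0 * np.mean(d <= band)) for band in BHS_BANDS)  # type: ignore[return-value]


def bhs_grade_from_percentages(p5: float, p10: float, p15: float) -> str:
    for grade in ("A", "B", "C"):
        t5, t10, t15 = BHS_TABLE[grade]
        if p5 >= t5 and p10 >= t10 and p15 >= t15:
            return grade
    return "D"


def grade_bp_bhs(diffs) -> BhsGrade:
    """British Hypertension Society letter grade for a difference multiset."""
    p5, p10, p15 = bhs_cumulative_percentages(diffs)
    return BhsGrade(bhs_grade_from_percentages(p5, p10, p15), p5, p10, p15)


# ---------------------------------------------------------------------------
# Heart rate and oximetry


@dataclass(frozen=True)
class HrThresholds:
    mad_max: float = 5.0   # bpm
    pct_max: float = 10.0  # %


def grade_hr(summary: AccuracySummary, thresholds: HrThresholds = HrThresholds()) -> bool:
    """Pass/fail for heart rate: either the bpm or the percent prong suffices."""
    if summary.vital is not Vital.HR:
        raise ValueError(f"HR criterion applies to HR, not {summary.vital.value}")
    if summary.mean_abs_pct_diff is None:
        raise ValueError("mean absolute percent difference undefined")
    return summary.mad <= thresholds.mad_max or summary.mean_abs_pct_diff <= thresholds.pct_max


SPO2_RMSE_MAX = 3.0  # %


def grade_spo2(rmse_value: float, rmse_max: float = SPO2_RMSE_MAX) -> bool:
    """Pass/fail for pulse oximetry RMSE accuracy."""
    if rmse_value < 0:
        raise ValueError(f"RMSE cannot be negative, got {rmse_value}")
    return rmse_value <= rmse_max


# ---------------------------------------------------------------------------
# Clinical detection


@dataclass(frozen=True)
class ClinicalCutoffs:
    """Abnormal-range cutoffs: stage-2 hypertension, bradycardia, hypoxemia."""

    sbp_high: float = 140.0  # >= mm Hg
    dbp_high: float = 90.0   # >= mm Hg
    hr_low: float = 60.0     # <  bpm
    spo2_low: float = 90.0   # <  %

    def condition(self, vital: Vital) -> tuple[str, str, float] | None:
        """(condition name, direction, cutoff) for a vital, if one applies."""
        return {
            Vital.SBP: ("hypertension_sbp", "ge", self.sbp_high),
            Vital.DBP: ("hypertension_dbp", "ge", self.dbp_high),
            Vital.HR: ("bradycardia", "lt", self.hr_low),
            Vital.SPO2: ("hypoxemia", "lt", self.spo2_low),
        }.get(Vital(vital))


@dataclass(frozen=True)
class DetectionRate:
    condition: str
    vital: Vital
    n_abnormal: int
    n_detected: int

    @property
    def rate(self) -> float | None:
        """Fraction detected, or None when no reference reading was abnormal."""
        if self.n_abnormal == 0:
            return None
        return self.n_detected / self.n_abnormal


def detection_rate(
    investigational,
    reference,
    vital: Vital,
    cutoffs: ClinicalCutoffs = ClinicalCutoffs(),
) -> DetectionRate:
    """Per-pair abnormal-value detection for one vital.

    A pair is abnormal when the REFERENCE value satisfies the cutoff and
    detected when the INVESTIGATIONAL value satisfies the same cutoff.  With
    no abnormal reference readings the rate is undefined (None), never 0.
    """
    vital = Vital(vital)
    cond = cutoffs.condition(vital)
    if cond is None:
        raise ValueError(f"no clinical cutoff defined for {vital.value}")
    name, direction, cutoff = cond
    inv = np.asarray(investigational, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if direction == "ge":
        abnormal, detected = ref >= cutoff, inv >= cutoff
    else:
        abnormal, detected = ref < cutoff, inv < cutoff
    return DetectionRate(
        condition=name,
        vital=vital,
        n_abnormal=int(abnormal.sum()),
        n_detected=int((abnormal & detected).sum()),
    )


# ---------------------------------------------------------------------------
# Failure accounting


@dataclass(frozen=True)
class FailureSummary:
    device: str
    vital: Vital
    n_participants: int            # kept subjects (denominator)
    participants_with_failure: int
    failed_measurements: int       # slots whose final attempt failed
    max_measurements: int          # 3 x kept subjects

    @property
    def participant_rate(self) -> float:
        return self.participants_with_failure / self.n_participants

    @property
    def measurement_rate(self) -> float:
        return self.failed_measurements / self.max_measurements


def failure_summary(
    records: StudyDataset | pd.DataFrame,
    kept_subjects: list[str],
    device: str,
    vital: Vital,
) -> FailureSummary:
    """Per-participant and per-measurement failure rates among kept subjects.

    A slot counts as failed when its final (highest-numbered) attempt failed;
    a participant is counted once however many of their slots failed.  The
    maximum is 3 measurements per kept subject.
    """
    if not kept_subjects:
        raise ValueError("kept subject set must be nonempty")
    df = records.records if isinstance(records, StudyDataset) else records
    vital = Vital(vital)
    inv = df[
        (df["role"] == Role.INVESTIGATIONAL.value)
        & (df["device"] == device)
        & (df["vital"] == vital.value)
        & (df["subject_id"].isin(kept_subjects))
    ]
    n_failed = 0
    failed_subjects: set[str] = set()
    if not inv.empty:
        last = inv.sort_values("attempt").groupby(["subject_id", "slot"]).tail(1)
        failed = last[last["failed"]]
        n_failed = int(len(failed))
        failed_subjects = set(failed["subject_id"].astype(str))
    return FailureSummary(
        device=device,
        vital=vital,
        n_participants=len(kept_subjects),
        participants_with_failure=len(failed_subjects),
        failed_measurements=n_failed,
        max_measurements=PAIRS_PER_SUBJECT * len(kept_subjects),
    )


# ---------------------------------------------------------------------------
# Consolidated report


@dataclass
class GradeReport:
    """All standard outcomes for one device x vital."""

    device: str
    vital: Vital
    aami_pass: bool | None = None
    bhs: BhsGrade | None = None
    hr_pass: bool | None = None
    spo2_pass: bool | None = None
    detection: DetectionRate | None = None
    failure: FailureSummary | None = None


def grade_device_vital(
    summary: AccuracySummary,
    diffs,
    investigational,
    reference,
    analysis_set: AnalysisSet | None = None,
    dataset: StudyDataset | None = None,
    cutoffs: ClinicalCutoffs = ClinicalCutoffs(),
    aami: AamiThresholds = AamiThresholds(),
    hr: HrThresholds = HrThresholds(),
    spo2_rmse_max: float = SPO2_RMSE_MAX,
) -> GradeReport:
    """Apply every applicable standard to one device x vital."""
    report = GradeReport(device=summary.device, vital=summary.vital)
    if summary.vital in (Vital.SBP, Vital.DBP):
        report.aami_pass = grade_bp_aami(summary, aami)
        report.bhs = grade_bp_bhs(diffs)
    elif summary.vital is Vital.HR:
        report.hr_pass = grade_hr(summary, hr)
    elif summary.vital is Vital.SPO2:
        report.spo2_pass = grade_spo2(summary.rmse, spo2_rmse_max)
    report.detection = detection_rate(investigational, reference, summary.vital, cutoffs)
    if analysis_set is not None and dataset is not None:
        report.failure = failure_summary(
            dataset, analysis_set.kept_subjects, summary.device, summary.vital
        )
    return report
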