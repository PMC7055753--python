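"""End-to-end validation run: dataset in, consolidated report out.

``run_validation`` applies subject exclusion, builds comparison pairs, and
computes — per device x vital — the accuracy summary, the applicable
standard grades, detection and failure rates, Bland-Altman quantities and
the normality-gated correlation; for devices with calibration records it
adds the calibration-dependence analysis.  The report is deterministic given
(dataset, config) and serializes to JSON with undefined statistics as
explicit nulls carrying a reason, never as 0.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .calibration import CalibrationDependence, calibration_dependence
from .errors import MissingCalibrationError
from .grading import (
    AamiThresholds,
    ClinicalCutoffs,
    GradeReport,
    HrThresholds,
    SPO2_RMSE_MAX,
    detection_rate,
    failure_summary,
    grade_bp_aami,
    grade_bp_bhs,
    grade_hr,
    grade_spo2,
)
from .protocol import AnalysisSet, build_analysis_set, exclusion_rules
from .records import StudyDataset
from .stats import (
    AccuracySummary,
    CorrelationResult,
    bland_altman,
    correlation,
    signed_diff_vs_reference,
    summarize_pairs,
)
from .vitals import UNITS, Vital

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Analysis thresholds and method switches (guideline values shipped)."""

    sbp_exclusion_threshold: float = 12.0  # mm Hg
    dbp_exclusion_threshold: float = 8.0   # mm Hg
    exclusion_mode: str = "consecutive"    # or "range"
    alpha: float = 0.05
    bland_altman_absolute_sd: bool = False
    calibration_variant: str = "text"      # or "figure"
    calibration_per_subject_mean: bool = False
    aami: AamiThresholds = field(default_factory=AamiThresholds)
    hr: HrThresholds = field(default_factory=HrThresholds)
    spo2_rmse_max: float = SPO2_RMSE_MAX
    cutoffs: ClinicalCutoffs = field(default_factory=ClinicalCutoffs)

    def __post_init__(self) -> None:
        if isinstance(self.aami, dict):
            self.aami = AamiThresholds(**self.aami)
        if isinstance(self.hr, dict):
            self.hr = HrThresholds(**self.hr)
        if isinstance(self.cutoffs, dict):
            self.cutoffs = ClinicalCutoffs(**self.cutoffs)

    def rules(self):
        return exclusion_rules(
            self.sbp_exclusion_threshold, self.dbp_exclusion_threshold, self.exclusion_mode
        )


@dataclass
class DeviceVitalResult:
    summary: AccuracySummary
    grades: GradeReport
    correlation: CorrelationResult
    proportional_bias: CorrelationResult | None
    loa: tuple[float | None, float | None]


@dataclass
class ValidationReport:
    n_subjects_total: int
    n_subjects_kept: int
    analysis_set: AnalysisSet
    results: dict[tuple[str, str], DeviceVitalResult]
    calibration: dict[str, CalibrationDependence]
    config: AnalysisConfig
    provenance: dict

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out: dict[str, Any] = {
            "schema_version": "1",
            "n_subjects_total": self.n_subjects_total,
            "n_subjects_kept": self.n_subjects_kept,
            "n_subjects_excluded": self.n_subjects_total - self.n_subjects_kept,
            "exclusions": self.analysis_set.exclusions.excluded.to_dict("records"),
            "unusable": self.analysis_set.unusable.to_dict("records"),
            "provenance": self.provenance,
            "devices": {},
        }
        for (device, vital), res in sorted(self.results.items()):
            dev = out["devices"].setdefault(device, {})
            s = res.summary
            g = res.grades
            entry: dict[str, Any] = {
                "n_pairs": s.n_pairs,
                "mean_signed_diff": s.mean_signed_diff,
                "mad": s.mad,
                "sd_abs_diff": _null(s.sd_abs_diff, "needs >= 2 pairs"),
                "mean_abs_pct_diff": _null(s.mean_abs_pct_diff, "undefined"),
                "sd_abs_pct_diff": _null(s.sd_abs_pct_diff, "undefined"),
                "rmse": s.rmse,
                "loa_low": _null(s.loa_low, "needs >= 2 pairs"),
                "loa_high": _null(s.loa_high, "needs >= 2 pairs"),
                "correlation": _corr_dict(res.correlation),
                "units": UNITS[s.vital],
            }
            if g.aami_pass is not None:
                entry["aami_pass"] = g.aami_pass
            if g.bhs is not None:
                entry["bhs"] = {
                    "grade": g.bhs.grade,
                    "pct_within_5": g.bhs.p5,
                    "pct_within_10": g.bhs.p10,
                    "pct_within_15": g.bhs.p15,
                }
            if g.hr_pass is not None:
                entry["hr_pass"] = g.hr_pass
            if g.spo2_pass is not None:
                entry["spo2_pass"] = g.spo2_pass
            if g.detection is not None:
                entry["detection"] = {
                    "condition": g.detection.condition,
                    "n_abnormal": g.detection.n_abnormal,
                    "n_detected": g.detection.n_detected,
                    "rate": _null(g.detection.rate, "no abnormal reference readings"),
                }
            if g.failure is not None:
                entry["failure"] = {
                    "participants_with_failure": g.failure.participants_with_failure,
                    "n_participants": g.failure.n_participants,
                    "participant_rate": g.failure.participant_rate,
                    "failed_measurements": g.failure.failed_measurements,
                    "max_measurements": g.failure.max_measurements,
                    "measurement_rate": g.failure.measurement_rate,
                }
            if res.proportional_bias is not None:
                entry["proportional_bias"] = _corr_dict(res.proportional_bias)
            dev[s.vital.value] = entry
        out["calibration"] = {
            device: {
                "variant": dep.variant,
                "per_subject_mean": dep.per_subject_mean,
                "n_points": len(dep.points),
                "correlation": _corr_dict(dep.result),
            }
            for device, dep in sorted(self.calibration.items())
        }
        return _jsonify(out)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = [
            "# Device validation report",
            "",
            f"Subjects: {d['n_subjects_total']} enrolled, "
            f"{d['n_subjects_excluded']} excluded by the variation rules, "
            f"{d['n_subjects_kept']} analyzed.",
            "",
        ]
        for device, vitals in d["devices"].items():
            lines.append(f"## {device}")
            for vital, e in vitals.items():
                unit = e["units"]
                lines += ["", f"### {vital}", ""]
                sd = e["sd_abs_diff"]
                sd_s = f" (SD {sd:.2f})" if isinstance(sd, (int, float)) else ""
                lines.append(
                    f"- pairs: {e['n_pairs']}; MAD {e['mad']:.2f}{sd_s} {unit}"
                    f"; RMSE {e['rmse']:.2f} {unit}"
                )
                if "aami_pass" in e:
                    lines.append(f"- guideline BP criterion: {'PASS' if e['aami_pass'] else 'FAIL'}")
                if "bhs" in e:
                    b = e["bhs"]
                    lines.append(
                        f"- BHS grade {b['grade']} "
                        f"(within 5/10/15 {unit}: {b['pct_within_5']:.0f}/"
                        f"{b['pct_within_10']:.0f}/{b['pct_within_15']:.0f}%)"
                    )
                if "hr_pass" in e:
                    lines.append(f"- HR criterion: {'PASS' if e['hr_pass'] else 'FAIL'}")
                if "spo2_pass" in e:
                    lines.append(f"- SpO2 RMSE criterion: {'PASS' if e['spo2_pass'] else 'FAIL'}")
                det = e.get("detection")
                if det:
                    rate = det["rate"]
                    rate_s = (
                        f"{100 * rate['value']:.0f}%" if isinstance(rate, dict) and rate.get("value") is not None
                        else (f"{100 * rate:.0f}%" if isinstance(rate, float) else "undefined")
                    )
                    lines.append(
                        f"- {det['condition']}: detected {det['n_detected']}/"
                        f"{det['n_abnormal']} ({rate_s})"
                    )
                fail = e.get("failure")
                if fail:
                    lines.append(
                        f"- failures: {fail['failed_measurements']}/{fail['max_measurements']} "
                        f"measurements ({100 * fail['measurement_rate']:.1f}%) in "
                        f"{fail['participants_with_failure']}/{fail['n_participants']} "
                        f"participants ({100 * fail['participant_rate']:.1f}%)"
                    )
            lines.append("")
        if d["calibration"]:
            lines.append("## Calibration dependence (SBP)")
            for device, c in d["calibration"].items():
                corr = c["correlation"]
                coef = corr.get("coefficient")
                coef_s = (
                    f"{coef:.2f} ({corr.get('method')})"
                    if isinstance(coef, float)
                    else f"undefined ({coef.get('reason') if isinstance(coef, dict) else 'n/a'})"
                )
                lines.append(
                    f"- {device} [{c['variant']} variant, {c['n_points']} points]: "
                    f"coefficient {coef_s}"
                )
            lines.append("")
        return "\n".join(lines)


def _null(value, reason: str):
    if value is None:
        return {"value": None, "reason": reason}
    return value


def _corr_dict(c: CorrelationResult) -> dict:
    return {
        "coefficient": _null(c.coefficient, c.reason or "undefined"),
        "method": c.method,
        "p_value": c.p_value,
        "normality_p": c.normality_p,
        "n": c.n,
    }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def run_validation(
    dataset: StudyDataset,
    config: AnalysisConfig | None = None,
) -> ValidationReport:
    """Run the full analysis on a dataset and return the report."""
    config = config or AnalysisConfig()
    aset = build_analysis_set(dataset, config.rules())
    n_total = len(dataset.subjects)
    logger.info(
        "exclusions: %d of %d subjects dropped by variation rules",
        n_total - len(aset.kept_subjects),
        n_total,
    )

    results: dict[tuple[str, str], DeviceVitalResult] = {}
    for device, vital_name in aset.device_vitals():
        vital = Vital(vital_name)
        pairs = aset.pairs_for(device, vital)
        if pairs.empty:
            logger.info("no pairs for %s/%s; skipped", device, vital_name)
            continue
        inv = pairs["investigational_value"].to_numpy(dtype=float)
        ref = pairs["reference_value"].to_numpy(dtype=float)
        d = inv - ref
        summary = summarize_pairs(
            device, vital, inv, ref, absolute_sd_loa=config.bland_altman_absolute_sd
        )
        grades = GradeReport(device=device, vital=vital)
        if vital in (Vital.SBP, Vital.DBP):
            grades.aami_pass = (
                grade_bp_aami(summary, config.aami) if summary.sd_abs_diff is not None else None
            )
            grades.bhs = grade_bp_bhs(d)
        elif vital is Vital.HR:
            grades.hr_pass = (
                grade_hr(summary, config.hr) if summary.mean_abs_pct_diff is not None else None
            )
        elif vital is Vital.SPO2:
            grades.spo2_pass = grade_spo2(summary.rmse, config.spo2_rmse_max)
        grades.detection = detection_rate(inv, ref, vital, config.cutoffs)
        grades.failure = failure_summary(dataset, aset.kept_subjects, device, vital)

        corr = _safe_corr(correlation, inv, ref, config.alpha, summary.n_pairs)
        prop = (
            _safe_corr(signed_diff_vs_reference, inv, ref, config.alpha, summary.n_pairs)
            if vital in (Vital.SBP, Vital.DBP)
            else None
        )
        ba = bland_altman(inv, ref, absolute_sd=config.bland_altman_absolute_sd)
        results[(device, vital_name)] = DeviceVitalResult(
            summary=summary,
            grades=grades,
            correlation=corr,
            proportional_bias=prop,
            loa=(ba.loa_low, ba.loa_high),
        )

    calibration: dict[str, CalibrationDependence] = {}
    for device in sorted(dataset.calibrations["device"].unique()):
        pairs = aset.pairs_for(device, Vital.SBP)
        if len(pairs) < 4:
            logger.info("calibration analysis skipped for %s: <4 SBP pairs", device)
            continue
        try:
            calibration[device] = calibration_dependence(
                pairs,
                dataset.calibration_map(device),
                variant=config.calibration_variant,  # type: ignore[arg-type]
                per_subject_mean=config.calibration_per_subject_mean,
                alpha=config.alpha,
            )
        except MissingCalibrationError as exc:
            logger.warning("calibration analysis failed for %s: %s", device, exc)

    return ValidationReport(
        n_subjects_total=n_total,
        n_subjects_kept=len(aset.kept_subjects),
        analysis_set=aset,
        results=results,
        calibration=calibration,
        config=config,
        provenance=dict(dataset.provenance),
    )


def _safe_corr(fn, inv, ref, alpha, n) -> CorrelationResult:
    if n < 4:
        return CorrelationResult(None, None, None, None, n, reason="fewer than 4 pairs")
    return fn(inv, ref, alpha)
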