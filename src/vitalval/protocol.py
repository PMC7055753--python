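"""Pairing and subject exclusion for the interleaved measurement protocol.

The protocol alternates standard (S) and investigational (I) readings:
S1 I2 S3 I4 S5 I6 S7.  The reference for investigational slot 2i is the
average of the two standard readings that bound it (slots 2i-1 and 2i+1),
which cancels first-order within-session drift.  Following the
sphygmomanometer validation guidelines the protocol derives from, subjects
whose sequential standard readings vary too much (more than 12 mm Hg for
SBP or 8 mm Hg for DBP between consecutive readings, by default) are
excluded from every vital's analysis; the exclusion decision reads standard
records only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import MissingStandardError, NoAnalyzableSubjectsError
from .records import MeasurementRecord, StudyDataset, frame_to_records, records_to_frame
from .vitals import (
    INVESTIGATIONAL_SLOTS,
    PAIRS_PER_SUBJECT,
    STANDARD_SLOTS,
    Role,
    Vital,
)

VariationMode = Literal["consecutive", "range"]


@dataclass(frozen=True)
class ComparisonPair:
    """One investigational reading matched to its bounded-average reference."""

    subject_id: str
    vital: Vital
    device: str
    pair_index: int  # 1..3
    investigational_value: float
    reference_value: float

    @property
    def signed_difference(self) -> float:
        return self.investigational_value - self.reference_value

    @property
    def pair_mean(self) -> float:
        return 0.5 * (self.investigational_value + self.reference_value)


@dataclass(frozen=True)
class ExclusionRule:
    """Maximum allowed variation in a vital's sequential standard readings."""

    vital: Vital
    threshold: float
    mode: VariationMode = "consecutive"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")

    def variation(self, standards: Sequence[float]) -> float:
        vals = np.asarray(standards, dtype=float)
        if self.mode == "range":
            return float(vals.max() - vals.min())
        return float(np.max(np.abs(np.diff(vals))))


#: Guideline defaults: 12 mm Hg for SBP, 8 mm Hg for DBP.
DEFAULT_EXCLUSION_RULES: tuple[ExclusionRule, ...] = (
    ExclusionRule(Vital.SBP, 12.0),
    ExclusionRule(Vital.DBP, 8.0),
)


def exclusion_rules(
    sbp_threshold: float = 12.0,
    dbp_threshold: float = 8.0,
    mode: VariationMode = "consecutive",
) -> tuple[ExclusionRule, ...]:
    return (
        ExclusionRule(Vital.SBP, sbp_threshold, mode),
        ExclusionRule(Vital.DBP, dbp_threshold, mode),
    )


def _as_records(records) -> list[MeasurementRecord]:
    if isinstance(records, StudyDataset):
        return frame_to_records(records.records)
    if isinstance(records, pd.DataFrame):
        return frame_to_records(records)
    return list(records)


def pair_measurements(
    records: Iterable[MeasurementRecord],
    vital: Vital,
    device: str,
) -> tuple[list[ComparisonPair], int]:
    """Match one subject's investigational readings to bounded references.

    ``records`` are one subject's records (other vitals/devices are ignored).
    Pair i uses the standards at slots 2i-1 and 2i+1.  A slot whose final
    attempt failed yields no pair and increments the failure count, so
    pairs + failures always equals 3.

    Raises :class:`MissingStandardError` when any of the four standard
    readings for the vital is absent or failed — the subject is unusable for
    this vital, which is distinct from guideline exclusion.
    """
    vital = Vital(vital)
    recs = _as_records(records)
    subjects = {r.subject_id for r in recs}
    if len(subjects) > 1:
        raise ValueError(f"records span multiple subjects: {sorted(subjects)}")

    standards: dict[int, float] = {}
    for r in recs:
        if r.role is Role.STANDARD and r.vital is vital and not r.failed:
            standards[r.slot] = float(r.value)  # type: ignore[arg-type]
    missing = [s for s in STANDARD_SLOTS if s not in standards]
    if missing:
        raise MissingStandardError(
            f"subject {next(iter(subjects), '?')!r}: missing standard {vital.value} "
            f"reading(s) at slot(s) {missing}"
        )

    # Final attempt per investigational slot decides success or failure.
    final: dict[int, MeasurementRecord] = {}
    for r in recs:
        if r.role is Role.INVESTIGATIONAL and r.vital is vital and r.device == device:
            cur = final.get(r.slot)
            if cur is None or r.attempt > cur.attempt:
                final[r.slot] = r
    missing_inv = [s for s in INVESTIGATIONAL_SLOTS if s not in final]
    if missing_inv:
        raise MissingStandardError(
            f"subject {next(iter(subjects), '?')!r}: no investigational "
            f"{vital.value}/{device} record at slot(s) {missing_inv}"
        )

    pairs: list[ComparisonPair] = []
    n_failed = 0
    for i, slot in enumerate(INVESTIGATIONAL_SLOTS, start=1):
        rec = final[slot]
        if rec.failed:
            n_failed += 1
            continue
        reference = 0.5 * (standards[slot - 1] + standards[slot + 1])
        pairs.append(
            ComparisonPair(
                subject_id=rec.subject_id,
                vital=vital,
                device=device,
                pair_index=i,
                investigational_value=float(rec.value),  # type: ignore[arg-type]
                reference_value=reference,
            )
        )
    assert len(pairs) + n_failed == PAIRS_PER_SUBJECT
    return pairs, n_failed


@dataclass
class ExclusionReport:
    """Outcome of applying the variation rules to all subjects."""

    kept: list[str]
    excluded: pd.DataFrame  # subject_id, vital, mode, threshold, observed_variation
    unassessable: list[str] = field(default_factory=list)

    @property
    def excluded_subjects(self) -> list[str]:
        return sorted(self.excluded["subject_id"].unique())


def apply_exclusions(
    records,
    rules: Sequence[ExclusionRule] = DEFAULT_EXCLUSION_RULES,
) -> ExclusionReport:
    """Apply the standard-reading variation rules subject-wise.

    A subject tripping any rule is excluded from ALL vital analyses.  The
    decision never reads investigational or calibration records.  Rules whose
    vital has no standard records in the dataset are skipped (e.g. a study
    where no device measures DBP).  Subjects lacking a complete set of four
    standard readings for an assessable rule vital are reported as
    ``unassessable`` — they are not excluded here, but pairing will flag them
    unusable for that vital.
    """
    if isinstance(records, StudyDataset):
        df = records.records
    elif isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)

    all_subjects = sorted(df["subject_id"].astype(str).unique())
    std = df[(df["role"] == Role.STANDARD.value) & (~df["failed"])]

    rows: list[tuple[str, str, str, float, float]] = []
    unassessable: set[str] = set()
    for rule in rules:
        sub = std[std["vital"] == rule.vital.value]
        if sub.empty:
            continue
        piv = sub.pivot_table(
            index="subject_id", columns="slot", values="value", aggfunc="first"
        )
        for slot in STANDARD_SLOTS:
            if slot not in piv.columns:
                piv[slot] = np.nan
        vals = piv[list(STANDARD_SLOTS)].to_numpy(dtype=float)
        complete = ~np.isnan(vals).any(axis=1)
        unassessable.update(str(s) for s in piv.index[~complete])
        if rule.mode == "range":
            variation = np.nanmax(vals, axis=1) - np.nanmin(vals, axis=1)
        else:
            variation = np.max(np.abs(np.diff(vals, axis=1)), axis=1)
        tripped = complete & (variation > rule.threshold)
        for sid, obs in zip(piv.index[tripped], variation[tripped]):
            rows.append(
                (str(sid), rule.vital.value, rule.mode, rule.threshold, float(obs))
            )

    excluded = pd.DataFrame(
        rows, columns=["subject_id", "vital", "mode", "threshold", "observed_variation"]
    )
    dropped = set(excluded["subject_id"])
    kept = [s for s in all_subjects if s not in dropped]
    return ExclusionReport(
        kept=kept, excluded=excluded, unassessable=sorted(unassessable - dropped)
    )


PAIR_COLUMNS = [
    "subject_id",
    "device",
    "vital",
    "pair_index",
    "investigational_value",
    "reference_value",
    "signed_difference",
    "pair_mean",
]


@dataclass
class AnalysisSet:
    """Comparison pairs over the kept subjects, plus the bookkeeping."""

    pairs: pd.DataFrame  # PAIR_COLUMNS
    failures: pd.DataFrame  # subject_id, device, vital, n_failed
    kept_subjects: list[str]
    exclusions: ExclusionReport
    unusable: pd.DataFrame  # subject_id, device, vital, reason
    #: subjects contributing pairs or failures, per (device, vital)
    analyzable: dict[tuple[str, str], int] = field(default_factory=dict)

    def pairs_for(self, device: str, vital: Vital) -> pd.DataFrame:
        v = Vital(vital).value
        return self.pairs[(self.pairs["device"] == device) & (self.pairs["vital"] == v)]

    def device_vitals(self) -> list[tuple[str, str]]:
        return sorted(self.analyzable)


def build_analysis_set(
    dataset: StudyDataset | pd.DataFrame,
    rules: Sequence[ExclusionRule] = DEFAULT_EXCLUSION_RULES,
) -> AnalysisSet:
    """Exclude subjects, then pair every device-vital over the survivors."""
    df = dataset.records if isinstance(dataset, StudyDataset) else dataset
    exclusions = apply_exclusions(df, rules)
    if not exclusions.kept:
        raise NoAnalyzableSubjectsError("every subject was excluded")

    recs = frame_to_records(df)
    by_subject: dict[str, list[MeasurementRecord]] = {}
    for r in recs:
        by_subject.setdefault(r.subject_id, []).append(r)

    combos = sorted(
        {(r.device, r.vital) for r in recs if r.role is Role.INVESTIGATIONAL},
        key=lambda dv: (dv[0], dv[1].value),
    )

    pair_rows: list[tuple] = []
    failure_rows: list[tuple] = []
    unusable_rows: list[tuple] = []
    analyzable: dict[tuple[str, str], int] = {}
    for device, vital in combos:
        n_analyzable = 0
        for sid in exclusions.kept:
            subject_recs = by_subject.get(sid, [])
            if not any(
                r.role is Role.INVESTIGATIONAL
                and r.device == device
                and r.vital is vital
                for r in subject_recs
            ):
                continue
            try:
                pairs, n_failed = pair_measurements(subject_recs, vital, device)
            except MissingStandardError as exc:
                unusable_rows.append((sid, device, vital.value, str(exc)))
                continue
            n_analyzable += 1
            for p in pairs:
                pair_rows.append(
                    (
                        p.subject_id,
                        p.device,
                        p.vital.value,
                        p.pair_index,
                        p.investigational_value,
                        p.reference_value,
                        p.signed_difference,
                        p.pair_mean,
                    )
                )
            if n_failed:
                failure_rows.append((sid, device, vital.value, n_failed))
        analyzable[(device, vital.value)] = n_analyzable

    return AnalysisSet(
        pairs=pd.DataFrame(pair_rows, columns=PAIR_COLUMNS),
        failures=pd.DataFrame(
            failure_rows, columns=["subject_id", "device", "vital", "n_failed"]
        ),
        kept_subjects=list(exclusions.kept),
        exclusions=exclusions,
        unusable=pd.DataFrame(
            unusable_rows, columns=["subject_id", "device", "vital", "reason"]
        ),
        analyzable=analyzable,
    )
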