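"""Measurement records and the in-memory study dataset.

A study is a flat log of timed readings.  Each record is one reading (or one
failed attempt): who was measured, which vital, which device in which role,
the protocol slot, the attempt number, and either a value or a failure flag.
The canonical on-disk form is a CSV with one row per record (see
:mod:`vitalval.io`); in memory the log is a :class:`pandas.DataFrame` plus a
calibration table, wrapped in :class:`StudyDataset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .vitals import (
    CALIBRATION_SLOT,
    INVESTIGATIONAL_SLOTS,
    MAX_ATTEMPTS,
    PLAUSIBLE_RANGE,
    STANDARD_SLOTS,
    Role,
    Vital,
)

SCHEMA_VERSION = "1"

RECORD_COLUMNS = [
    "subject_id",
    "vital",
    "role",
    "device",
    "slot",
    "attempt",
    "value",
    "failed",
]

CALIBRATION_COLUMNS = ["subject_id", "device", "calibration_value"]


def _slots_for_role(role: Role) -> tuple[int, ...]:
    if role is Role.STANDARD:
        return STANDARD_SLOTS
    if role is Role.INVESTIGATIONAL:
        return INVESTIGATIONAL_SLOTS
    return (CALIBRATION_SLOT,)


@dataclass(frozen=True)
class MeasurementRecord:
    """One timed reading or failed attempt."""

    subject_id: str
    vital: Vital
    role: Role
    device: str
    slot: int
    attempt: int = 1
    value: float | None = None
    failed: bool = False

    def __post_init__(self) -> None:
        if self.failed == (self.value is not None):
            raise ValueError(
                f"record must carry a value XOR a failure flag, got value={self.value!r} "
                f"failed={self.failed!r}"
            )
        if self.slot not in _slots_for_role(self.role):
            raise ValueError(
                f"slot {self.slot} is not valid for role {self.role.value!r} "
                f"(allowed: {_slots_for_role(self.role)})"
            )
        if not 1 <= self.attempt <= MAX_ATTEMPTS:
            raise ValueError(f"attempt must be in 1..{MAX_ATTEMPTS}, got {self.attempt}")
        if self.value is not None:
            lo, hi = PLAUSIBLE_RANGE[self.vital]
            if not (math.isfinite(self.value) and lo <= self.value <= hi):
                raise ValueError(
                    f"{self.vital.value} value {self.value} outside plausible "
                    f"range [{lo}, {hi}]"
                )


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Convert a record sequence to the canonical DataFrame layout."""
    rows = [
        (
            r.subject_id,
            r.vital.value,
            r.role.value,
            r.device,
            r.slot,
            r.attempt,
            float("nan") if r.value is None else float(r.value),
            bool(r.failed),
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df["slot"] = df["slot"].astype(int)
    df["attempt"] = df["attempt"].astype(int)
    df["value"] = df["value"].astype(float)
    df["failed"] = df["failed"].astype(bool)
    return df


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    """Convert the canonical DataFrame layout back to record objects."""
    out: list[MeasurementRecord] = []
    for row in df.itertuples(index=False):
        value = None if (row.value is None or pd.isna(row.value)) else float(row.value)
        out.append(
            MeasurementRecord(
                subject_id=str(row.subject_id),
                vital=Vital(row.vital),
                role=Role(row.role),
                device=str(row.device),
                slot=int(row.slot),
                attempt=int(row.attempt),
                value=value,
                failed=bool(row.failed),
            )
        )
    return out


@dataclass
class StudyDataset:
    """Measurement log + calibration table + provenance.

    ``calibrations`` has columns ``subject_id, device, calibration_value`` and
    one row per subject per calibration-dependent device.  ``provenance``
    records where the data came from (simulator seed and config hash, or
    ``"external"``) and always carries ``schema_version``.
    """

    records: pd.DataFrame
    calibrations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=CALIBRATION_COLUMNS)
    )
    provenance: dict = field(
        default_factory=lambda: {"source": "external", "schema_version": SCHEMA_VERSION}
    )

    def __post_init__(self) -> None:
        self.provenance.setdefault("schema_version", SCHEMA_VERSION)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.records["subject_id"].unique())

    @property
    def devices(self) -> list[str]:
        inv = self.records[self.records["role"] == Role.INVESTIGATIONAL.value]
        return sorted(inv["device"].unique())

    def calibration_map(self, device: str) -> dict[str, float]:
        """Per-subject calibration value for one device."""
        sub = self.calibrations[self.calibrations["device"] == device]
        return dict(zip(sub["subject_id"].astype(str), sub["calibration_value"].astype(float)))

    def equals(self, other: "StudyDataset") -> bool:
        return self.records.equals(other.records) and self.calibrations.reset_index(
            drop=True
        ).equals(other.calibrations.reset_index(drop=True))


def validate_record_frame(df: pd.DataFrame) -> list[str]:
    """Validate a raw record table; return one message per bad row.

    Row numbers in messages are 1-based data rows (header excluded), matching
    what a user sees when the CSV is opened minus the header line.
    """
    errors: list[str] = []
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing column(s): {', '.join(missing)}"]

    valid_vitals = {v.value for v in Vital}
    valid_roles = {r.value for r in Role}
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.vital not in valid_vitals:
            errors.append(f"row {i}: unknown vital {row.vital!r}")
            continue
        if row.role not in valid_roles:
            errors.append(f"row {i}: unknown role {row.role!r}")
            continue
        vital = Vital(row.vital)
        role = Role(row.role)
        try:
            slot = int(row.slot)
            attempt = int(row.attempt)
        except (TypeError, ValueError):
            errors.append(f"row {i}: slot/attempt must be integers")
            continue
        if slot not in _slots_for_role(role):
            errors.append(
                f"row {i}: slot {slot} invalid for role {role.value!r} "
                f"(allowed {_slots_for_role(role)})"
            )
        if not 1 <= attempt <= MAX_ATTEMPTS:
            errors.append(f"row {i}: attempt {attempt} outside 1..{MAX_ATTEMPTS}")
        failed = bool(row.failed)
        has_value = not (row.value is None or pd.isna(row.value))
        if failed == has_value:
            errors.append(f"row {i}: 'failed' must be true exactly when 'value' is empty")
        if has_value:
            lo, hi = PLAUSIBLE_RANGE[vital]
            v = float(row.value)
            if not (math.isfinite(v) and lo <= v <= hi):
                errors.append(
                    f"row {i}: {vital.value} value {v} outside plausible range [{lo}, {hi}]"
                )
        key = (row.subject_id, row.device, row.vital, slot, attempt)
        if key in seen:
            errors.append(
                f"row {i}: duplicate (subject, device, vital, slot, attempt) "
                f"{key} first seen at row {seen[key]}"
            )
        else:
            seen[key] = i
    return errors
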