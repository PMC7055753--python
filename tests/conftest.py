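"""Shared builders for hand-crafted measurement logs."""

from __future__ import annotations

import pytest

from vitalval import CohortConfig, DeviceModel, MeasurementRecord, Role, Vital
from vitalval.vitals import INVESTIGATIONAL_SLOTS, STANDARD_SLOTS


def make_subject_records(
    subject_id: str,
    vital: Vital,
    standards: list[float],
    investigational: list[float | None],
    device: str = "dev",
) -> list[MeasurementRecord]:
    """Records for one subject/vital: 4 standards, 3 investigational slots.

    ``None`` in ``investigational`` marks a failed slot (single failed
    attempt).
    """
    recs = [
        MeasurementRecord(subject_id, vital, Role.STANDARD, "std", slot, value=float(v))
        for slot, v in zip(STANDARD_SLOTS, standards)
    ]
    for slot, v in zip(INVESTIGATIONAL_SLOTS, investigational):
        if v is None:
            recs.append(
                MeasurementRecord(
                    subject_id, vital, Role.INVESTIGATIONAL, device, slot, failed=True
                )
            )
        else:
            recs.append(
                MeasurementRecord(
                    subject_id, vital, Role.INVESTIGATIONAL, device, slot, value=float(v)
                )
            )
    return recs


@pytest.fixture
def noise_free_device() -> DeviceModel:
    """A device measuring all four vitals with no error sources."""
    return DeviceModel(
        name="perfect",
        vitals_measured=frozenset(Vital),
    )


@pytest.fixture
def noise_free_cohort() -> CohortConfig:
    """Subject-to-subject variation only: no drift within the session."""
    return CohortConfig(
        n_subjects=12,
        drift_sd={v: 0.0 for v in Vital},
        seed=42,
    )
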