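"""Vital-sign vocabulary shared by the whole package.

The measurement protocol interleaves a hospital-grade standard monitor with
the device under test: standard readings occupy slots 1, 3, 5 and 7,
investigational readings occupy slots 2, 4 and 6, so each investigational
reading is bounded by two standard readings taken one minute before and
after it.  Slot 0 is reserved for the pre-protocol cuff calibration reading
that calibration-dependent devices require.
"""

from __future__ import annotations

from enum import Enum


class Vital(str, Enum):
    """Vital signs the pipeline knows about."""

    SBP = "SBP"    # systolic blood pressure, mm Hg
    DBP = "DBP"    # diastolic blood pressure, mm Hg
    HR = "HR"      # heart rate, beats per minute
    SPO2 = "SPO2"  # peripheral oxygen saturation, %


class Role(str, Enum):
    """Who produced a measurement record."""

    STANDARD = "standard"
    INVESTIGATIONAL = "investigational"
    CALIBRATION = "calibration"


#: Physiologically plausible value ranges, used for input validation.
PLAUSIBLE_RANGE: dict[Vital, tuple[float, float]] = {
    Vital.SBP: (20.0, 300.0),
    Vital.DBP: (20.0, 300.0),
    Vital.HR: (20.0, 250.0),
    Vital.SPO2: (0.0, 100.0),
}

UNITS: dict[Vital, str] = {
    Vital.SBP: "mm Hg",
    Vital.DBP: "mm Hg",
    Vital.HR: "bpm",
    Vital.SPO2: "%",
}

STANDARD_SLOTS: tuple[int, ...] = (1, 3, 5, 7)
INVESTIGATIONAL_SLOTS: tuple[int, ...] = (2, 4, 6)
CALIBRATION_SLOT: int = 0
N_SLOTS: int = 7
#: Comparison pairs per subject per device-vital (one per investigational slot).
PAIRS_PER_SUBJECT: int = 3
#: Maximum attempts per investigational slot (first try plus two retries).
MAX_ATTEMPTS: int = 3


def quantize(x: float, resolution: float) -> float:
    """Round ``x`` to the nearest multiple of ``resolution``.

    Half-way cases round up (away from the lower multiple), so the result is
    deterministic and independent of the platform's banker's rounding.  A
    non-positive resolution disables rounding.
    """
    if resolution <= 0:
        return float(x)
    import math

    return float(math.floor(x / resolution + 0.5) * resolution)
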