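"""Virtual validation studies.

Generates measurement logs with the statistical structure the analysis
pipeline assumes: per subject, a latent vital-sign trajectory over the seven
protocol slots (a baseline draw plus a Gaussian random walk, emulating the
slow within-session drift that motivates the guideline exclusion rule), read
out by a noisy standard monitor at slots 1/3/5/7 and by one or more
investigational device models at slots 2/4/6 with up to three attempts per
slot.

Device models support an additive bias, a proportional bias (a slope pivoting
around an anchor value, which reproduces the "low readings estimated high,
high readings estimated low" failure mode), Gaussian read noise, Bernoulli
per-attempt failures, and — for cuffless blood-pressure devices — a
calibration coupling ``k``: the reading tracks the entered cuff calibration
value and follows only a fraction ``k`` of the true pressure change since
calibration.  ``k = 1`` is a device that genuinely tracks pressure, ``k = 0``
one that merely replays its calibration value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .errors import ConfigurationError
from .records import (
    CALIBRATION_COLUMNS,
    SCHEMA_VERSION,
    MeasurementRecord,
    StudyDataset,
    records_to_frame,
)
from .vitals import (
    CALIBRATION_SLOT,
    INVESTIGATIONAL_SLOTS,
    MAX_ATTEMPTS,
    N_SLOTS,
    STANDARD_SLOTS,
    Role,
    Vital,
    quantize,
)

#: Baseline population distributions (mean, SD) of the emulated cohort:
#: preadmission-clinic adults at rest.
DEFAULT_BASELINE_MEANS: dict[Vital, float] = {
    Vital.SBP: 125.0,
    Vital.DBP: 76.0,
    Vital.HR: 72.0,
    Vital.SPO2: 96.0,
}
DEFAULT_BASELINE_SDS: dict[Vital, float] = {
    Vital.SBP: 15.0,
    Vital.DBP: 9.0,
    Vital.HR: 12.0,
    Vital.SPO2: 2.0,
}
#: Per-slot random-walk SD of the latent trajectory.  Chosen, together with
#: the default standard-monitor noise, so that roughly 30% of simulated
#: subjects trip the guideline variation rule — a free parameter of the
#: simulator, documented in docs/methods.md.
DEFAULT_DRIFT_SD: dict[Vital, float] = {
    Vital.SBP: 3.0,
    Vital.DBP: 2.0,
    Vital.HR: 1.5,
    Vital.SPO2: 0.3,
}

_VITAL_ORDER = list(Vital)


def _clip_display(vital: Vital, raw: float) -> float:
    """Clamp a raw reading to the vital's displayable range."""
    from .vitals import PLAUSIBLE_RANGE

    lo, hi = PLAUSIBLE_RANGE[vital]
    return float(min(max(raw, lo), hi))


def _check_map(name: str, m: Mapping[Vital, float], nonneg: bool = False) -> None:
    for v, x in m.items():
        if not np.isfinite(x):
            raise ConfigurationError(f"{name}[{Vital(v).value}] is not finite: {x}")
        if nonneg and x < 0:
            raise ConfigurationError(f"{name}[{Vital(v).value}] must be >= 0, got {x}")


@dataclass
class CohortConfig:
    """Population and session-drift parameters of a virtual cohort."""

    n_subjects: int
    baseline_means: dict[Vital, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MEANS)
    )
    baseline_sds: dict[Vital, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_SDS)
    )
    drift_sd: dict[Vital, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT_SD))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        self.baseline_means = {Vital(k): float(v) for k, v in self.baseline_means.items()}
        self.baseline_sds = {Vital(k): float(v) for k, v in self.baseline_sds.items()}
        self.drift_sd = {Vital(k): float(v) for k, v in self.drift_sd.items()}
        _check_map("baseline_means", self.baseline_means)
        _check_map("baseline_sds", self.baseline_sds, nonneg=True)
        _check_map("drift_sd", self.drift_sd, nonneg=True)
        for v in self.baseline_means:
            if v not in self.baseline_sds:
                raise ConfigurationError(f"baseline_sds missing entry for {v.value}")

    @property
    def vitals(self) -> list[Vital]:
        return [v for v in _VITAL_ORDER if v in self.baseline_means]


@dataclass
class ReferenceModel:
    """Error model of the standard (hospital-grade) monitor.

    A stand-in for the validated reference monitor: unbiased Gaussian read
    noise and display quantisation.  The reference never fails.
    """

    name: str = "standard-monitor"
    noise_sd: dict[Vital, float] = field(
        default_factory=lambda: {
            Vital.SBP: 3.0,
            Vital.DBP: 2.5,
            Vital.HR: 2.0,
            Vital.SPO2: 1.0,
        }
    )
    resolution: dict[Vital, float] = field(
        default_factory=lambda: {v: 1.0 for v in Vital}
    )

    def __post_init__(self) -> None:
        self.noise_sd = {Vital(k): float(v) for k, v in self.noise_sd.items()}
        self.resolution = {Vital(k): float(v) for k, v in self.resolution.items()}
        _check_map("noise_sd", self.noise_sd, nonneg=True)

    def reading(self, vital: Vital, true_value: float, rng: np.random.Generator) -> float:
        raw = true_value + rng.normal(0.0, self.noise_sd.get(vital, 0.0))
        raw = _clip_display(vital, raw)
        return quantize(raw, self.resolution.get(vital, 1.0))


#: Investigational readings are reported at display resolution: whole mm Hg,
#: whole bpm, whole percent.
DEVICE_RESOLUTION = 1.0


@dataclass
class DeviceModel:
    """Error model of an investigational device.

    For a calibration-dependent device measuring SBP the reading is

        cal_reading + k * (true_now - true_at_calibration)
                    + slope * (true_now - anchor) + bias + noise

    rounded to display resolution; for everything else the leading term is
    simply ``true_now``.
    """

    name: str
    vitals_measured: frozenset[Vital] = frozenset()
    bias: dict[Vital, float] = field(default_factory=dict)
    slope: dict[Vital, float] = field(default_factory=dict)
    anchor: dict[Vital, float] = field(default_factory=dict)
    noise_sd: dict[Vital, float] = field(default_factory=dict)
    failure_prob: float = 0.0
    calibration_coupling: float = 1.0
    requires_calibration: bool = False

    def __post_init__(self) -> None:
        self.vitals_measured = frozenset(Vital(v) for v in self.vitals_measured)
        if not self.vitals_measured:
            raise ConfigurationError(f"device {self.name!r} measures no vitals")
        self.bias = {Vital(k): float(v) for k, v in self.bias.items()}
        self.slope = {Vital(k): float(v) for k, v in self.slope.items()}
        self.anchor = {Vital(k): float(v) for k, v in self.anchor.items()}
        self.noise_sd = {Vital(k): float(v) for k, v in self.noise_sd.items()}
        _check_map("bias", self.bias)
        _check_map("slope", self.slope)
        _check_map("anchor", self.anchor)
        _check_map("noise_sd", self.noise_sd, nonneg=True)
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ConfigurationError(
                f"failure_prob must be in [0, 1], got {self.failure_prob}"
            )
        if not 0.0 <= self.calibration_coupling <= 1.0:
            raise ConfigurationError(
                f"calibration_coupling must be in [0, 1], got {self.calibration_coupling}"
            )
        for v in self.slope:
            if self.slope[v] != 0.0 and v not in self.anchor:
                raise ConfigurationError(
                    f"device {self.name!r}: slope for {v.value} needs an anchor"
                )
        if self.requires_calibration and Vital.SBP not in self.vitals_measured:
            raise ConfigurationError(
                f"device {self.name!r} requires calibration but does not measure SBP"
            )

    def reading(
        self,
        vital: Vital,
        true_now: float,
        rng: np.random.Generator,
        cal_reading: float | None = None,
        true_at_calibration: float | None = None,
    ) -> float:
        if (
            self.requires_calibration
            and vital is Vital.SBP
            and cal_reading is not None
            and true_at_calibration is not None
        ):
            raw = cal_reading + self.calibration_coupling * (true_now - true_at_calibration)
        else:
            raw = true_now
        raw += self.slope.get(vital, 0.0) * (true_now - self.anchor.get(vital, 0.0))
        raw += self.bias.get(vital, 0.0)
        raw += rng.normal(0.0, self.noise_sd.get(vital, 0.0))
        raw = _clip_display(vital, raw)
        return quantize(raw, DEVICE_RESOLUTION)


def subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Independent, reproducible random stream for one subject.

    Child streams are keyed by subject index, so trajectories do not change
    when the cohort size does.
    """
    child = np.random.SeedSequence(seed, spawn_key=(subject_index,))
    return np.random.default_rng(child)


def generate_true_trajectory(
    config: CohortConfig,
    subject_index: int,
    rng: np.random.Generator | None = None,
) -> dict[Vital, np.ndarray]:
    """Latent per-slot true values for one subject.

    Slot 1 is the baseline draw; each later slot adds one Gaussian
    random-walk increment.  SpO2 baselines are drawn truncated to (0, 100]
    and the trajectory is clamped to at most 100%.
    """
    if rng is None:
        rng = subject_rng(config.seed, subject_index)
    out: dict[Vital, np.ndarray] = {}
    for vital in config.vitals:
        mean = config.baseline_means[vital]
        sd = config.baseline_sds[vital]
        baseline = float(rng.normal(mean, sd))
        if vital is Vital.SPO2:
            for _ in range(100):
                if 0.0 < baseline <= 100.0:
                    break
                baseline = float(rng.normal(mean, sd))
            baseline = min(max(baseline, 1e-6), 100.0)
        steps = rng.normal(0.0, config.drift_sd.get(vital, 0.0), N_SLOTS - 1)
        traj = baseline + np.concatenate([[0.0], np.cumsum(steps)])
        if vital is Vital.SPO2:
            traj = np.clip(traj, 1e-6, 100.0)
        if not np.all(np.isfinite(traj)):
            raise ConfigurationError("non-finite trajectory value generated")
        out[vital] = traj
    return out


def simulate_study(
    config: CohortConfig,
    reference: ReferenceModel | None = None,
    devices: Sequence[DeviceModel] = (),
    seed: int | None = None,
) -> StudyDataset:
    """Run one virtual study and return its measurement log.

    Per subject: a cuff calibration reading for every device that requires
    one (taken at the slot-1 time point), four standard readings per vital at
    slots 1/3/5/7, and up to three attempts per investigational slot per
    device-vital — each attempt fails independently with the device's
    ``failure_prob``; a success ends the slot, three failures leave it failed.
    All attempts, failed or not, are retained in the log.  Identical
    ``(config, seed)`` give byte-identical output.
    """
    import pandas as pd

    if reference is None:
        reference = ReferenceModel()
    devices = list(devices)
    if not devices:
        raise ConfigurationError("device list must not be empty")
    eff_seed = config.seed if seed is None else int(seed)

    study_vitals = [
        v for v in _VITAL_ORDER if any(v in d.vitals_measured for d in devices)
    ]
    for v in study_vitals:
        if v not in config.baseline_means:
            raise ConfigurationError(f"cohort config lacks a baseline for {v.value}")
    if any(d.requires_calibration for d in devices) and Vital.SBP not in config.baseline_means:
        raise ConfigurationError("calibration-dependent devices need an SBP baseline")

    records: list[MeasurementRecord] = []
    cal_rows: list[tuple[str, str, float]] = []

    for i in range(config.n_subjects):
        rng = subject_rng(eff_seed, i)
        sid = f"S{i + 1:04d}"
        truths = generate_true_trajectory(config, i, rng)

        cal_readings: dict[str, float] = {}
        for dev in devices:
            if dev.requires_calibration:
                true_cal = float(truths[Vital.SBP][0])
                cal = reference.reading(Vital.SBP, true_cal, rng)
                cal_readings[dev.name] = cal
                cal_rows.append((sid, dev.name, cal))
                records.append(
                    MeasurementRecord(
                        subject_id=sid,
                        vital=Vital.SBP,
                        role=Role.CALIBRATION,
                        device=dev.name,
                        slot=CALIBRATION_SLOT,
                        attempt=1,
                        value=cal,
                    )
                )

        for slot in range(1, N_SLOTS + 1):
            if slot in STANDARD_SLOTS:
                for vital in study_vitals:
                    records.append(
                        MeasurementRecord(
                            subject_id=sid,
                            vital=vital,
                            role=Role.STANDARD,
                            device=reference.name,
                            slot=slot,
                            attempt=1,
                            value=reference.reading(
                                vital, float(truths[vital][slot - 1]), rng
                            ),
                        )
                    )
            else:
                for dev in devices:
                    for vital in _VITAL_ORDER:
                        if vital not in dev.vitals_measured:
                            continue
                        for attempt in range(1, MAX_ATTEMPTS + 1):
                            fails = rng.random() < dev.failure_prob
                            if fails:
                                records.append(
                                    MeasurementRecord(
                                        subject_id=sid,
                                        vital=vital,
                                        role=Role.INVESTIGATIONAL,
                                        device=dev.name,
                                        slot=slot,
                                        attempt=attempt,
                                        failed=True,
                                    )
                                )
                                continue
                            value = dev.reading(
                                vital,
                                float(truths[vital][slot - 1]),
                                rng,
                                cal_reading=cal_readings.get(dev.name),
                                true_at_calibration=float(truths[Vital.SBP][0])
                                if dev.requires_calibration
                                else None,
                            )
                            records.append(
                                MeasurementRecord(
                                    subject_id=sid,
                                    vital=vital,
                                    role=Role.INVESTIGATIONAL,
                                    device=dev.name,
                                    slot=slot,
                                    attempt=attempt,
                                    value=value,
                                )
                            )
                            break

    calibrations = pd.DataFrame(cal_rows, columns=CALIBRATION_COLUMNS)
    provenance = {
        "source": "vitalval.synthetic",
        "generator_version": _pkg_version,
        "seed": eff_seed,
        "n_subjects": config.n_subjects,
        "schema_version": SCHEMA_VERSION,
    }
    return StudyDataset(
        records=records_to_frame(records),
        calibrations=calibrations,
        provenance=provenance,
    )
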