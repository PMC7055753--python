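"""File formats: measurement/calibration CSVs and the YAML study config.

Measurement CSV (RFC 4180, UTF-8, dot decimal), one row per reading or
failed attempt::

    subject_id,vital,role,device,slot,attempt,value,failed

Units are fixed by column convention (mm Hg for SBP/DBP, bpm for HR, % for
SpO2).  Failed attempts leave ``value`` empty and set ``failed`` to true.
Calibration CSV: ``subject_id,device,calibration_value``.

The study config is a single YAML file with up to four blocks — ``cohort``,
``reference``, ``devices`` and ``analysis`` — whose keys mirror the
corresponding dataclass fields; missing blocks fall back to package
defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import DatasetValidationError
from .records import (
    CALIBRATION_COLUMNS,
    RECORD_COLUMNS,
    SCHEMA_VERSION,
    StudyDataset,
    validate_record_frame,
)
from .synthetic import CohortConfig, DeviceModel, ReferenceModel
from .vitals import PLAUSIBLE_RANGE, Vital


def read_measurements(
    records_path: str | Path,
    calibrations_path: str | Path | None = None,
) -> StudyDataset:
    """Read and validate a measurement CSV (plus optional calibration CSV).

    Every schema violation is collected with its 1-based data-row number and
    the whole file is rejected via :class:`DatasetValidationError` if any row
    is bad.
    """
    df = pd.read_csv(records_path, dtype={"subject_id": str, "device": str})
    if "failed" in df.columns:
        df["failed"] = (
            df["failed"].astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
        )
    errors = validate_record_frame(df)
    if errors:
        raise DatasetValidationError(errors)
    df = df[RECORD_COLUMNS].copy()
    df["slot"] = df["slot"].astype(int)
    df["attempt"] = df["attempt"].astype(int)
    df["value"] = df["value"].astype(float)
    df["failed"] = df["failed"].astype(bool)

    calibrations = pd.DataFrame(columns=CALIBRATION_COLUMNS)
    if calibrations_path is not None:
        calibrations = pd.read_csv(
            calibrations_path, dtype={"subject_id": str, "device": str}
        )
        cal_errors = []
        missing = [c for c in CALIBRATION_COLUMNS if c not in calibrations.columns]
        if missing:
            cal_errors.append(f"calibration file missing column(s): {', '.join(missing)}")
        else:
            lo, hi = PLAUSIBLE_RANGE[Vital.SBP]
            for i, v in enumerate(calibrations["calibration_value"], start=1):
                if pd.isna(v) or not lo <= float(v) <= hi:
                    cal_errors.append(
                        f"calibration row {i}: value {v} outside plausible SBP range [{lo}, {hi}]"
                    )
        if cal_errors:
            raise DatasetValidationError(cal_errors)
    return StudyDataset(
        records=df,
        calibrations=calibrations,
        provenance={"source": "external", "schema_version": SCHEMA_VERSION},
    )


def write_measurements(dataset: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset to ``out_dir`` as CSVs plus a provenance JSON.

    Output is deterministic: the same dataset writes byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "measurements.csv",
        "calibrations": out / "calibrations.csv",
        "provenance": out / "provenance.json",
    }
    dataset.records.to_csv(paths["records"], index=False)
    dataset.calibrations.to_csv(paths["calibrations"], index=False)
    paths["provenance"].write_text(
        json.dumps(dataset.provenance, indent=2, sort_keys=True) + "\n"
    )
    return paths


# ---------------------------------------------------------------------------
# Study config


def _vital_map(d: dict | None) -> dict[Vital, float]:
    return {Vital(k.upper()): float(v) for k, v in (d or {}).items()}


def load_study_config(path: str | Path):
    """Parse a YAML study config into simulator + analysis objects.

    Returns ``(cohort, reference, devices, analysis)``; see
    :func:`default_study_config` for the shape.  The ``analysis`` element is
    an :class:`~vitalval.pipeline.AnalysisConfig`.
    """
    from .pipeline import AnalysisConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_raw = dict(raw.get("cohort", {}))
    for key in ("baseline_means", "baseline_sds", "drift_sd"):
        if key in cohort_raw:
            cohort_raw[key] = _vital_map(cohort_raw[key])
    cohort = CohortConfig(**cohort_raw) if cohort_raw else None

    ref_raw = dict(raw.get("reference", {}))
    for key in ("noise_sd", "resolution"):
        if key in ref_raw:
            ref_raw[key] = _vital_map(ref_raw[key])
    reference = ReferenceModel(**ref_raw)

    devices = []
    for dev_raw in raw.get("devices", []):
        dev_raw = dict(dev_raw)
        dev_raw["vitals_measured"] = frozenset(
            Vital(v.upper()) for v in dev_raw.pop("vitals", dev_raw.pop("vitals_measured", []))
        )
        for key in ("bias", "slope", "anchor", "noise_sd"):
            if key in dev_raw:
                dev_raw[key] = _vital_map(dev_raw[key])
        devices.append(DeviceModel(**dev_raw))

    analysis = AnalysisConfig(**raw.get("analysis", {}))
    return cohort, reference, devices, analysis


def default_study_config() -> dict:
    """A study-shaped example config: a calibration-dependent tricorder-like
    device and a noisy watch-like device, over the default cohort."""
    return {
        "cohort": {
            "n_subjects": 127,
            "seed": 0,
        },
        "reference": {},
        "devices": [
            {
                "name": "tricorder",
                "vitals": ["SBP", "HR", "SPO2"],
                "bias": {"SBP": 2.0, "HR": 0.5, "SPO2": 1.0},
                "noise_sd": {"SBP": 4.0, "HR": 2.0, "SPO2": 2.5},
                "failure_prob": 0.37,
                "requires_calibration": True,
                "calibration_coupling": 0.5,
            },
            {
                "name": "watch",
                "vitals": ["SBP", "DBP", "HR"],
                "slope": {"SBP": -0.5, "DBP": -0.4},
                "anchor": {"SBP": 125.0, "DBP": 76.0},
                "bias": {"HR": -2.0},
                "noise_sd": {"SBP": 12.0, "DBP": 7.0, "HR": 8.0},
                "failure_prob": 0.67,
            },
        ],
        "analysis": {},
    }


def write_default_config(path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(default_study_config(), sort_keys=False))
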