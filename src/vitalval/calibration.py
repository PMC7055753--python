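"""Calibration-dependence analysis for cuffless blood-pressure devices.

A cuffless device calibrated once against a cuff may degrade as the true
pressure departs from the calibration value.  Two formulations of the
post-hoc check are implemented as named variants:

* ``"text"`` (default): x = |reference - calibration|,
  y = |reference - investigational| — does the device's absolute error grow
  with the distance of the current pressure from the calibration value?
* ``"figure"``: x = reference - calibration, y = investigational -
  calibration — signed excursions from the calibration value, where a device
  that truly tracks pressure falls on the identity line.

Both use the package's normality-gated correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import MissingCalibrationError
from .stats import CorrelationResult, _gated_correlation
from .vitals import Vital

Variant = Literal["text", "figure"]


@dataclass
class CalibrationDependence:
    variant: str
    result: CorrelationResult
    points: pd.DataFrame  # subject_id, x, y (one row per pair or per subject)
    per_subject_mean: bool = False


def calibration_dependence(
    pairs: pd.DataFrame,
    calibrations: Mapping[str, float] | pd.DataFrame,
    variant: Variant = "text",
    per_subject_mean: bool = False,
    alpha: float = 0.05,
) -> CalibrationDependence:
    """Correlate device error with distance from the calibration value.

    ``pairs`` is a comparison-pair table (SBP rows of one device) with
    columns ``subject_id, investigational_value, reference_value``;
    ``calibrations`` maps subject_id to the cuff calibration value.  By
    default every pair contributes one point; ``per_subject_mean`` collapses
    each subject's points to their mean before correlating.
    """
    if variant not in ("text", "figure"):
        raise ValueError(f"unknown variant {variant!r}")
    if isinstance(calibrations, pd.DataFrame):
        calibrations = dict(
            zip(
                calibrations["subject_id"].astype(str),
                calibrations["calibration_value"].astype(float),
            )
        )
    subjects = pairs["subject_id"].astype(str)
    missing = sorted(set(subjects) - set(calibrations))
    if missing:
        raise MissingCalibrationError(missing)

    cal = subjects.map(calibrations).to_numpy(dtype=float)
    inv = pairs["investigational_value"].to_numpy(dtype=float)
    ref = pairs["reference_value"].to_numpy(dtype=float)
    if variant == "text":
        x = np.abs(ref - cal)
        y = np.abs(ref - inv)
    else:
        x = ref - cal
        y = inv - cal
    points = pd.DataFrame({"subject_id": subjects.to_numpy(), "x": x, "y": y})
    if per_subject_mean:
        points = points.groupby("subject_id", as_index=False)[["x", "y"]].mean()
    result = _gated_correlation(points["x"].to_numpy(), points["y"].to_numpy(), alpha)
    return CalibrationDependence(
        variant=variant, result=result, points=points, per_subject_mean=per_subject_mean
    )
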