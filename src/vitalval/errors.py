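"""Exception hierarchy."""

from __future__ import annotations


class VitalValError(Exception):
    """Base class for package errors."""


class ConfigurationError(VitalValError, ValueError):
    """A simulator or analysis configuration is invalid."""


class DatasetValidationError(VitalValError, ValueError):
    """A measurement file failed schema validation.

    ``errors`` holds one human-readable message per offending row, each
    prefixed with the 1-based data-row number.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} validation error(s): {preview}{more}")


class MissingStandardError(VitalValError, ValueError):
    """A subject lacks the four standard readings needed for pairing."""


class MissingCalibrationError(VitalValError, ValueError):
    """Paired subjects lack a calibration value."""

    def __init__(self, subjects: list[str]):
        self.subjects = list(subjects)
        super().__init__(
            "missing calibration value for subject(s): " + ", ".join(self.subjects)
        )


class NoAnalyzableSubjectsError(VitalValError, ValueError):
    """Every subject was excluded or unusable; nothing to analyze."""


class EmptyInputError(VitalValError, ValueError):
    """A statistic was requested on an empty collection of pairs."""
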