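"""Exception and warning hierarchy."""


class PredsliceError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PredsliceError, ValueError):
    """An input violates a precondition (out of range, wrong sign, non-finite)."""


class DegenerateInputError(PredsliceError, ValueError):
    """The input is structurally unusable (zero variance, monomorphic markers, ...)."""


class RankDeficiencyError(PredsliceError, ValueError):
    """The fixed-effect block of the mixed-model equations is singular."""


class UnadjustableRecordError(PredsliceError, ValueError):
    """A validation record has a fixed-effect level with no estimate."""


class CalibrationError(PredsliceError, RuntimeError):
    """The composite-trait calibration could not reach its target."""


class ClampWarning(UserWarning):
    """An estimate fell outside its natural range and was clamped."""


class InflatedAccuracyWarning(ClampWarning):
    """Predictivity-implied accuracy exceeded 1; usually a sign that Me or N is off."""
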