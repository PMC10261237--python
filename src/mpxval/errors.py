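"""Exception and warning types shared across the package."""


class MpxvalError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MpxvalError, ValueError):
    """Invalid configuration (bad probabilities, non-positive sizes, ...)."""


class InsufficientDataError(MpxvalError, ValueError):
    """Not enough data to perform the requested computation."""


class CalibrationError(MpxvalError, ValueError):
    """Calibration fit failed QC (e.g. non-negative slope)."""


class InvalidSampleError(MpxvalError, ValueError):
    """A sample cannot be quantified (control-gene failure)."""


class AmbiguousBandError(MpxvalError, ValueError):
    """A gel band matches more than one expected fragment size."""


class DegenerateClassesError(MpxvalError, ValueError):
    """Both index-test classes must be present for AUC estimation."""


class SchemaError(MpxvalError, ValueError):
    """An input file violates the expected tabular schema."""


class EfficiencyWarning(UserWarning):
    """Amplification efficiency outside the accepted QC window."""


class DuplicateCutoffWarning(UserWarning):
    """Duplicate cutoffs in a sweep grid were collapsed."""


class MultipleFusionBandsWarning(UserWarning):
    """More than one fusion band observed in a single lane."""
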