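"""Exception hierarchy shared across the pipeline."""


class MvsmlmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MvsmlmError):
    """Inconsistent pipeline configuration (shapes, geometry, thresholds)."""


class CalibrationError(MvsmlmError):
    """Invalid camera calibration or PSF calibration input."""


class RegistrationError(MvsmlmError):
    """Degenerate or underdetermined inter-camera registration."""


class FitError(MvsmlmError):
    """Numerical failure inside an MLE fit or CRB computation."""


class ParseError(MvsmlmError):
    """Malformed movie, table or model file."""


class ZRangeError(FitError):
    """Axial position outside a spline PSF's calibrated z range."""
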