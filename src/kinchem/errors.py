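"""Shared exception types."""


class KinchemError(Exception):
    """Base class for package errors."""


class FormatError(KinchemError, ValueError):
    """Malformed input file or matrix."""


class SampleLookupError(KinchemError, KeyError):
    """Unknown sample or population label."""


class JackknifeError(KinchemError, ValueError):
    """Block jackknife cannot be computed (fewer than two non-empty blocks)."""


class EmptyStatisticError(KinchemError, ValueError):
    """No usable SNPs for a statistic."""


class BaselineError(KinchemError, ValueError):
    """Degenerate or missing mismatch-rate baselines."""


class CalibrationError(KinchemError, ValueError):
    """Invalid one-point calibration input."""


class GeometryError(KinchemError, ValueError):
    """Invalid scan geometry or ROI polygon."""


class PhantomError(KinchemError, ValueError):
    """Invalid phantom layout."""


class WindowError(KinchemError, ValueError):
    """Blank window inconsistent with the scan length."""


class ConfigurationError(KinchemError, ValueError):
    """Missing or invalid run configuration."""
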