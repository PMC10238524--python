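"""Exception hierarchy for mvmar."""


class MvmarError(Exception):
    """Base class for all mvmar errors."""


class GeometryError(MvmarError, ValueError):
    """Image / sinogram shape does not match the scan geometry."""


class ValidationError(MvmarError, ValueError):
    """Invalid input values (non-finite data, bad parameters, unknown labels)."""


class ConfigurationError(MvmarError, ValueError):
    """Unknown filter names, malformed configuration files, bad option values."""


class DegenerateInputError(MvmarError, ValueError):
    """Too few distinct gray values for a well-posed multi-class threshold.

    Raised by the Otsu routines; block-wise segmentation catches it and
    falls back to global-image thresholds.
    """


class UndefinedMetricError(MvmarError, ZeroDivisionError):
    """A fidelity metric is undefined (zero reference mean / zero-energy ROI)."""
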