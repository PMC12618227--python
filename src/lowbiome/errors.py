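"""Exception types shared across the pipeline stages."""


class LowbiomeError(Exception):
    """Base class for all package errors."""


class ConfigError(LowbiomeError):
    """A simulation or pipeline configuration field is invalid.

    The message always names the offending field.
    """


class PackingError(LowbiomeError):
    """Cells could not be packed at the requested density."""


class ThresholdError(LowbiomeError):
    """A data-driven threshold could not be derived (underdetermined input)."""


class GeometryError(LowbiomeError):
    """Spatial geometry is inconsistent (e.g. cell area exceeds the FOV area)."""


class EmptyResultError(LowbiomeError):
    """A filter removed every row/column, leaving nothing to analyze."""


class AnnotationError(LowbiomeError):
    """Too few observations to annotate (e.g. quartile labels need >= 4 ROIs)."""
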