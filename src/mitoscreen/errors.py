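"""Exception hierarchy shared across the package."""


class MitoscreenError(Exception):
    """Base class for all package-specific errors."""


class GenerationError(MitoscreenError):
    """A synthetic-data generator could not satisfy its constraints."""


class FormatError(MitoscreenError):
    """An input file or array does not match the expected layout."""


class ValidationError(MitoscreenError):
    """A table or annotation set failed schema validation."""


class DegenerateGeometryError(MitoscreenError):
    """Geometric input is degenerate (collinear points, zero vectors...)."""


class UndefinedRatioError(MitoscreenError):
    """A ratio is undefined because its denominator is zero or negative."""


class TrainingError(MitoscreenError):
    """Classifier training input violates its preconditions."""


class DegenerateDataError(MitoscreenError):
    """A statistic is undefined on this data (e.g. zero spread)."""
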