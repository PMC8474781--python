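"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
ModelError -> 4.
"""


class MitotickError(Exception):
    """Base class for all package errors."""


class ConfigError(MitotickError):
    """Invalid configuration (simulation config, model spec, clock file)."""


class DataError(MitotickError):
    """Malformed or inconsistent input data."""


class FormatError(DataError):
    """A file violates its declared format (duplicate IDs, bad header...)."""


class ParseError(DataError):
    """A cell could not be parsed; message carries row/column context."""


class AlignmentError(DataError):
    """No overlap between a beta matrix and its sample sheet."""


class CoverageError(DataError):
    """Too few clock/predictor CpGs present in the matrix."""


class DegenerateDataError(DataError):
    """Zero-variance input where variance is required."""


class ModelError(MitotickError):
    """Statistical model could not be estimated."""


class CollinearityError(ModelError):
    """Rank-deficient design matrix; message lists aliased columns."""


class SeparationError(ModelError):
    """Perfect separation in a logistic fit (monotone likelihood)."""
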