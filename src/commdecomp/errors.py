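"""Exception hierarchy for commdecomp."""


class CommdecompError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CommdecompError):
    """Invalid scenario or run configuration."""


class InputError(CommdecompError):
    """Malformed or inconsistent input data."""


class ImputationError(CommdecompError):
    """A missing trait cell cannot be imputed; the message names the cell."""


class DegenerateDistanceError(CommdecompError):
    """Distance matrix has no positive principal-coordinate eigenvalue."""


class UndefinedStatisticError(CommdecompError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
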