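"""Exception hierarchy shared across the pipeline modules."""


class PefriskError(Exception):
    """Base class for all package errors."""


class ConfigError(PefriskError):
    """Invalid configuration value."""


class CohortParseError(PefriskError):
    """A cohort CSV cell could not be parsed; message names row and column."""


class DataError(PefriskError):
    """Input data violates a precondition (empty history, single class, ...)."""
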