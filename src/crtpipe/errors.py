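"""Exception hierarchy shared across the pipeline.

The CLI maps these onto process exit codes (schema 2, insufficient data 3,
configuration/parameter 4).
"""


class CrtPipeError(Exception):
    """Base class for all crtpipe errors."""


class SchemaError(CrtPipeError):
    """A recording or table violates the documented file schema or a
    data-model invariant.  The message names the offending column/row."""


class InsufficientDataError(CrtPipeError):
    """Too few samples/events to carry out the requested computation."""


class ConfigError(CrtPipeError):
    """Invalid pipeline configuration."""


class ParameterError(CrtPipeError):
    """Degenerate or out-of-range simulation/scheme parameters."""


class UndefinedCorrelationError(InsufficientDataError):
    """Correlation undefined (zero variance or too few pairs)."""
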