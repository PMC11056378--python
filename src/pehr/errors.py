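"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2,
DataValidationError -> 3, ModelFitError -> 4.
"""


class PehrError(Exception):
    """Base class for all package errors."""


class ConfigError(PehrError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class DataValidationError(PehrError, ValueError):
    """Malformed or inconsistent input data."""


class ModelFitError(PehrError, RuntimeError):
    """A statistical model failed to fit (non-convergence, separation, ...)."""
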