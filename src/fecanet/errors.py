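"""Shared exception types for pipeline stages."""


class ConfigurationError(ValueError):
    """A stage cannot run with the given table/configuration."""


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested quantity."""


class DegenerateDataError(ValueError):
    """Input is degenerate (constant column, zero variance, ...)."""
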