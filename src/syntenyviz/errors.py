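"""Exception types shared across the package."""


class SyntenyVizError(Exception):
    """Base class for all package errors."""


class FormatError(SyntenyVizError, ValueError):
    """A data file (or in-memory value) violates a format contract."""


class ConfigError(SyntenyVizError, ValueError):
    """A converter field specification, plot config, or view state is invalid."""
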