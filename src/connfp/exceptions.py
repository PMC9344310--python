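"""Exception hierarchy."""


class ConnfpError(Exception):
    """Base class for all package errors."""


class FormatError(ConnfpError):
    """A file could not be parsed as the expected plain-text format."""


class ValidationError(ConnfpError):
    """Parsed data violates a structural invariant."""


class ConfigError(ConnfpError):
    """An analysis configuration is invalid or incomplete."""
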