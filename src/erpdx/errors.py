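"""Exception hierarchy shared across the package."""


class ErpdxError(Exception):
    """Base class for all package errors."""


class FormatError(ErpdxError):
    """A file does not match the expected tabular schema."""


class ValidationError(ErpdxError):
    """A domain invariant is violated (unknown channel, bad interval, ...)."""


class CoverageError(ErpdxError):
    """A waveform does not cover the analysis interval of its condition."""


class ConfigError(ErpdxError):
    """An invalid configuration value."""
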