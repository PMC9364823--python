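"""Exception types shared across the pipeline stages."""


class RiliError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(RiliError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class FormatError(RiliError, ValueError):
    """An input file does not satisfy its declared format contract."""


class EmptyResultError(RiliError, RuntimeError):
    """An operation removed every record; carries diagnostic counts."""

    def __init__(self, message: str, **counts):
        super().__init__(message)
        self.counts = dict(counts)


class DependencyError(RiliError, RuntimeError):
    """A pipeline stage was requested before its upstream artifacts exist."""
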