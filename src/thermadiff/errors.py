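"""Exception hierarchy shared by all pipeline stages."""


class ThermadiffError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ThermadiffError, ValueError):
    """Invalid configuration (bad counts, negative SDs, injury outside span...)."""


class StreamFormatError(ThermadiffError, ValueError):
    """A stream file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StreamValidationError(ThermadiffError, ValueError):
    """A parsed stream violates the data-model invariants."""


class UnsupportedStreamError(ThermadiffError, ValueError):
    """Stream shape outside the supported domain (e.g. one foot never worn)."""


class WindowError(ThermadiffError, ValueError):
    """Analysis-window extraction failed (insufficient minutes, bad span)."""


class StatsError(ThermadiffError, ValueError):
    """Degenerate input to a statistical routine."""
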