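"""Exception hierarchy shared across the package."""


class SleepsoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SleepsoError):
    """A file could not be parsed into the expected container."""


class ValidationError(SleepsoError):
    """An object violates its declared invariants."""


class ParameterError(SleepsoError):
    """A parameter is outside its admissible range."""


class InsufficientDataError(SleepsoError):
    """Not enough data to perform the requested computation."""


class DegenerateEventError(SleepsoError):
    """An event segment is too short or flat to be measured."""
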