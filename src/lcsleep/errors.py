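"""Exception hierarchy.

Validation errors (bad parameters/config) and data errors (bad signal
content) are kept distinct so the CLI can map them to exit codes 2 and 3.
"""


class LCSleepError(Exception):
    """Base class for all package errors."""


class ValidationError(LCSleepError):
    """A parameter or configuration value violates a precondition."""


class FormatError(LCSleepError):
    """An input file does not conform to the expected layout."""


class DataError(LCSleepError):
    """Input data content is invalid (wrong shapes, non-monotone time, ...)."""


class InsufficientDataError(DataError):
    """Recording too short for the requested analysis."""


class DegenerateSignalError(DataError):
    """Constant / all-zero signal, e.g. a flat or disconnected sensor."""


class FixtureError(LCSleepError):
    """A packaged reference table is missing or corrupted."""
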