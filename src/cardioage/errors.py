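"""Exception hierarchy shared across the package.

The distinction matters for the command-line interface, which maps each
class to its own exit code so batch callers can tell a bad config from a
bad input file or a degenerate statistic.
"""


class CardioAgeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardioAgeError):
    """A config object is invalid; the message names the offending field."""


class InputError(CardioAgeError):
    """Caller-supplied data is unusable (empty text, missing file, ...)."""


class DegenerateStatisticsError(CardioAgeError):
    """A statistic is undefined on the given data (e.g. single-class AUC)."""
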