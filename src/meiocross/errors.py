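"""Exception hierarchy.

Readers and estimators reject malformed input rather than coercing it; every
error names the offending record where one exists.
"""


class MeiocrossError(Exception):
    """Base class for all package errors."""


class ParameterError(MeiocrossError, ValueError):
    """A simulation or estimator parameter is out of its admissible range."""


class DataError(MeiocrossError, ValueError):
    """An input record violates the format or a biological invariant."""


class UndefinedCoCError(MeiocrossError, ValueError):
    """Coefficient of coincidence undefined (no recombinants in an interval).

    Carries the offending counts so callers can report them.
    """

    def __init__(self, message: str, counts=None):
        super().__init__(message)
        self.counts = counts


class DegenerateTestError(MeiocrossError, ValueError):
    """A hypothesis test cannot be computed (e.g. pooled proportion 0 or 1)."""


class ConfigError(MeiocrossError, ValueError):
    """A run configuration is inconsistent or references missing files."""
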