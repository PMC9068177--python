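"""Exception hierarchy for the bcrisk pipeline.

Every stage raises a subclass of :class:`BcriskError`, so callers can catch
pipeline failures without masking programming errors.
"""


class BcriskError(Exception):
    """Base class for all bcrisk errors."""


class SchemaError(BcriskError):
    """A column is missing, a factor set is misaligned, or a code is illegal."""


class ParseError(BcriskError):
    """A cell could not be parsed as an integer code.

    Carries the 1-based data row number in :attr:`row`.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DegenerateFactorError(BcriskError):
    """A factor's normalization divisor is zero."""


class DomainError(BcriskError):
    """A numeric argument is outside its mathematical domain."""


class BalanceError(BcriskError):
    """A balancing operation cannot be performed (single class, empty result)."""


class CalibrationError(BcriskError):
    """The synthetic outcome model could not reach the target prevalence."""


class ConfigError(BcriskError):
    """A configuration file or option set is malformed."""


class ProtocolError(BcriskError):
    """An evaluation protocol is infeasible (e.g. folds exceed minority size)."""


class FitError(BcriskError):
    """Tree induction received empty or inconsistent training data."""
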