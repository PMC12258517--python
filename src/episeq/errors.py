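"""Exception hierarchy.

Input problems (bad files, bad parameters) and computation problems
(degenerate statistics) are distinct branches so callers — and the CLI
exit codes — can tell them apart.
"""


class EpiseqError(Exception):
    """Base class for all package errors."""


class ParameterError(EpiseqError, ValueError):
    """An argument is outside its documented range; names the offending field."""


class FormatError(EpiseqError, ValueError):
    """A file does not match the expected layout; names the missing piece."""


class DataError(EpiseqError, ValueError):
    """Input data violates an invariant (duplicate genes, empty join, ...)."""


class InsufficientDataError(DataError):
    """Too few usable observations for the requested statistic."""


class DegenerateNullError(EpiseqError, ArithmeticError):
    """The bootstrap null distribution has zero spread; a Z-score is undefined."""


class SingularFitError(EpiseqError, ArithmeticError):
    """The regression design is singular (zero predictor variance)."""


class DegenerateTableError(DataError):
    """A contingency table has a zero margin; expected counts are undefined."""
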