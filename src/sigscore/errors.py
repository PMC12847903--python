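"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems exit with 2,
insufficient data with 3.
"""


class SigScoreError(Exception):
    """Base class for all package errors."""


class ValidationError(SigScoreError, ValueError):
    """Invalid input values, malformed files, or violated invariants."""


class CatalogError(ValidationError):
    """A SIG catalog violates one of its structural invariants."""


class InsufficientDataError(SigScoreError):
    """Too few samples / observations to run the requested analysis."""


class DegenerateSplitError(InsufficientDataError):
    """A group split left one arm empty."""


class UndefinedStatisticError(SigScoreError):
    """The requested statistic is undefined on this input (e.g. constant ranks,
    a fully censored cohort)."""
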