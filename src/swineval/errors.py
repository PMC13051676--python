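"""Exception hierarchy shared across the package.

Validation failures are raised, never clamped: a probability outside
[0, 1] or a missing exchange rate in a cost ledger indicates a broken
configuration, and silently repairing it would corrupt downstream
economics.
"""


class SwinevalError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SwinevalError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(SwinevalError, ValueError):
    """A configuration file or parameter set fails validation."""


class InsufficientDataError(SwinevalError, ValueError):
    """Too few observations to carry out a statistical procedure."""


class SeparationError(SwinevalError, RuntimeError):
    """Complete separation: a maximum-likelihood logit fit does not exist."""

    def __init__(self, term: str, message: str | None = None):
        self.term = term
        super().__init__(message or f"complete separation involving term {term!r}")


class RankDeficiencyError(SwinevalError, RuntimeError):
    """The design matrix is rank deficient."""

    def __init__(self, columns, message: str | None = None):
        self.columns = list(columns)
        super().__init__(
            message or f"design matrix is rank deficient; collinear terms: {self.columns}"
        )
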