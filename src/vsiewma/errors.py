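"""Exception hierarchy for chart construction and evaluation."""


class VsiEwmaError(Exception):
    """Base class for all package errors."""


class DomainError(VsiEwmaError, ValueError):
    """An argument lies outside its mathematical domain."""


class InvalidDesignError(VsiEwmaError, ValueError):
    """Chart design parameters violate their invariants (e.g. W >= K)."""


class ResolutionError(VsiEwmaError, ValueError):
    """Markov-chain state resolution below the supported floor."""


class ConditioningError(VsiEwmaError, ArithmeticError):
    """(I - Q) is singular or too ill-conditioned to solve reliably."""


class InsufficientDataError(VsiEwmaError, ValueError):
    """Not enough observations for Phase I estimation."""


class DataError(VsiEwmaError, ValueError):
    """Invalid observation values (e.g. nonpositive waiting times)."""


class InfeasibleDesignError(VsiEwmaError, RuntimeError):
    """No (K, W) satisfies the design constraints at this grid point."""


class OptimizationError(VsiEwmaError, RuntimeError):
    """The design search found no feasible grid point at all."""


class ConfigurationError(VsiEwmaError, ValueError):
    """Invalid quadrature or search configuration."""
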