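"""Exception hierarchy for neoglyc.

ValidationError maps to CLI exit code 1, everything else to 2.
"""


class NeoglycError(Exception):
    """Base class for package errors."""


class ValidationError(NeoglycError, ValueError):
    """Invalid input data or configuration."""


class InsufficientDataError(ValidationError):
    """Not enough measurements/transition pairs for the requested operation."""


class IntegrationError(NeoglycError, RuntimeError):
    """ODE integration failed or produced non-finite state."""


class NoSteadyStateError(NeoglycError, ArithmeticError):
    """The requested steady state does not exist (e.g. insulin input exceeds
    the saturating clearance capacity)."""
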