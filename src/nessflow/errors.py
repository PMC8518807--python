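"""Exception hierarchy for nessflow."""


class NessflowError(Exception):
    """Base class for all package errors."""


class NetworkParseError(NessflowError):
    """Raised when a network description file cannot be parsed.

    Carries the 1-based line number when one is known.
    """

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class NetworkValidationError(NessflowError):
    """Raised when a parsed network violates a structural invariant."""


class DomainError(NessflowError):
    """Raised when an operation is evaluated outside its domain
    (e.g. negative concentrations)."""


class ThermodynamicallyIncompleteError(NessflowError):
    """Raised by thermodynamic operations on networks containing strictly
    irreversible reactions: the affinity RT*ln(v_f/v_r) is undefined when
    a reverse partner is missing."""


class UndefinedAffinityError(NessflowError):
    """Raised when a forward or reverse unidirectional rate is zero so the
    affinity of the pair diverges."""


class WegscheiderError(NessflowError):
    """Raised when rate constants are inconsistent with detailed balance
    (Wegscheider cycle conditions), so no reference equilibrium exists."""


class IntegrationError(NessflowError):
    """Raised when the ODE solver fails; carries the last valid state."""

    def __init__(self, message, t=None, last_state=None):
        super().__init__(message)
        self.t = t
        self.last_state = last_state
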