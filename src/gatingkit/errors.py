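"""Exception hierarchy for gatingkit."""


class GatingKitError(Exception):
    """Base class for all gatingkit errors."""


class SchemeNotFoundError(GatingKitError, KeyError):
    """Requested builtin kinetic scheme id is unknown."""


class SchemeValidationError(GatingKitError, ValueError):
    """A kinetic scheme violates a structural invariant."""


class UnresolvedRateError(GatingKitError, KeyError):
    """An edge references a rate name with no value."""


class ReducibleChainError(GatingKitError, ValueError):
    """The chain is reducible at the requested concentration.

    Carries ``blocks``: the strongly connected components found, as lists of
    state labels, so callers can see which block is disconnected.
    """

    def __init__(self, message, blocks=None):
        super().__init__(message)
        self.blocks = blocks or []


class ResolutionError(GatingKitError, ValueError):
    """Sampling interval or dead time incompatible with the data."""


class EmptyRecordError(GatingKitError, ValueError):
    """No dwell survives resolution imposition."""


class SingularFitError(GatingKitError, ValueError):
    """Degenerate data make the requested fit singular."""


class NoSeparationError(GatingKitError, ValueError):
    """Adjacent mixture components overlap: no critical-time root in bracket."""


class NonIdentifiableError(GatingKitError, ValueError):
    """Data carry no information about the requested parameters."""


class InsufficientDataError(GatingKitError, ValueError):
    """Too few samples or events for the requested analysis."""


class ProtocolError(GatingKitError, ValueError):
    """An experimental-protocol contract is violated (e.g. missing bracket)."""


class ConvergenceError(GatingKitError, RuntimeError):
    """No optimization start converged; carries the per-start record."""

    def __init__(self, message, starts=None):
        super().__init__(message)
        self.starts = starts or []
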