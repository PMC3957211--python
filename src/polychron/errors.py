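"""Exception hierarchy for the polychron simulator."""


class PolychronError(Exception):
    """Base class for all package-specific errors."""


class CodeSpecError(PolychronError, ValueError):
    """Invalid constant-weight code specification (weight must satisfy 0 < N < M)."""


class CodeLookupError(PolychronError, LookupError):
    """Encode/decode of an out-of-range index or an invalid codeword."""


class BusOverlapError(PolychronError, ValueError):
    """Events too close together to be separable on the asynchronous bus."""


class BusOverflowError(PolychronError, RuntimeError):
    """Synchroniser FIFO overflowed; ``dropped`` counts the lost entries."""

    def __init__(self, dropped: int, message: str | None = None):
        self.dropped = dropped
        super().__init__(message or f"FIFO overflow: {dropped} entries dropped")


class SequencingError(PolychronError, ValueError):
    """Events presented out of time order to an event-driven component."""


class CapacityError(PolychronError, RuntimeError):
    """Axon array exhausted during training; ``pattern_index`` names the offender."""

    def __init__(self, pattern_index: int | None = None, message: str | None = None):
        self.pattern_index = pattern_index
        super().__init__(
            message
            or f"axon array capacity exhausted while training pattern {pattern_index}"
        )


class ProgrammingError(PolychronError, ValueError):
    """Requested axonal delay is non-positive or exceeds the ramp range."""


class RoutingError(PolychronError, LookupError):
    """Address outside the domain of a router look-up table."""


class InternalStateError(PolychronError, RuntimeError):
    """Inconsistent neuron/controller state (e.g. fire from an unassigned neuron)."""


class PatternSpecError(PolychronError, ValueError):
    """Infeasible synthetic pattern specification."""
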