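"""Exception hierarchy for stemfate."""


class StemfateError(Exception):
    """Base class for all stemfate errors."""


class ParameterError(StemfateError, ValueError):
    """A rate, probability, or generator parameter violates its constraints."""


class GridError(StemfateError, ValueError):
    """A time grid is non-uniform, too short, or otherwise unusable."""


class IntegrationError(StemfateError, RuntimeError):
    """Forward integration produced an inconsistent state (e.g. negative abundance)."""


class DegeneratePopulationError(StemfateError, ZeroDivisionError):
    """Total population hit zero where a fraction was requested."""


class SingularClosureError(StemfateError, ValueError):
    """The algebraic closure is singular (stem fraction at or below 0, or >= 2)."""


class NoSolutionError(StemfateError, RuntimeError):
    """No admissible initial triple exists for the requested inversion."""


class SizeError(StemfateError, ValueError):
    """A combinatorial enumeration would exceed its configured cap."""
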