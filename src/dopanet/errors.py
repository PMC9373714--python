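"""Exception types shared across the package."""


class DopanetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DopanetError, ValueError):
    """An invalid kinetic or structural parameter value."""


class WrongModeError(ParameterError):
    """A current routine was called with a channel of the wrong mode/kind."""


class InvalidStateError(DopanetError, ValueError):
    """A state variable left its physical domain (e.g. [Ca2+] <= 0)."""


class TopologyError(DopanetError, ValueError):
    """A compartment/graph operation referenced a nonexistent adjacency."""


class AlignmentError(DopanetError, ValueError):
    """Arrays that must share a grid or length do not."""


class RangeError(DopanetError, ValueError):
    """A scalar argument fell outside its documented range."""


class ConfigError(DopanetError, ValueError):
    """A manifest or parameter file failed validation."""


class NumericalBlowupError(DopanetError, ArithmeticError):
    """The integrator produced a non-finite state variable."""
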