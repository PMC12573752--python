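"""Exception hierarchy for dfqmmm."""


class DFQMMMError(Exception):
    """Base class for all package errors."""


class InvalidCellError(DFQMMMError):
    """Lattice vectors are linearly dependent or the cell volume vanishes."""


class GridMismatchError(DFQMMMError):
    """Fields that must share a grid were built on different grids."""


class ResolutionError(DFQMMMError):
    """A Gaussian width is too narrow for the real-space grid to resolve."""


class NegativeDensityError(DFQMMMError):
    """A functional received a density with significantly negative values."""


class NonConvergenceError(DFQMMMError):
    """An iterative solver exhausted its iteration budget.

    Carries the energy (or residual) trace accumulated so far in ``trace``.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class OscillationError(NonConvergenceError):
    """The outer SCF energy started cycling instead of descending."""


class PolarizationCatastropheError(NonConvergenceError):
    """The induced-dipole iteration diverged (mutual over-polarization).

    ``pair`` names the two site indices with the strongest coupling.
    """

    def __init__(self, message, pair=None, trace=None):
        super().__init__(message, trace)
        self.pair = pair


class InconsistencyError(DFQMMMError):
    """Inputs that must agree (grids, configs, cells, alpha/mu) do not."""


class ParseError(DFQMMMError):
    """A structured text file could not be parsed; carries the line number."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class PackingError(DFQMMMError):
    """Random molecular packing failed within the attempt budget."""
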