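"""Periodic real-space grid engine.

A :class:`Grid` discretizes a periodic :class:`SimulationCell` with an
FFT-friendly number of points per axis chosen from a plane-wave-style kinetic
energy cutoff.  :class:`ScalarField` wraps real values sampled on that grid
(densities in e/bohr^3, potentials in Ha per electron).  Reciprocal-space
machinery provides spectral gradients and a Poisson/Hartree solver under the
neutralizing-background (G=0 removed) convention.

Conventions
-----------
* Discrete Fourier transforms follow numpy: ``f_G = fftn(f_r)``; a continuous
  Fourier coefficient ``F(G) = \\int f(r) exp(-iG.r) dr`` relates to the
  discrete one by ``F(G) = f_G * (V/N)``.
* ``solve_hartree`` returns phi with ``lap(phi) = -4 pi rho``, i.e. the
  repulsive electron-electron interaction when ``rho`` is an electron density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from math import ceil, pi, sqrt

import numpy as np

from .exceptions import GridMismatchError, InvalidCellError

__all__ = [
    "SimulationCell",
    "Grid",
    "ScalarField",
    "VectorField",
    "build_grid",
    "integrate",
    "solve_hartree",
    "spectral_gradient",
    "spectral_divergence",
    "spectral_laplacian",
    "next_fft_friendly",
]


def next_fft_friendly(n: int) -> int:
    """Smallest integer >= n whose prime factors are all in {2, 3, 5}."""
    n = max(int(n), 1)
    while True:
        m = n
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


class SimulationCell:
    """Periodic simulation cell defined by three lattice vectors (bohr).

    Parameters
    ----------
    lattice_vectors : (3, 3) array_like
        Rows are the lattice vectors a_1, a_2, a_3 in bohr.
    """

    def __init__(self, lattice_vectors):
        A = np.array(lattice_vectors, dtype=float).reshape(3, 3)
        vol = abs(float(np.linalg.det(A)))
        if not np.isfinite(A).all() or vol < 1e-10:
            raise InvalidCellError(
                "lattice vectors must be linearly independent with positive volume"
            )
        self.lattice = A
        self.periodic = True

    @classmethod
    def cubic(cls, edge_bohr: float) -> "SimulationCell":
        return cls(np.eye(3) * float(edge_bohr))

    @property
    def volume(self) -> float:
        return abs(float(np.linalg.det(self.lattice)))

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.lattice, axis=1)

    @property
    def reciprocal(self) -> np.ndarray:
        """Reciprocal lattice vectors as rows: B = 2 pi inv(A)^T."""
        return 2.0 * pi * np.linalg.inv(self.lattice).T

    def wrap_fractional(self, positions) -> np.ndarray:
        """Map Cartesian positions (bohr) to fractional coordinates in [0, 1)."""
        frac = np.atleast_2d(positions) @ np.linalg.inv(self.lattice)
        return frac % 1.0

    def minimum_image(self, dr) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors (bohr)."""
        frac = np.atleast_2d(dr) @ np.linalg.inv(self.lattice)
        frac -= np.round(frac)
        out = frac @ self.lattice
        return out if np.ndim(dr) > 1 else out[0]

    def __eq__(self, other):
        return isinstance(other, SimulationCell) and np.allclose(
            self.lattice, other.lattice
        )

    def __repr__(self):
        return f"SimulationCell(lengths={np.round(self.lengths, 4)} bohr)"


class Grid:
    """Real-space grid over a periodic cell, with cached reciprocal vectors."""

    def __init__(self, cell: SimulationCell, shape, cutoff: float | None = None):
        shape = tuple(int(n) for n in shape)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError("grid shape must be three positive integers")
        self.cell = cell
        self.shape = shape
        self.cutoff = cutoff

    @property
    def spacing(self) -> np.ndarray:
        """Grid spacing per axis, |a_i| / n_i (bohr)."""
        return self.cell.lengths / np.array(self.shape, dtype=float)

    @property
    def npoints(self) -> int:
        return int(np.prod(self.shape))

    @property
    def dv(self) -> float:
        """Voxel volume (bohr^3)."""
        return self.cell.volume / self.npoints

    @cached_property
    def g_vectors(self) -> np.ndarray:
        """Reciprocal vectors on the FFT mesh, shape (3, n1, n2, n3)."""
        B = self.cell.reciprocal
        ms = [np.fft.fftfreq(n, d=1.0 / n) for n in self.shape]
        M = np.meshgrid(*ms, indexing="ij")
        G = np.einsum("dxyz,de->exyz", np.array(M), B)
        return G

    @cached_property
    def g2(self) -> np.ndarray:
        return np.sum(self.g_vectors**2, axis=0)

    @cached_property
    def coordinates(self) -> np.ndarray:
        """Cartesian coordinates of grid points, shape (3, n1, n2, n3) (bohr)."""
        fr = [np.arange(n) / n for n in self.shape]
        F = np.meshgrid(*fr, indexing="ij")
        return np.einsum("dxyz,de->exyz", np.array(F), self.cell.lattice)

    def nearest_index(self, position) -> tuple[int, int, int]:
        """Grid index nearest a Cartesian position.

        Exact half-way ties break toward the lexicographically smaller index
        (deterministic across platforms).
        """
        frac = self.cell.wrap_fractional(position)[0]
        idx = []
        for f, n in zip(frac, self.shape):
            x = f * n
            i = int(np.floor(x + 0.5 - 1e-12)) % n
            idx.append(i)
        return tuple(idx)

    def min_image_distance(self, position) -> np.ndarray:
        """Distance from every grid point to ``position`` with minimum image."""
        dr = self.coordinates - np.asarray(position, float).reshape(3, 1, 1, 1)
        frac = np.einsum("exyz,ed->dxyz", dr, np.linalg.inv(self.cell.lattice).T)
        frac -= np.round(frac)
        dr = np.einsum("dxyz,de->exyz", frac, self.cell.lattice)
        return np.sqrt(np.sum(dr**2, axis=0))

    def compatible_with(self, other: "Grid") -> bool:
        return self.shape == other.shape and self.cell == other.cell

    def __repr__(self):
        return f"Grid(shape={self.shape}, spacing={np.round(self.spacing, 4)} bohr)"


def build_grid(cell: SimulationCell, cutoff: float) -> Grid:
    """Build a grid whose spacing satisfies h <= pi / sqrt(2 * cutoff).

    The bound is the plane-wave aliasing condition for a kinetic-energy cutoff
    ``cutoff`` (Ha): the shortest resolvable wavelength is ``2 h``, so
    ``G_max = pi / h`` must obey ``G_max^2 / 2 >= cutoff``.  Each axis count is
    rounded *up* to an FFT-friendly (2,3,5-smooth) size, never coarser.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    h_max = pi / sqrt(2.0 * cutoff)
    shape = tuple(next_fft_friendly(ceil(L / h_max)) for L in cell.lengths)
    return Grid(cell, shape, cutoff=cutoff)


@dataclass
class ScalarField:
    """Real-valued function sampled on a periodic grid."""

    grid: Grid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: Grid) -> "ScalarField":
        return cls(grid, np.zeros(grid.shape))

    @classmethod
    def from_function(cls, grid: Grid, fn) -> "ScalarField":
        x, y, z = grid.coordinates
        return cls(grid, np.asarray(fn(x, y, z), dtype=float))

    @classmethod
    def from_recip_coefficients(cls, grid: Grid, coeffs: np.ndarray) -> "ScalarField":
        """Synthesize from continuous Fourier coefficients F(G) on the mesh."""
        vals = np.fft.ifftn(coeffs).real * (grid.npoints / grid.cell.volume)
        return cls(grid, vals)

    def fft(self) -> np.ndarray:
        return np.fft.fftn(self.values)

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())

    def _check(self, other):
        if not self.grid.compatible_with(other.grid):
            raise GridMismatchError("fields live on incompatible grids")

    def __add__(self, other):
        if isinstance(other, ScalarField):
            self._check(other)
            return ScalarField(self.grid, self.values + other.values)
        return ScalarField(self.grid, self.values + other)

    def __sub__(self, other):
        if isinstance(other, ScalarField):
            self._check(other)
            return ScalarField(self.grid, self.values - other.values)
        return ScalarField(self.grid, self.values - other)

    def __mul__(self, other):
        if isinstance(other, ScalarField):
            self._check(other)
            return ScalarField(self.grid, self.values * other.values)
        return ScalarField(self.grid, self.values * other)

    __rmul__ = __mul__

    def __neg__(self):
        return ScalarField(self.grid, -self.values)


@dataclass
class VectorField:
    """Three scalar components on a shared grid (e.g. -grad v, Ha/bohr)."""

    grid: Grid
    components: np.ndarray = field(repr=False)  # shape (3, n1, n2, n3)

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (3, *self.grid.shape):
            raise GridMismatchError("vector field components do not match the grid")

    def magnitude(self) -> ScalarField:
        return ScalarField(self.grid, np.sqrt(np.sum(self.components**2, axis=0)))

    def at_index(self, idx) -> np.ndarray:
        return self.components[(slice(None), *idx)]


def integrate(f: ScalarField) -> float:
    """Trapezoid-free periodic quadrature: sum(values) * voxel volume."""
    return float(np.sum(f.values) * f.grid.dv)


def solve_hartree(rho: ScalarField) -> ScalarField:
    """Solve lap(phi) = -4 pi rho with periodic boundaries.

    The G = 0 component is set to zero (uniform neutralizing background), so
    ``phi`` is defined up to that convention.  For an electron density this is
    the (positive, repulsive) Hartree potential in Ha per electron.
    """
    grid = rho.grid
    rho_G = rho.fft()
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_G = 4.0 * pi * rho_G / grid.g2
    phi_G[grid.g2 == 0.0] = 0.0
    return ScalarField(grid, np.fft.ifftn(phi_G).real)


def spectral_gradient(f: ScalarField) -> VectorField:
    """Gradient via multiplication by iG in reciprocal space."""
    grid = f.grid
    f_G = f.fft()
    comps = np.empty((3, *grid.shape))
    for d in range(3):
        comps[d] = np.fft.ifftn(1j * grid.g_vectors[d] * f_G).real
    return VectorField(grid, comps)


def spectral_divergence(v: VectorField) -> ScalarField:
    grid = v.grid
    out = np.zeros(grid.shape, dtype=complex)
    for d in range(3):
        out += 1j * grid.g_vectors[d] * np.fft.fftn(v.components[d])
    return ScalarField(grid, np.fft.ifftn(out).real)


def spectral_laplacian(f: ScalarField) -> ScalarField:
    grid = f.grid
    return ScalarField(grid, -np.fft.ifftn(grid.g2 * f.fft()).real)
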