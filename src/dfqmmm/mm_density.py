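"""Backward mapping: classical multipoles -> smooth electron densities.

Each MM site carries a permanent charge q and an isolated-atom valence count
N.  Its valence electron density is a normalized Gaussian of width sigma_q
scaled by (N - q), so the site presents net charge q once its smeared ionic
core (+N) is added.  An induced point dipole mu maps onto the gradient of a
normalized Gaussian of width sigma_mu:

    rho_mu(r) = -mu . grad g_sigma(r - R)

which integrates to zero and has first electron-density moment +mu.  The MM
ionic potential uses an analytic local pseudopotential

    v_loc(r) = -N * erf(r / (sqrt(2) sigma_core)) / r

(the energy-per-electron potential of a Gaussian core of charge +N and width
sigma_core), attractive for electrons with the correct -N/r tail.

All fields are synthesized in reciprocal space, which sums periodic images
exactly for the band-limited representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .exceptions import ResolutionError
from .grid import Grid, ScalarField

__all__ = [
    "MMSite",
    "InducedDipole",
    "charge_density",
    "dipole_density",
    "assemble_mm_density",
    "mm_ionic_potential",
    "ionic_charge_density",
    "gaussian_density",
]

#: minimum Gaussian width, in units of the largest grid spacing, below which a
#: width is considered unresolvable on the grid
MIN_WIDTH_SPACINGS = 1.5


@dataclass
class MMSite:
    """One classical site of the MM subsystem (atomic units).

    q is the permanent (physical) charge in e; N the valence electron count of
    the isolated atom; sigma_q / sigma_mu the Gaussian widths of the permanent
    charge / induced-dipole densities (bohr); alpha the isotropic dipole
    polarizability (bohr^3); k_SE the self-energy correction constant
    (Ha / (e bohr)^2); sigma_core the width of the smeared ionic core used by
    the local pseudopotential (defaults to sigma_q / 2); molecule an integer
    label used for intramolecular field exclusions.
    """

    position: np.ndarray
    element: str = "X"
    q: float = 0.0
    N: float = 0.0
    sigma_q: float = 1.0
    sigma_mu: float = 1.0
    alpha: float = 0.0
    k_SE: float = 0.0
    sigma_core: float | None = None
    molecule: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.sigma_q <= 0 or self.sigma_mu <= 0:
            raise ValueError("Gaussian widths must be positive")
        if self.alpha < 0 or self.N < 0:
            raise ValueError("alpha and N must be nonnegative")
        if self.sigma_core is None:
            self.sigma_core = 0.5 * self.sigma_q


@dataclass
class InducedDipole:
    """Induced dipole at an MM site, in the electron-displacement convention.

    ``mu`` is the first moment of the induced *electron* density (e*bohr);
    the physical charge dipole is -mu.  ``mu_ref`` is the isolated-MM
    reference dipole mu' entering the self-energy correction k_SE |mu - mu'|^2.
    """

    site_index: int
    mu: np.ndarray
    mu_ref: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).reshape(3)
        self.mu_ref = np.asarray(self.mu_ref, dtype=float).reshape(3)
        if not (np.isfinite(self.mu).all() and np.isfinite(self.mu_ref).all()):
            raise ValueError("dipole components must be finite")


def _check_width(sigma: float, grid: Grid, what: str):
    hmax = float(np.max(grid.spacing))
    if sigma < MIN_WIDTH_SPACINGS * hmax:
        raise ResolutionError(
            f"{what} width {sigma:.3f} bohr is under-resolved: grid spacing "
            f"{hmax:.3f} bohr requires sigma >= {MIN_WIDTH_SPACINGS * hmax:.3f}"
        )


def _structure_factor(grid: Grid, position: np.ndarray) -> np.ndarray:
    G = grid.g_vectors
    phase = np.einsum("dxyz,d->xyz", G, np.asarray(position, float))
    return np.exp(-1j * phase)


def gaussian_density(grid: Grid, position, amplitude: float, sigma: float) -> ScalarField:
    """Periodic-image-summed normalized Gaussian times ``amplitude``."""
    coeffs = amplitude * np.exp(-0.5 * sigma**2 * grid.g2) * _structure_factor(
        grid, position
    )
    return ScalarField.from_recip_coefficients(grid, coeffs)


def charge_density(site: MMSite, grid: Grid) -> ScalarField:
    """Valence electron density of one site: (N - q) g_sigma_q(r - R)."""
    _check_width(site.sigma_q, grid, f"charge Gaussian ({site.element})")
    return gaussian_density(grid, site.position, site.N - site.q, site.sigma_q)


def dipole_density(d: InducedDipole, site: MMSite, grid: Grid) -> ScalarField:
    """Electron density of an induced dipole: -mu . grad g_sigma_mu(r - R)."""
    _check_width(site.sigma_mu, grid, f"dipole Gaussian ({site.element})")
    if not np.any(d.mu):
        return ScalarField.zeros(grid)
    G = grid.g_vectors
    muG = np.einsum("dxyz,d->xyz", G, d.mu)
    coeffs = (
        -1j * muG * np.exp(-0.5 * site.sigma_mu**2 * grid.g2)
        * _structure_factor(grid, site.position)
    )
    return ScalarField.from_recip_coefficients(grid, coeffs)


def assemble_mm_density(
    sites: Sequence[MMSite],
    dipoles: Sequence[InducedDipole],
    grid: Grid,
) -> ScalarField:
    """Total MM valence electron density: sum of charge and dipole terms.

    Integrates to sum_i (N_i - q_i) independently of the dipole values.
    """
    coeffs = np.zeros(grid.shape, dtype=complex)
    for site in sites:
        _check_width(site.sigma_q, grid, f"charge Gaussian ({site.element})")
        coeffs += (
            (site.N - site.q)
            * np.exp(-0.5 * site.sigma_q**2 * grid.g2)
            * _structure_factor(grid, site.position)
        )
    for d in dipoles:
        if d.site_index < 0 or d.site_index >= len(sites):
            raise IndexError(f"dipole references unknown site {d.site_index}")
        site = sites[d.site_index]
        if not np.any(d.mu):
            continue
        _check_width(site.sigma_mu, grid, f"dipole Gaussian ({site.element})")
        muG = np.einsum("dxyz,d->xyz", grid.g_vectors, d.mu)
        coeffs += (
            -1j * muG
            * np.exp(-0.5 * site.sigma_mu**2 * grid.g2)
            * _structure_factor(grid, site.position)
        )
    return ScalarField.from_recip_coefficients(grid, coeffs)


def _erf_potential_coeffs(grid: Grid, position, n_valence: float, sigma_core: float):
    """Fourier coefficients of -N erf(r/(sqrt2 sigma))/r (background removed)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        coeffs = (
            -4.0 * np.pi * n_valence
            * np.exp(-0.5 * sigma_core**2 * grid.g2)
            / grid.g2
        )
    coeffs[grid.g2 == 0.0] = 0.0
    return coeffs * _structure_factor(grid, position)


def mm_ionic_potential(sites: Sequence[MMSite], grid: Grid) -> ScalarField:
    """Local pseudopotential of all MM ionic cores, v_MM(r) (Ha/electron).

    Attractive for electrons, with a -N_i/r tail per site, evaluated with the
    same neutralizing-background convention as the Hartree solver.
    """
    coeffs = np.zeros(grid.shape, dtype=complex)
    for site in sites:
        coeffs += _erf_potential_coeffs(grid, site.position, site.N, site.sigma_core)
    return ScalarField.from_recip_coefficients(grid, coeffs)


def ionic_charge_density(sites: Sequence[MMSite], grid: Grid) -> ScalarField:
    """Smeared ionic (positive) charge density: sum_i N_i g_sigma_core(r-R_i).

    This is exactly the charge distribution whose electron-energy potential is
    the erf local pseudopotential above; it is used for grid-consistent
    ion-ion cross energies.
    """
    coeffs = np.zeros(grid.shape, dtype=complex)
    for site in sites:
        coeffs += (
            site.N
            * np.exp(-0.5 * site.sigma_core**2 * grid.g2)
            * _structure_factor(grid, site.position)
        )
    return ScalarField.from_recip_coefficients(grid, coeffs)
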