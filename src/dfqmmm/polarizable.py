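"""Minimal polarizable force field: charges + Thole-damped induced dipoles.

A deliberately small stand-in for production many-body water potentials: rigid
3-site water monomers with fixed atomic point charges, one isotropic
polarizability on oxygen, Thole exponential damping between inducible sites,
and 1-2/1-3 intramolecular permanent-field exclusions.  It exercises the full
mutual-polarization machinery of the embedding workflow.

Field convention
----------------
All fields handled here are in the *electron convention*: the negative
gradient of the energy-per-electron potential, i.e. the negative of the
conventional electric field.  Dipole vectors are electron-displacement
dipoles (physical charge dipole = -mu).  Classical electrostatics is
sign-symmetric, so all energies are convention-independent; the convention
makes the coupling to the grid-based embedding field sign-exact with no
conversions: mu = alpha * (field from ``qm_field_at_mm_sites``).

MM-MM interactions use real-space Coulomb with the minimum-image convention
(cells are large relative to the molecular aggregates treated at this scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import (
    InconsistencyError,
    NonConvergenceError,
    PolarizationCatastropheError,
)
from .grid import SimulationCell
from .mm_density import InducedDipole, MMSite

__all__ = [
    "MMState",
    "WATER_MM_PARAMS",
    "THOLE_A_DEFAULT",
    "sites_from_atoms",
    "solve_induced_dipoles",
    "isolated_mm_reference",
    "mm_internal_energy",
    "compute_mm_state",
]

#: Built-in rigid water model: TIP3P-like charges on atoms, AMOEBA-style
#: isotropic atomic polarizabilities (O 0.837 A^3, H 0.496 A^3), declared
#: default Gaussian widths for the backward mapping.
WATER_MM_PARAMS = {
    "O": dict(q=-0.834, N=6.0, sigma_q=1.1, sigma_mu=1.0, alpha=5.650, k_SE=0.0),
    "H": dict(q=0.417, N=1.0, sigma_q=0.9, sigma_mu=0.8, alpha=3.348, k_SE=0.0),
}

THOLE_A_DEFAULT = 0.39


@dataclass
class MMState:
    """Converged classical state of the MM subsystem."""

    sites: list
    dipoles: list
    energy_perm: float
    energy_ind: float
    energy_SE_corr: float

    @property
    def energy(self) -> float:
        return self.energy_perm + self.energy_ind + self.energy_SE_corr


def sites_from_atoms(elements, positions, molecules, params=None) -> list[MMSite]:
    """Build MM sites from element labels, positions (bohr), molecule ids."""
    params = params or WATER_MM_PARAMS
    sites = []
    for el, pos, mol in zip(elements, positions, molecules):
        if el not in params:
            raise KeyError(f"no MM parameters for element {el!r}")
        sites.append(MMSite(position=pos, element=el, molecule=int(mol), **params[el]))
    return sites


def _displacements(positions: np.ndarray, cell: SimulationCell | None):
    """Pairwise displacement r_i - r_j (n, n, 3), minimum image if periodic."""
    dr = positions[:, None, :] - positions[None, :, :]
    if cell is not None:
        flat = dr.reshape(-1, 3)
        dr = cell.minimum_image(flat).reshape(dr.shape)
    return dr


def _thole_factors(r, u3_scale, thole_a, damped):
    """lambda3, lambda5 screening factors for a pair at distance r."""
    if not damped or u3_scale <= 0:
        return 1.0, 1.0
    au3 = thole_a * r**3 / u3_scale
    e = np.exp(-au3)
    return 1.0 - e, 1.0 - (1.0 + au3) * e


def _permanent_field(sites, positions, cell, thole_a, damped):
    """Electron-convention field of the permanent charges at every site.

    Sites belonging to the same molecule are excluded (1-2/1-3 exclusion).
    The field from a physical charge q at displacement rvec (from source to
    target) is -q rvec / r^3, Thole-screened when both sites are polarizable.
    """
    n = len(sites)
    field = np.zeros((n, 3))
    dr = _displacements(positions, cell)
    for i, si in enumerate(sites):
        for j, sj in enumerate(sites):
            if i == j or sj.q == 0.0 or si.molecule == sj.molecule:
                continue
            rvec = dr[i, j]
            r = float(np.linalg.norm(rvec))
            u3 = (si.alpha * sj.alpha) ** 0.5 if si.alpha > 0 and sj.alpha > 0 else 0.0
            lam3, _ = _thole_factors(r, u3, thole_a, damped)
            field[i] += -sj.q * rvec * lam3 / r**3
    return field


def _dipole_tensor(rvec, r, lam3, lam5):
    rhat = rvec / r
    return (3.0 * lam5 * np.outer(rhat, rhat) - lam3 * np.eye(3)) / r**3


def _interaction_tensors(sites, positions, cell, thole_a, damped):
    """Damped dipole-dipole tensors T_ij for polarizable pairs (i != j)."""
    n = len(sites)
    T = np.zeros((n, n, 3, 3))
    dr = _displacements(positions, cell)
    for i, si in enumerate(sites):
        if si.alpha <= 0:
            continue
        for j, sj in enumerate(sites):
            if j == i or sj.alpha <= 0:
                continue
            rvec = dr[i, j]
            r = float(np.linalg.norm(rvec))
            u3 = (si.alpha * sj.alpha) ** 0.5
            lam3, lam5 = _thole_factors(r, u3, thole_a, damped)
            T[i, j] = _dipole_tensor(rvec, r, lam3, lam5)
    return T


def solve_induced_dipoles(
    sites: Sequence[MMSite],
    external_field=None,
    cell: SimulationCell | None = None,
    thole_a: float = THOLE_A_DEFAULT,
    damped: bool = True,
    tol: float = 1e-8,
    max_iter: int = 2000,
    mixing: float = 0.7,
) -> list[InducedDipole]:
    """Self-consistent induced dipoles mu_i = alpha_i (E_perm + E_ext + T mu).

    Returns one :class:`InducedDipole` per polarizable site (alpha > 0),
    converged to max|delta mu| < ``tol`` e*bohr.  A diverging iteration (the
    polarization catastrophe) raises :class:`PolarizationCatastropheError`
    naming the most strongly coupled pair.
    """
    n = len(sites)
    positions = np.array([s.position for s in sites], dtype=float).reshape(n, 3)
    alphas = np.array([s.alpha for s in sites])
    pol = np.where(alphas > 0)[0]
    if len(pol) == 0:
        return []

    ext = np.zeros((n, 3)) if external_field is None else np.asarray(
        external_field, float
    ).reshape(n, 3)
    e0 = _permanent_field(sites, positions, cell, thole_a, damped) + ext
    T = _interaction_tensors(sites, positions, cell, thole_a, damped)

    mu = np.zeros((n, 3))
    mu[pol] = alphas[pol, None] * e0[pol]
    deltas = []
    for it in range(max_iter):
        field = e0.copy()
        for i in pol:
            field[i] += np.einsum("jab,jb->a", T[i, pol], mu[pol])
        mu_new = np.zeros((n, 3))
        mu_new[pol] = alphas[pol, None] * field[pol]
        delta = float(np.max(np.abs(mu_new - mu)))
        mu = (1.0 - mixing) * mu + mixing * mu_new
        deltas.append(delta)
        if delta < tol:
            break
        diverging = len(deltas) > 30 and deltas[-1] > 1.05 * deltas[-11] and deltas[-1] > tol * 100
        if diverging or np.max(np.abs(mu)) > 1e3:
            pair = _strongest_pair(sites, positions, cell, pol)
            raise PolarizationCatastropheError(
                f"induced-dipole iteration diverged (polarization catastrophe) "
                f"between sites {pair[0]} and {pair[1]}",
                pair=pair,
                trace=deltas,
            )
    else:
        raise NonConvergenceError(
            f"induced dipoles not converged in {max_iter} iterations", trace=deltas
        )

    return [InducedDipole(site_index=int(i), mu=mu[i].copy()) for i in pol]


def _strongest_pair(sites, positions, cell, pol):
    best, best_pair = -1.0, (int(pol[0]), int(pol[0]))
    dr = _displacements(positions, cell)
    for a, i in enumerate(pol):
        for j in pol[a + 1 :]:
            r = float(np.linalg.norm(dr[i, j]))
            coupling = 4.0 * sites[i].alpha * sites[j].alpha / r**6
            if coupling > best:
                best, best_pair = coupling, (int(i), int(j))
    return best_pair


def isolated_mm_reference(
    sites: Sequence[MMSite],
    cell: SimulationCell | None = None,
    **kwargs,
) -> list[InducedDipole]:
    """Reference dipoles mu' of the isolated MM system (zero external field)."""
    dipoles = solve_induced_dipoles(sites, external_field=None, cell=cell, **kwargs)
    for d in dipoles:
        d.mu_ref = d.mu.copy()
    return dipoles


def mm_internal_energy(
    sites: Sequence[MMSite],
    dipoles: Sequence[InducedDipole],
    external_field=None,
    cell: SimulationCell | None = None,
    thole_a: float = THOLE_A_DEFAULT,
    damped: bool = True,
    return_parts: bool = False,
):
    """Classical MM energy at the given dipoles (Ha).

    permanent-permanent Coulomb (minimum image, intramolecular pairs
    excluded) + induction (-mu.E + |mu|^2/(2 alpha), with the mutual
    dipole-dipole term counted once) + the self-energy correction
    sum_i k_SE |mu_i - mu'_i|^2.  ``external_field`` (electron convention)
    contributes -mu.E_ext when given; the embedding driver omits it because
    the QM-MM coupling is counted through the density instead.
    """
    n = len(sites)
    positions = np.array([s.position for s in sites], dtype=float).reshape(n, 3)
    dr = _displacements(positions, cell)

    e_perm = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if sites[i].molecule == sites[j].molecule:
                continue
            r = float(np.linalg.norm(dr[i, j]))
            e_perm += sites[i].q * sites[j].q / r

    mu = np.zeros((n, 3))
    mu_ref = np.zeros((n, 3))
    for d in dipoles:
        mu[d.site_index] = d.mu
        mu_ref[d.site_index] = d.mu_ref
    for i in range(n):
        if sites[i].alpha == 0.0 and np.any(mu[i]):
            raise InconsistencyError(f"site {i} has alpha = 0 but a nonzero dipole")

    e_ind = 0.0
    e_se = 0.0
    if np.any(mu):
        ext = np.zeros((n, 3)) if external_field is None else np.asarray(
            external_field, float
        ).reshape(n, 3)
        e0 = _permanent_field(sites, positions, cell, thole_a, damped) + ext
        T = _interaction_tensors(sites, positions, cell, thole_a, damped)
        for i in range(n):
            if sites[i].alpha == 0.0:
                continue
            e_ind += -float(mu[i] @ e0[i]) + float(mu[i] @ mu[i]) / (2.0 * sites[i].alpha)
            e_se += sites[i].k_SE * float(np.sum((mu[i] - mu_ref[i]) ** 2))
            for j in range(n):
                if j != i and sites[j].alpha > 0:
                    e_ind -= 0.5 * float(mu[i] @ T[i, j] @ mu[j])
    if return_parts:
        return e_perm, e_ind, e_se
    return e_perm + e_ind + e_se


def compute_mm_state(
    sites: Sequence[MMSite],
    external_field=None,
    cell: SimulationCell | None = None,
    dipoles: Sequence[InducedDipole] | None = None,
    **kwargs,
) -> MMState:
    """Solve dipoles (unless given) and package the classical energies."""
    if dipoles is None:
        ref = isolated_mm_reference(sites, cell=cell, **kwargs)
        dipoles = solve_induced_dipoles(sites, external_field, cell=cell, **kwargs)
        ref_by_idx = {d.site_index: d.mu_ref for d in ref}
        for d in dipoles:
            d.mu_ref = ref_by_idx[d.site_index]
    e_perm, e_ind, e_se = mm_internal_energy(
        sites, dipoles, external_field=external_field, cell=cell,
        return_parts=True, **{k: v for k, v in kwargs.items() if k in ("thole_a", "damped")},
    )
    return MMState(list(sites), list(dipoles), e_perm, e_ind, e_se)
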