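"""Orbital-free DFT ground-state solver on the periodic grid.

Minimizes E[rho] = T_s[rho] + E_H[rho] + E_xc[rho] + int v_ext rho over
nonnegative densities with fixed electron count, using the sqrt-density
parametrization rho = phi^2.  The electron-number constraint is enforced
exactly by curvilinear (great-circle) steps on the sphere ||phi||^2 = N, with
a projected, preconditioned nonlinear conjugate-gradient direction and a
parabolic line search whose energy sequence is non-increasing.

The default additive kinetic functional is vW + TF (lam = 1), the standard
orbital-free choice for single-molecule fragments; the von Weizsacker piece
is evaluated exactly through phi (T_vW = 1/2 int |grad phi|^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .exceptions import NonConvergenceError
from .functionals import (
    KineticConfig,
    gga_kinetic,
    thomas_fermi,
    xc_energy,
)
from .grid import Grid, ScalarField, integrate, solve_hartree
from .mm_density import _erf_potential_coeffs, gaussian_density

__all__ = [
    "Atom",
    "QMSubsystem",
    "EmbeddingTerm",
    "qm_ionic_potential",
    "minimize_ofdft",
]


@dataclass
class Atom:
    """One QM nucleus: position (bohr), element, valence electron count."""

    position: np.ndarray
    element: str = "X"
    n_valence: float = 1.0
    sigma_core: float = 0.5

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class QMSubsystem:
    """Atoms, electron count, and optimized electron density of one fragment."""

    atoms: list
    n_electrons: float
    density: ScalarField
    energies: dict = dc_field(default_factory=dict)
    mu: float = 0.0  # chemical potential (Ha)
    trace: list = dc_field(default_factory=list)
    converged: bool = False

    @property
    def energy(self) -> float:
        return sum(self.energies.values())


def qm_ionic_potential(atoms, grid: Grid) -> ScalarField:
    """Superposition of analytic local pseudopotentials of the QM nuclei."""
    coeffs = np.zeros(grid.shape, dtype=complex)
    for atom in atoms:
        coeffs += _erf_potential_coeffs(
            grid, atom.position, atom.n_valence, atom.sigma_core
        )
    return ScalarField.from_recip_coefficients(grid, coeffs)


def _atomic_guess(atoms, n_electrons, grid: Grid) -> ScalarField:
    """Superposed atomic Gaussians, rescaled to the requested electron count."""
    if atoms:
        rho = ScalarField.zeros(grid)
        for atom in atoms:
            rho = rho + gaussian_density(grid, atom.position, atom.n_valence, 1.2)
        rho = ScalarField(grid, np.maximum(rho.values, 1e-8))
    else:
        rho = ScalarField(grid, np.full(grid.shape, 1e-3))
    rho = rho * (n_electrons / integrate(rho))
    return rho


class EmbeddingTerm:
    """Differentiable environment coupling added to the inner minimization.

    Holds a frozen environment density and ionic potential; contributes

        E_emb[rho] = int rho (v_env + Hartree(rho_env))
                   + (F[rho + rho_env] - F[rho])  for F in {T_s^nad, E_xc^nad}

    (environment-only constants omitted: they do not move the minimizer).
    Making the inner solve variational in the full embedded energy removes
    the slowly-converging outer relaxation of the Pauli/xc potentials.
    """

    def __init__(self, rho_env, v_env, cfg_nad, include_kinetic=True, include_xc=True):
        self.rho_env = rho_env
        self.cfg_nad = cfg_nad
        self.include_kinetic = include_kinetic
        self.include_xc = include_xc
        self.v_classical = v_env + solve_hartree(rho_env)
        # mapped dipole densities may dip below zero where the dipole term
        # dominates; kinetic/xc functionals see the clipped (physical) density
        # while Coulomb terms use the exact mapped one
        self._rho_env_func = ScalarField(
            rho_env.grid, np.maximum(rho_env.values, 0.0)
        )

    def parts(self, rho: ScalarField, need_potential: bool = True):
        from .functionals import kinetic_functional

        e = float(np.sum(rho.values * self.v_classical.values)) * rho.grid.dv
        v = self.v_classical.values.copy() if need_potential else None
        if self.include_kinetic or self.include_xc:
            rho_tot = rho + self._rho_env_func
            if self.include_kinetic:
                rt = kinetic_functional(rho_tot, self.cfg_nad, potential=need_potential)
                rq = kinetic_functional(rho, self.cfg_nad, potential=need_potential)
                e += rt.energy - rq.energy
                if need_potential:
                    v += rt.potential.values - rq.potential.values
            if self.include_xc:
                xt = xc_energy(rho_tot, potential=need_potential)
                xq = xc_energy(rho, potential=need_potential)
                e += xt.energy - xq.energy
                if need_potential:
                    v += xt.potential.values - xq.potential.values
        return e, v


class _Objective:
    """Energy and phi-gradient of the orbital-free functional."""

    def __init__(self, grid, v_ext, cfg, include_hartree, include_xc, embedding=None):
        self.grid = grid
        self.v_ext = v_ext
        self.cfg = cfg
        self.include_hartree = include_hartree
        self.include_xc = include_xc
        self.embedding = embedding
        # von Weizsacker weight handled exactly via phi
        if cfg.family == "vW":
            self.lam_vw, self.local_kinetic = 1.0, None
        elif cfg.family == "TF+vW":
            self.lam_vw, self.local_kinetic = cfg.lam, "TF"
        elif cfg.family == "TF":
            self.lam_vw, self.local_kinetic = 0.0, "TF"
        else:  # GGA
            self.lam_vw, self.local_kinetic = 0.0, "GGA"

    def parts(self, phi: np.ndarray, need_grad: bool = True):
        grid = self.grid
        rho = ScalarField(grid, phi**2)
        dv = grid.dv

        phi_G = np.fft.fftn(phi)
        t_vw = 0.0
        if self.lam_vw:
            t_vw = (
                0.5 * self.lam_vw
                * float(np.sum(grid.g2 * np.abs(phi_G) ** 2))
                * dv / grid.npoints
            )

        v_local = self.v_ext.values.copy() if need_grad else None
        energy = t_vw + float(np.sum(rho.values * self.v_ext.values)) * dv

        if self.local_kinetic == "TF":
            res = thomas_fermi(rho, potential=need_grad)
            energy += res.energy
            if need_grad:
                v_local += res.potential.values
        elif self.local_kinetic == "GGA":
            res = gga_kinetic(rho, self.cfg, potential=need_grad)
            energy += res.energy
            if need_grad:
                v_local += res.potential.values

        if self.include_hartree:
            v_h = solve_hartree(rho)
            energy += 0.5 * float(np.sum(rho.values * v_h.values)) * dv
            if need_grad:
                v_local += v_h.values
        if self.include_xc:
            res = xc_energy(rho, potential=need_grad)
            energy += res.energy
            if need_grad:
                v_local += res.potential.values
        if self.embedding is not None:
            e_emb, v_emb = self.embedding.parts(rho, need_potential=need_grad)
            energy += e_emb
            if need_grad:
                v_local += v_emb
        return energy, v_local, phi_G

    def energy(self, phi: np.ndarray) -> float:
        return self.parts(phi, need_grad=False)[0]

    def energy_and_grad(self, phi: np.ndarray):
        energy, v_local, phi_G = self.parts(phi)
        grad = 2.0 * phi * v_local
        if self.lam_vw:
            grad += self.lam_vw * np.fft.ifftn(self.grid.g2 * phi_G).real
        return energy, grad


def minimize_ofdft(
    v_ext: ScalarField,
    n_electrons: float,
    cfg: KineticConfig | None = None,
    init: ScalarField | None = None,
    atoms=None,
    include_hartree: bool = True,
    include_xc: bool = True,
    embedding: EmbeddingTerm | None = None,
    tol: float = 1e-8,
    max_iter: int = 3000,
    g0sq: float = 10.0,
) -> QMSubsystem:
    """Variational orbital-free ground state under ``v_ext``.

    Converged when the energy change stays below ``tol`` (Ha; callers scale by
    the atom count) on two consecutive accepted steps.  Raises
    :class:`NonConvergenceError` carrying the energy trace on iteration
    exhaustion.  ``g0sq`` sets the kinetic preconditioner crossover 1/(1 +
    G^2/g0sq) applied to the gradient.
    """
    if n_electrons <= 0:
        raise ValueError("n_electrons must be positive")
    cfg = cfg or KineticConfig(family="TF+vW", lam=1.0)
    atoms = list(atoms) if atoms else []
    grid = v_ext.grid
    dv = grid.dv

    rho0 = init if init is not None else _atomic_guess(atoms, n_electrons, grid)
    phi = np.sqrt(np.maximum(rho0.values, 0.0))
    norm = float(np.sum(phi**2)) * dv
    phi *= np.sqrt(n_electrons / norm)

    obj = _Objective(grid, v_ext, cfg, include_hartree, include_xc, embedding)
    precond_G = 1.0 / (1.0 + grid.g2 / g0sq)

    def inner(a, b):
        return float(np.sum(a * b)) * dv

    energy, grad = obj.energy_and_grad(phi)
    trace = [energy]
    direction = None
    gPg_prev = None
    theta_prev = 0.1
    n_flat = 0
    converged = False

    for it in range(max_iter):
        g_perp = grad - (inner(grad, phi) / n_electrons) * phi
        pg = np.fft.ifftn(precond_G * np.fft.fftn(g_perp)).real
        pg -= (inner(pg, phi) / n_electrons) * phi
        gPg = inner(g_perp, pg)
        if direction is None or it % 25 == 0:
            direction = -pg
        else:
            beta = max(gPg / gPg_prev, 0.0)
            direction = -pg + beta * direction
        gPg_prev = gPg

        d_perp = direction - (inner(direction, phi) / n_electrons) * phi
        d_norm = np.sqrt(inner(d_perp, d_perp))
        if d_norm < 1e-300:
            converged = True
            break
        d_hat = d_perp * (np.sqrt(n_electrons) / d_norm)
        slope = inner(grad, d_hat)
        if slope > 0:  # not a descent direction: restart on steepest descent
            direction = -pg
            d_perp = direction - (inner(direction, phi) / n_electrons) * phi
            d_norm = np.sqrt(inner(d_perp, d_perp))
            d_hat = d_perp * (np.sqrt(n_electrons) / d_norm)
            slope = inner(grad, d_hat)

        def rotate(theta):
            return phi * np.cos(theta) + d_hat * np.sin(theta)

        theta_t = min(max(theta_prev, 1e-4), 0.5)
        e_t = obj.energy(rotate(theta_t))
        curv = (e_t - energy - slope * theta_t) / theta_t**2
        if curv > 0:
            theta = float(np.clip(-0.5 * slope / curv, 0.05 * theta_t, 4.0 * theta_t))
        else:
            theta = 2.0 * theta_t
        e_new = obj.energy(rotate(theta))
        if e_t < e_new:
            theta, e_new = theta_t, e_t
        k = 0
        while e_new > energy and k < 25:
            theta *= 0.5
            e_new = obj.energy(rotate(theta))
            k += 1
        if e_new > energy:
            converged = True  # no further descent possible at machine precision
            break

        phi = rotate(theta)
        # re-normalize against drift (rotation preserves the norm analytically)
        phi *= np.sqrt(n_electrons / (float(np.sum(phi**2)) * dv))
        theta_prev = theta
        de = energy - e_new
        energy, grad = obj.energy_and_grad(phi)
        trace.append(energy)
        if de < tol:
            n_flat += 1
            if n_flat >= 2:
                converged = True
                break
        else:
            n_flat = 0

    if not converged:
        raise NonConvergenceError(
            f"orbital-free minimization did not converge in {max_iter} iterations "
            f"(last dE = {trace[-2] - trace[-1]:.3e} Ha)",
            trace=trace,
        )

    rho = ScalarField(grid, phi**2)
    mu = inner(grad, phi) / (2.0 * n_electrons)

    energies = {"E_ext": float(np.sum(rho.values * v_ext.values)) * dv}
    t_s = 0.0
    if obj.lam_vw:
        phi_G = np.fft.fftn(phi)
        t_s += 0.5 * obj.lam_vw * float(np.sum(grid.g2 * np.abs(phi_G) ** 2)) * dv / grid.npoints
    if obj.local_kinetic == "TF":
        t_s += thomas_fermi(rho).energy
    elif obj.local_kinetic == "GGA":
        t_s += gga_kinetic(rho, cfg).energy
    energies["T_s"] = t_s
    if include_hartree:
        energies["E_H"] = 0.5 * integrate(rho * solve_hartree(rho))
    if include_xc:
        energies["E_xc"] = xc_energy(rho).energy

    return QMSubsystem(
        atoms=atoms,
        n_electrons=float(n_electrons),
        density=rho,
        energies=energies,
        mu=mu,
        trace=trace,
        converged=True,
    )
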