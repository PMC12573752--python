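"""Mutual-polarization QM/MM workflow.

The outer self-consistency loop couples one or more orbital-free QM
subsystems to the polarizable MM model:

1. assemble the MM valence density from permanent charges and current dipoles;
2. build each QM subsystem's embedding potential (classical electrostatics of
   everything else plus nonadditive kinetic/xc potential differences) and
   minimize its density;
3. evaluate the classical part of the QM field at the grid points nearest the
   MM sites and re-solve the induced dipoles (with damped mixing);
4. repeat until both the total energy change (per atom) and the L2 norm of
   the QM density change fall below their thresholds.

The public surface follows the model/results idiom: :class:`QMMM` is built
from a :class:`~dfqmmm.io.Geometry` plus a :class:`RunConfig`, its
:meth:`QMMM.fit` returns a :class:`QMMMResults` carrying the converged
densities, dipoles, energy breakdown, SCF trace and a ``summary()`` table.
``run_qmmm`` / ``interaction_energy`` / ``qm_size_scan`` are the functional
spelling of the same operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .exceptions import InconsistencyError, OscillationError
from .functionals import KineticConfig, kinetic_functional, xc_energy
from .grid import (
    Grid,
    ScalarField,
    build_grid,
    integrate,
    solve_hartree,
)
from .io import Geometry
from .mm_density import (
    InducedDipole,
    assemble_mm_density,
    gaussian_density,
    ionic_charge_density,
    mm_ionic_potential,
)
from .nonadditive import EnergyBreakdown, qm_field_at_mm_sites
from .ofdft import (
    Atom,
    EmbeddingTerm,
    QMSubsystem,
    minimize_ofdft,
    qm_ionic_potential,
)
from .polarizable import (
    THOLE_A_DEFAULT,
    WATER_MM_PARAMS,
    MMState,
    isolated_mm_reference,
    mm_internal_energy,
    sites_from_atoms,
    solve_induced_dipoles,
)
from .units import HARTREE_TO_KCALMOL

__all__ = [
    "RunConfig",
    "QMMMSystem",
    "QMMM",
    "QMMMResults",
    "run_qmmm",
    "interaction_energy",
    "isolated_mm_energy",
    "qm_size_scan",
]

logger = logging.getLogger("dfqmmm")

MIN_SITE_SEPARATION = 0.5  # bohr


def _default_additive():
    return KineticConfig(family="TF+vW", lam=1.0)


def _default_nonadditive():
    return KineticConfig(family="GGA")


@dataclass
class RunConfig:
    """Run settings for the embedding workflow (energies Ha, lengths bohr)."""

    cutoff: float = 25.0
    kinetic_additive: KineticConfig = dc_field(default_factory=_default_additive)
    kinetic_nonadditive: KineticConfig = dc_field(default_factory=_default_nonadditive)
    polarizable: bool = True
    include_ts_nad: bool = True  # Pauli term in the embedding potential
    include_xc_nad: bool = True
    scf_energy_tol: float = 1e-8  # Ha per atom, outer loop
    scf_density_tol: float = 1e-6  # electrons, L2 norm of the QM density change
    max_outer: int = 60
    dipole_mixing: float = 0.5
    inner_tol: float = 1e-8  # Ha per atom, density minimizer
    inner_max_iter: int = 3000
    mm_params: dict = dc_field(default_factory=lambda: {k: dict(v) for k, v in WATER_MM_PARAMS.items()})
    thole_a: float = THOLE_A_DEFAULT
    declared_charge: float = 0.0
    #: target window for QM-size convergence scans (kcal/mol)
    scan_convergence_band: float = 2.0

    def matches(self, other: "RunConfig") -> bool:
        return (
            self.cutoff == other.cutoff
            and self.kinetic_additive == other.kinetic_additive
            and self.kinetic_nonadditive == other.kinetic_nonadditive
            and self.mm_params == other.mm_params
        )


@dataclass
class QMMMSystem:
    """A geometry split into QM and MM fragments, plus run settings."""

    geometry: Geometry
    config: RunConfig = dc_field(default_factory=RunConfig)

    def __post_init__(self):
        pos = self.geometry.positions
        cell = self.geometry.cell
        n = len(pos)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(cell.minimum_image(pos[i] - pos[j]))
                if d < MIN_SITE_SEPARATION:
                    raise InconsistencyError(
                        f"atoms {i} and {j} are {d:.3f} bohr apart "
                        f"(< {MIN_SITE_SEPARATION} bohr)"
                    )
        total_q = 0.0  # QM fragments are built neutral; MM sites carry q_i
        for fid in self.geometry.fragments_with_role("MM"):
            for a in self.geometry.fragment_atoms(fid):
                el = self.geometry.elements[a]
                total_q += self.config.mm_params[el]["q"]
        if abs(total_q - self.config.declared_charge) > 1e-6:
            raise InconsistencyError(
                f"total charge {total_q:+.6f} differs from declared "
                f"{self.config.declared_charge:+.6f}"
            )

    @property
    def cell(self):
        return self.geometry.cell


class QMMM:
    """Density-functionalized QM/MM model for a geometry.

    Parameters
    ----------
    geometry : Geometry
        Atoms with fragment assignments and QM/MM roles.
    config : RunConfig, optional
        Grid cutoff, functionals, SCF thresholds and MM parameters.
    """

    def __init__(self, geometry: Geometry, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.system = QMMMSystem(geometry, self.config)
        self.geometry = geometry

    @classmethod
    def from_geometry(cls, geometry: Geometry, config: RunConfig | None = None):
        return cls(geometry, config)

    def fit(self, start: "QMMMResults | None" = None) -> "QMMMResults":
        """Run the mutual-polarization SCF to convergence."""
        return run_qmmm(self.system, start=start, model=self)

    def fit_isolated_fragment(self, fid: int) -> "QMMMResults":
        """Fit one fragment alone (QM role) in the same cell and config."""
        geom = self.geometry
        keep = geom.fragment_atoms(fid)
        sub = Geometry(
            [geom.elements[i] for i in keep],
            geom.positions[keep],
            geom.cell,
            np.zeros(len(keep), dtype=int),
            {0: "QM"},
        )
        return QMMM(sub, self.config).fit()


# ---------------------------------------------------------------------------
# assembly helpers
# ---------------------------------------------------------------------------

def _qm_fragment_atoms(geometry: Geometry, fid: int, mm_params: dict) -> list[Atom]:
    atoms = []
    for i in geometry.fragment_atoms(fid):
        el = geometry.elements[i]
        p = mm_params[el]
        atoms.append(
            Atom(
                position=geometry.positions[i],
                element=el,
                n_valence=p["N"],
                sigma_core=p.get("sigma_core") or 0.5 * p["sigma_q"],
            )
        )
    return atoms


def _mm_sites(geometry: Geometry, mm_params: dict):
    idx = [
        i
        for fid in geometry.fragments_with_role("MM")
        for i in geometry.fragment_atoms(fid)
    ]
    if not idx:
        return []
    return sites_from_atoms(
        [geometry.elements[i] for i in idx],
        [geometry.positions[i] for i in idx],
        [geometry.fragments[i] for i in idx],
        params=mm_params,
    )


def _hartree_energy(rho: ScalarField) -> float:
    return 0.5 * integrate(rho * solve_hartree(rho))


def _gaussian_self_energy(atoms) -> float:
    """sum_i N_i^2 / (2 sqrt(pi) sigma_i): self-energy of the smeared cores."""
    return sum(a.n_valence**2 / (2.0 * np.sqrt(np.pi) * a.sigma_core) for a in atoms)


def _ionic_density_for_atoms(atoms, grid: Grid) -> ScalarField:
    rho = ScalarField.zeros(grid)
    for a in atoms:
        rho = rho + gaussian_density(grid, a.position, a.n_valence, a.sigma_core)
    return rho


# ---------------------------------------------------------------------------
# total-energy bookkeeping
# ---------------------------------------------------------------------------

def _total_energy(
    cfg: RunConfig,
    grid: Grid,
    qm_subsystems: list[QMSubsystem],
    qm_potentials: list[ScalarField],
    sites,
    dipoles,
    rho_mm: ScalarField | None,
    v_mm: ScalarField | None,
    cell,
) -> EnergyBreakdown:
    """Full energy decomposition at the current densities and dipoles.

    Additive QM terms use the additive functionals; the nonadditive terms use
    the configured nonadditive kinetic (GGA) and PBE xc in the telescoped form
    F[rho_tot] - sum_F F[rho_F], which handles any number of QM subsystems
    without pairwise approximation.  The MM additive energy is the classical
    force-field energy; QM-MM coupling enters only through the density terms,
    so the classical dipole-external coupling is *not* double counted.
    """
    knad = cfg.kinetic_nonadditive
    bd = EnergyBreakdown()

    rho_qm_list = [s.density for s in qm_subsystems]
    have_mm = rho_mm is not None and len(sites) > 0

    # additive QM components (with their own ionic potentials + smeared-core
    # ion-ion repulsion inside each fragment)
    for k, (sub, v_i) in enumerate(zip(qm_subsystems, qm_potentials)):
        # additive components as evaluated by the minimizer itself (its
        # phi-form von Weizsacker term differs from the rho-form at grid
        # level; the bookkeeping must match the variational objective)
        comp = dict(sub.energies)
        rho_ion = _ionic_density_for_atoms(sub.atoms, grid)
        comp["E_ii"] = _hartree_energy(rho_ion) - _gaussian_self_energy(sub.atoms)
        bd.additive[f"QM{k}"] = comp

    if not rho_qm_list:
        if have_mm:
            bd.E_mm_classical = mm_internal_energy(
                sites, dipoles, external_field=None, cell=cell, thole_a=cfg.thole_a
            )
        return bd

    # telescoped nonadditive terms over all fragments (QM subsystems + MM)
    frag_rhos = list(rho_qm_list) + ([rho_mm] if have_mm else [])
    frag_vs = list(qm_potentials) + ([v_mm] if have_mm else [])

    rho_qm_tot = rho_qm_list[0]
    for r in rho_qm_list[1:]:
        rho_qm_tot = rho_qm_tot + r
    if rho_qm_list:
        v_qm_tot = qm_potentials[0]
        for v in qm_potentials[1:]:
            v_qm_tot = v_qm_tot + v

    def _clip(r):
        # kinetic/xc functionals require nonnegative densities; the mapped
        # dipole density can dip below zero near strongly polarized sites
        if float(np.min(r.values)) < 0.0:
            return ScalarField(r.grid, np.maximum(r.values, 0.0))
        return r

    def t_of(r):
        return kinetic_functional(_clip(r), knad, potential=False).energy

    def xc_of(r):
        return xc_energy(_clip(r), potential=False).energy

    t_frag = [t_of(r) for r in frag_rhos]
    xc_frag = [xc_of(r) for r in frag_rhos]
    eh_frag = [_hartree_energy(r) for r in frag_rhos]
    ext_frag = [integrate(r * v) for r, v in zip(frag_rhos, frag_vs)]

    t_qm_tot = t_of(rho_qm_tot) if len(rho_qm_list) > 1 else t_frag[0]
    xc_qm_tot = xc_of(rho_qm_tot) if len(rho_qm_list) > 1 else xc_frag[0]
    eh_qm_tot = _hartree_energy(rho_qm_tot) if len(rho_qm_list) > 1 else eh_frag[0]

    nq = len(rho_qm_list)
    # coupling among QM subsystems (Eq.-10-style, zero for a single subsystem)
    if nq > 1:
        ext_qm_tot = integrate(rho_qm_tot * v_qm_tot)
        e_qm_nad = (
            (t_qm_tot - sum(t_frag[:nq]))
            + (xc_qm_tot - sum(xc_frag[:nq]))
            + (eh_qm_tot - sum(eh_frag[:nq]))
            + (ext_qm_tot - sum(ext_frag[:nq]))
        )
        # ion-ion coupling among QM fragments
        rho_ions = [
            _ionic_density_for_atoms(s.atoms, grid) for s in qm_subsystems
        ]
        rho_ion_tot = rho_ions[0]
        for r in rho_ions[1:]:
            rho_ion_tot = rho_ion_tot + r
        e_qm_nad += _hartree_energy(rho_ion_tot) - sum(
            _hartree_energy(r) for r in rho_ions
        )
        bd.E_qm_internal_nad = e_qm_nad

    if have_mm:
        rho_tot = rho_qm_tot + rho_mm
        bd.T_s_nad = t_of(rho_tot) - t_qm_tot - t_frag[-1]
        bd.E_xc_nad = xc_of(rho_tot) - xc_qm_tot - xc_frag[-1]
        bd.E_coul_cross = _hartree_energy(rho_tot) - eh_qm_tot - eh_frag[-1]
        bd.E_ext_cross_AonB = integrate(rho_mm * v_qm_tot)
        bd.E_ext_cross_BonA = integrate(rho_qm_tot * v_mm)

        # ion-ion between the QM nuclei and the smeared MM cores
        qm_atoms = [a for s in qm_subsystems for a in s.atoms]
        rho_ion_qm = _ionic_density_for_atoms(qm_atoms, grid)
        rho_ion_mm = ionic_charge_density(sites, grid)
        bd.ion_ion = integrate(rho_ion_qm * solve_hartree(rho_ion_mm))

        bd.E_mm_classical = mm_internal_energy(
            sites, dipoles, external_field=None, cell=cell, thole_a=cfg.thole_a
        )
    return bd


# ---------------------------------------------------------------------------
# the outer SCF
# ---------------------------------------------------------------------------

def run_qmmm(
    system: QMMMSystem,
    start: "QMMMResults | None" = None,
    model: QMMM | None = None,
) -> "QMMMResults":
    """Iterate QM densities and MM dipoles to mutual self-consistency."""
    cfg = system.config
    geom = system.geometry
    cell = geom.cell
    grid = build_grid(cell, cfg.cutoff)

    qm_fids = geom.fragments_with_role("QM")
    qm_atoms = [_qm_fragment_atoms(geom, fid, cfg.mm_params) for fid in qm_fids]
    qm_potentials = [qm_ionic_potential(atoms, grid) for atoms in qm_atoms]
    n_electrons = [sum(a.n_valence for a in atoms) for atoms in qm_atoms]
    natoms_total = geom.n_atoms

    sites = _mm_sites(geom, cfg.mm_params)
    have_mm = len(sites) > 0
    v_mm = mm_ionic_potential(sites, grid) if have_mm else None

    # dipole initialization: isolated-MM reference mu' (zero in charge-only mode)
    if have_mm and cfg.polarizable:
        dipoles = isolated_mm_reference(sites, cell=cell, thole_a=cfg.thole_a)
        mu_ref = {d.site_index: d.mu_ref.copy() for d in dipoles}
    else:
        dipoles, mu_ref = [], {}

    # QM density initialization (warm start when provided)
    subsystems: list[QMSubsystem] = []
    if start is not None:
        init_rhos = [s.density for s in start.qm_subsystems]
    else:
        init_rhos = [None] * len(qm_fids)

    energy_prev = None
    rho_prev = None
    trace = []
    converged = False

    for it in range(1, cfg.max_outer + 1):
        rho_mm = (
            assemble_mm_density(sites, dipoles, grid) if have_mm else None
        )

        new_subsystems = []
        for k in range(len(qm_fids)):
            rho_other = rho_mm.copy() if have_mm else ScalarField.zeros(grid)
            v_other = v_mm.copy() if have_mm else ScalarField.zeros(grid)
            for j, sub in enumerate(subsystems):
                if j != k:
                    rho_other = rho_other + sub.density
                    v_other = v_other + qm_potentials[j]
            rho_k = subsystems[k].density if subsystems else init_rhos[k]
            embedded = have_mm or len(qm_fids) > 1
            emb = (
                EmbeddingTerm(
                    rho_other, v_other, cfg.kinetic_nonadditive,
                    include_kinetic=cfg.include_ts_nad,
                    include_xc=cfg.include_xc_nad,
                )
                if embedded
                else None
            )
            sub = minimize_ofdft(
                qm_potentials[k],
                n_electrons[k],
                cfg.kinetic_additive,
                init=rho_k,
                atoms=qm_atoms[k],
                embedding=emb,
                tol=cfg.inner_tol * max(len(qm_atoms[k]), 1),
                max_iter=cfg.inner_max_iter,
            )
            new_subsystems.append(sub)
        subsystems = new_subsystems

        # classical embedding field at the MM sites, dipole re-solve + mixing
        max_dmu = 0.0
        if have_mm and cfg.polarizable and subsystems:
            rho_qm_tot = subsystems[0].density
            for s in subsystems[1:]:
                rho_qm_tot = rho_qm_tot + s.density
            v_qm_tot = qm_potentials[0]
            for v in qm_potentials[1:]:
                v_qm_tot = v_qm_tot + v
            field = qm_field_at_mm_sites(rho_qm_tot, v_qm_tot, sites)
            ext = np.array(field)
            new_dipoles = solve_induced_dipoles(
                sites, external_field=ext, cell=cell, thole_a=cfg.thole_a
            )
            old = {d.site_index: d.mu for d in dipoles}
            mixed = []
            for d in new_dipoles:
                mu_old = old.get(d.site_index, np.zeros(3))
                mu = (1.0 - cfg.dipole_mixing) * mu_old + cfg.dipole_mixing * d.mu
                max_dmu = max(max_dmu, float(np.max(np.abs(mu - mu_old))))
                mixed.append(
                    InducedDipole(
                        d.site_index, mu, mu_ref.get(d.site_index, np.zeros(3))
                    )
                )
            dipoles = mixed

        breakdown = _total_energy(
            cfg, grid, subsystems, qm_potentials, sites, dipoles,
            assemble_mm_density(sites, dipoles, grid) if have_mm else None,
            v_mm, cell,
        )
        energy = breakdown.total

        rho_qm_tot = None
        if subsystems:
            rho_qm_tot = subsystems[0].density
            for s in subsystems[1:]:
                rho_qm_tot = rho_qm_tot + s.density
        if rho_qm_tot is None:
            d_rho = 0.0
        elif rho_prev is not None:
            diff = rho_qm_tot.values - rho_prev.values
            d_rho = float(np.sqrt(np.sum(diff**2) * grid.dv * cell.volume))
        else:
            d_rho = np.inf
        d_e = np.inf if energy_prev is None else energy - energy_prev
        trace.append(
            {
                "iteration": it,
                "E_total": energy,
                "dE": d_e,
                "d_rho": d_rho,
                "max_dmu": max_dmu,
            }
        )
        logger.info(
            "iter %3d  E_total=%.10f Ha  dE=%.3e  |d_rho|=%.3e e  max|d_mu|=%.3e",
            it, energy, d_e if np.isfinite(d_e) else float("nan"), d_rho, max_dmu,
        )

        if energy_prev is not None:
            # cycling detector: the energy increments must keep shrinking;
            # small transient uphill steps during damped dipole relaxation are
            # normal, a non-decaying |dE| envelope is not
            des = [abs(t["dE"]) for t in trace[2:] if np.isfinite(t["dE"])]
            tol_total = cfg.scf_energy_tol * max(natoms_total, 1)
            if len(des) >= 12:
                recent, earlier = max(des[-6:]), max(des[-12:-6])
                if recent > 0.8 * earlier and recent > 100.0 * tol_total:
                    raise OscillationError(
                        "outer SCF energy is cycling instead of descending",
                        trace=trace,
                    )
            dipole_done = (not cfg.polarizable) or max_dmu < 1e-7
            if (
                abs(d_e) < cfg.scf_energy_tol * max(natoms_total, 1)
                and d_rho < cfg.scf_density_tol
                and dipole_done
            ):
                converged = True
        energy_prev = energy
        rho_prev = rho_qm_tot
        if converged:
            break
        if not have_mm and len(qm_fids) <= 1 and it >= 1:
            converged = True  # bare minimization: nothing left to iterate
            break

    mm_state = MMState(
        sites,
        dipoles,
        *(
            mm_internal_energy(
                sites, dipoles, external_field=None, cell=cell,
                thole_a=cfg.thole_a, return_parts=True,
            )
            if have_mm
            else (0.0, 0.0, 0.0)
        ),
    )
    return QMMMResults(
        model=model,
        system=system,
        grid=grid,
        qm_subsystems=subsystems,
        qm_potentials=qm_potentials,
        mm_state=mm_state,
        breakdown=breakdown,
        scf_trace=trace,
        converged=converged,
    )


class QMMMResults:
    """Converged state of a QM/MM run.

    Attributes
    ----------
    qm_subsystems : list of QMSubsystem
    mm_state : MMState
    breakdown : EnergyBreakdown
    scf_trace : list of per-iteration records
    converged : bool
    """

    def __init__(
        self, model, system, grid, qm_subsystems, qm_potentials, mm_state,
        breakdown, scf_trace, converged,
    ):
        self.model = model
        self.system = system
        self.grid = grid
        self.qm_subsystems = qm_subsystems
        self.qm_potentials = qm_potentials
        self.mm_state = mm_state
        self.breakdown = breakdown
        self.scf_trace = scf_trace
        self.converged = converged

    @property
    def total_energy(self) -> float:
        """Total energy (Ha)."""
        return self.breakdown.total

    @property
    def qm_density(self) -> ScalarField | None:
        if not self.qm_subsystems:
            return None
        rho = self.qm_subsystems[0].density
        for s in self.qm_subsystems[1:]:
            rho = rho + s.density
        return rho

    def qm_dipole_moment(self) -> np.ndarray:
        """Electron+ion dipole of the QM region about its ionic centroid (e*bohr)."""
        rho = self.qm_density
        if rho is None:
            return np.zeros(3)
        atoms = [a for s in self.qm_subsystems for a in s.atoms]
        center = np.mean([a.position for a in atoms], axis=0)
        mu = np.zeros(3)
        for a in atoms:
            mu += a.n_valence * (a.position - center)  # ionic (+) part
        dr = rho.grid.coordinates - center.reshape(3, 1, 1, 1)
        frac = np.einsum(
            "exyz,ed->dxyz", dr, np.linalg.inv(rho.grid.cell.lattice).T
        )
        frac -= np.round(frac)
        dr = np.einsum("dxyz,de->exyz", frac, rho.grid.cell.lattice)
        mu -= np.sum(dr * rho.values[None], axis=(1, 2, 3)) * rho.grid.dv
        return mu

    def summary(self) -> str:
        lines = ["Density-functionalized QM/MM results", "=" * 44]
        lines.append(f"converged            : {self.converged}")
        lines.append(f"outer iterations     : {len(self.scf_trace)}")
        lines.append(f"grid                 : {self.grid.shape}, cutoff {self.grid.cutoff} Ha")
        lines.append(
            f"QM subsystems        : {len(self.qm_subsystems)}   "
            f"MM sites: {len(self.mm_state.sites)}"
        )
        lines.append(
            f"total energy         : {self.total_energy:.10f} Ha "
            f"({self.total_energy * HARTREE_TO_KCALMOL:.6f} kcal/mol)"
        )
        lines.append("")
        lines.append(self.breakdown.to_report())
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Energy change per outer iteration on a log scale."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        its = [t["iteration"] for t in self.scf_trace[1:]]
        des = [abs(t["dE"]) for t in self.scf_trace[1:]]
        ax.semilogy(its, des, "o-")
        ax.set_xlabel("outer iteration")
        ax.set_ylabel("|dE| (Ha)")
        return ax


# ---------------------------------------------------------------------------
# interaction energies and scans
# ---------------------------------------------------------------------------

def isolated_mm_energy(system: QMMMSystem) -> float:
    """Classical energy of the MM subsystem alone (its own dipoles mu') in Ha."""
    cfg = system.config
    sites = _mm_sites(system.geometry, cfg.mm_params)
    if not sites:
        return 0.0
    if cfg.polarizable:
        dipoles = isolated_mm_reference(sites, cell=system.cell, thole_a=cfg.thole_a)
    else:
        dipoles = []
    return mm_internal_energy(
        sites, dipoles, external_field=None, cell=system.cell, thole_a=cfg.thole_a
    )


def interaction_energy(
    result: QMMMResults,
    isolated_qm,
    isolated_mm_energy_ha: float = 0.0,
) -> float:
    """E_int = E_total - sum(E_isolated fragments), in kcal/mol.

    ``isolated_qm`` is one result or a list of results for the isolated QM
    fragments, which must share the cell, grid cutoff and functional
    configuration with ``result``.
    """
    iso = isolated_qm if isinstance(isolated_qm, (list, tuple)) else [isolated_qm]
    for r in iso:
        if not (r.system.cell == result.system.cell):
            raise InconsistencyError("isolated runs must share the simulation cell")
        if not r.system.config.matches(result.system.config):
            raise InconsistencyError("isolated runs must share the run configuration")
    e = result.total_energy - sum(r.total_energy for r in iso) - isolated_mm_energy_ha
    return e * HARTREE_TO_KCALMOL


def _scan_roles(geom: Geometry, solute_fids, ordering, n_qm: int) -> dict:
    roles = {f: "MM" for f in geom.fragment_ids}
    for f in solute_fids:
        roles[f] = "QM"
    for f in ordering[:n_qm]:
        roles[f] = "QM"
    return roles


def qm_size_scan(
    base_system: QMMMSystem,
    ordering,
    sizes,
) -> pd.DataFrame:
    """Interaction energy vs the number of solvent molecules promoted to QM.

    ``ordering`` lists the solvent fragment ids sorted by distance to the
    solute; it must cover every MM fragment of the base system.  For each
    size, the n nearest solvent molecules become separate QM subsystems and
    the solute-environment interaction energy is recorded in both the
    polarizable and the charge-only variant of the MM model.

    The returned frame carries ``attrs["convergence_band_kcal"]`` (the
    configured target window, default +-2 kcal/mol) and
    ``attrs["band_converged"]``: per variant, whether the last two sizes
    differ by less than the band.
    """
    geom = base_system.geometry
    cfg = base_system.config
    solute_fids = geom.fragments_with_role("QM")
    mm_fids = set(geom.fragments_with_role("MM"))
    if set(ordering) != mm_fids:
        raise InconsistencyError("ordering must cover exactly the solvent fragments")

    iso_solute = {}
    rows = []
    for polarizable in (True, False):
        cfg_v = replace(cfg, polarizable=polarizable)
        key = "E_int_polarizable" if polarizable else "E_int_charge_only"
        for n_qm in sizes:
            roles = _scan_roles(geom, solute_fids, list(ordering), int(n_qm))
            full = QMMM(geom.with_roles(roles), cfg_v).fit()
            # environment alone: same partition with the solute removed
            env_idx = [
                i for i in range(geom.n_atoms)
                if int(geom.fragments[i]) not in solute_fids
            ]
            remap = {f: f for f in geom.fragment_ids if f not in solute_fids}
            env_geom = Geometry(
                [geom.elements[i] for i in env_idx],
                geom.positions[env_idx],
                geom.cell,
                geom.fragments[env_idx],
                {f: roles[f] for f in remap},
            )
            env = QMMM(env_geom, cfg_v).fit()
            if polarizable not in iso_solute:
                solute_idx = [
                    i for i in range(geom.n_atoms)
                    if int(geom.fragments[i]) in solute_fids
                ]
                sol_geom = Geometry(
                    [geom.elements[i] for i in solute_idx],
                    geom.positions[solute_idx],
                    geom.cell,
                    geom.fragments[solute_idx],
                    {f: "QM" for f in solute_fids},
                )
                iso_solute[polarizable] = QMMM(sol_geom, cfg_v).fit()
            e_int = (
                full.total_energy
                - env.total_energy
                - iso_solute[polarizable].total_energy
            ) * HARTREE_TO_KCALMOL
            rows.append({"n_qm_waters": int(n_qm), key: e_int})

    df = pd.DataFrame(rows).groupby("n_qm_waters").first().reset_index()
    df.attrs["convergence_band_kcal"] = cfg.scan_convergence_band
    df.attrs["band_converged"] = {
        col: (
            bool(abs(df[col].iloc[-1] - df[col].iloc[-2]) < cfg.scan_convergence_band)
            if len(df) >= 2
            else False
        )
        for col in ("E_int_polarizable", "E_int_charge_only")
    }
    return df
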