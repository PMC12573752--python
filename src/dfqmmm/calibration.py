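"""Width-calibration evaluators.

The width fit needs many interaction-energy evaluations as the Gaussian
widths vary.  A full mutual-polarization SCF per evaluation is wasteful:
the QM density relaxation and the induced dipoles are only weakly coupled to
the MM widths.  The frozen-density evaluator therefore precomputes, per
configuration, the vacuum QM density (one orbital-free minimization) and the
dipoles induced by its field, then evaluates the width-dependent interaction

    E_int(theta) = E_nad[rho_QM, rho_MM(theta)] + E_ion-ion(theta)

with the ion-ion cross term in closed form (two-Gaussian Coulomb with
minimum image).  This is the model used both to generate internal reference
energies (at known widths) and to fit them back.
"""

from __future__ import annotations

from math import erf, sqrt

import numpy as np

from .driver import RunConfig, _mm_sites, _qm_fragment_atoms
from .grid import build_grid, integrate, solve_hartree
from .mm_density import assemble_mm_density, mm_ionic_potential
from .functionals import kinetic_functional, xc_energy
from .nonadditive import qm_field_at_mm_sites
from .ofdft import minimize_ofdft, qm_ionic_potential
from .polarizable import solve_induced_dipoles
from .units import HARTREE_TO_KCALMOL

__all__ = ["WIDTH_PARAM_NAMES", "frozen_density_width_evaluator", "dimer_width_evaluator"]

WIDTH_PARAM_NAMES = ("sigma_q_O", "sigma_q_H", "sigma_mu_O", "sigma_mu_H")


def _two_gaussian_coulomb(q1, q2, d, s1, s2):
    s = sqrt(2.0 * (s1**2 + s2**2))
    if d < 1e-12:
        return 2.0 * q1 * q2 / (sqrt(np.pi) * s)
    return q1 * q2 * erf(d / s) / d


class _FrozenConfiguration:
    """Per-geometry precomputation for the width evaluator."""

    def __init__(self, geometry, cfg: RunConfig):
        self.geometry = geometry
        self.cfg = cfg
        self.grid = build_grid(geometry.cell, cfg.cutoff)
        qm_fids = geometry.fragments_with_role("QM")
        atoms = [
            a
            for fid in qm_fids
            for a in _qm_fragment_atoms(geometry, fid, cfg.mm_params)
        ]
        self.qm_atoms = atoms
        v_qm = qm_ionic_potential(atoms, self.grid)
        sub = minimize_ofdft(
            v_qm,
            sum(a.n_valence for a in atoms),
            cfg.kinetic_additive,
            atoms=atoms,
            tol=cfg.inner_tol * max(len(atoms), 1),
            max_iter=cfg.inner_max_iter,
        )
        self.rho_qm = sub.density
        self.v_qm = v_qm
        self.hartree_qm = solve_hartree(self.rho_qm)
        from .driver import _ionic_density_for_atoms

        # grid-evaluated so every electrostatic piece shares the same
        # neutralizing-background convention (they only cancel jointly)
        self.hartree_ion_qm = solve_hartree(_ionic_density_for_atoms(atoms, self.grid))
        self.t_qm = kinetic_functional(
            self.rho_qm, cfg.kinetic_nonadditive, potential=False
        ).energy
        self.xc_qm = xc_energy(self.rho_qm, potential=False).energy
        # dipole directions/magnitudes are width-independent: they respond to
        # the grid-evaluated QM field and the permanent charges only
        self.sites0 = _mm_sites(geometry, cfg.mm_params)
        if cfg.polarizable and self.sites0:
            field = qm_field_at_mm_sites(self.rho_qm, v_qm, self.sites0)
            self.dipoles = solve_induced_dipoles(
                self.sites0, external_field=np.array(field),
                cell=geometry.cell, thole_a=cfg.thole_a,
            )
        else:
            self.dipoles = []

    def energy(self, widths: dict) -> float:
        """Interaction energy (kcal/mol) at the given per-element widths."""
        params = {
            el: dict(p) for el, p in self.cfg.mm_params.items()
        }
        for el in params:
            if f"sigma_q_{el}" in widths:
                params[el]["sigma_q"] = widths[f"sigma_q_{el}"]
            if f"sigma_mu_{el}" in widths:
                params[el]["sigma_mu"] = widths[f"sigma_mu_{el}"]
            if f"k_SE_{el}" in widths:
                params[el]["k_SE"] = widths[f"k_SE_{el}"]
        sites = _mm_sites(self.geometry, params)
        grid = self.grid
        rho_mm = assemble_mm_density(sites, self.dipoles, grid)
        v_mm = mm_ionic_potential(sites, grid)

        # kinetic/xc functionals see the clipped (nonnegative) mapped density;
        # Coulomb terms keep the exact one -- same convention as the driver
        from .grid import ScalarField

        rho_mm_f = ScalarField(grid, np.maximum(rho_mm.values, 0.0))
        rho_tot = self.rho_qm + rho_mm_f
        knad = self.cfg.kinetic_nonadditive
        ts_nad = (
            kinetic_functional(rho_tot, knad, potential=False).energy
            - self.t_qm
            - kinetic_functional(rho_mm_f, knad, potential=False).energy
        )
        xc_nad = (
            xc_energy(rho_tot, potential=False).energy
            - self.xc_qm
            - xc_energy(rho_mm_f, potential=False).energy
        )
        coul = integrate(rho_mm * self.hartree_qm)
        ext = integrate(rho_mm * self.v_qm) + integrate(self.rho_qm * v_mm)

        from .mm_density import ionic_charge_density

        e_ii = integrate(ionic_charge_density(sites, grid) * self.hartree_ion_qm)
        # self-energy correction at the frozen dipoles (k_SE may be fitted)
        e_se = sum(
            sites[d.site_index].k_SE * float(np.sum((d.mu - d.mu_ref) ** 2))
            for d in self.dipoles
        )
        return (ts_nad + xc_nad + coul + ext + e_ii + e_se) * HARTREE_TO_KCALMOL


def frozen_density_width_evaluator(
    geometries,
    cfg: RunConfig,
    param_names=WIDTH_PARAM_NAMES,
):
    """Build ``evaluator(theta) -> energies`` plus start point and bounds.

    ``theta`` is ordered by ``param_names``; the start point is the config's
    current widths, bounds are [0.55 * max grid spacing * 3, 3.0] bohr for
    widths (resolvability-safe) and [0, 1] for k_SE entries.
    """
    configs = [_FrozenConfiguration(g, cfg) for g in geometries]
    hmax = max(float(np.max(c.grid.spacing)) for c in configs)

    def evaluator(theta):
        widths = dict(zip(param_names, np.asarray(theta, float)))
        return np.array([c.energy(widths) for c in configs])

    x0, lo, hi = [], [], []
    for name in param_names:
        if name.startswith("k_SE"):
            el = name.split("_")[-1]
            x0.append(cfg.mm_params[el].get("k_SE", 0.0))
            lo.append(0.0)
            hi.append(1.0)
        else:
            kind, el = name.rsplit("_", 1)
            key = "sigma_q" if kind == "sigma_q" else "sigma_mu"
            x0.append(cfg.mm_params[el][key])
            lo.append(max(1.5 * hmax, 0.3))
            hi.append(3.0)
    return evaluator, np.array(x0), tuple(param_names), (np.array(lo), np.array(hi))


def dimer_width_evaluator(geometry, cfg: RunConfig, n_configs: int = 6):
    """Width evaluator over a small scan of modified copies of a dimer.

    Generates ``n_configs`` geometries by scaling the QM-MM separation of the
    input two-fragment geometry between 0.9x and 1.3x and simultaneously
    rotating the MM fragment about its centroid, so that different atoms face
    the QM region.  The orientational diversity gives the residuals
    independent sensitivity to all four (charge and dipole, O and H) widths.
    """
    from .io import Geometry, _rotation_about

    geoms = []
    qm_fids = geometry.fragments_with_role("QM")
    mm_fids = geometry.fragments_with_role("MM")
    qm_idx = [i for f in qm_fids for i in geometry.fragment_atoms(f)]
    mm_idx = [i for f in mm_fids for i in geometry.fragment_atoms(f)]
    c_qm = np.mean(geometry.positions[qm_idx], axis=0)
    c_mm = np.mean(geometry.positions[mm_idx], axis=0)
    axis = geometry.cell.minimum_image(c_mm - c_qm)
    for k, f in enumerate(np.linspace(0.9, 1.3, n_configs)):
        pos = geometry.positions.copy()
        R = _rotation_about([0.0, 1.0, 0.0], 2.0 * np.pi * k / max(n_configs, 1))
        center = c_mm + (f - 1.0) * axis
        pos[mm_idx] = (pos[mm_idx] - c_mm) @ R.T + center
        geoms.append(
            Geometry(
                list(geometry.elements), pos, geometry.cell,
                geometry.fragments.copy(), dict(geometry.roles),
            )
        )
    return frozen_density_width_evaluator(geoms, cfg)
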