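"""Nonadditive interaction energy and embedding objects.

The subsystem-DFT interaction between two electron densities rho_A, rho_B with
external (ionic) potentials v_A, v_B is

    E_nad = T_s^nad + E_xc^nad + int rho_A(r) rho_B(r') / |r-r'|
          + int rho_B v_A + int rho_A v_B

with F^nad[rho_A, rho_B] = F[rho_A + rho_B] - F[rho_A] - F[rho_B] for the
kinetic and exchange-correlation pieces.  The nonadditive kinetic term encodes
Pauli repulsion between fragments and prevents charge spill-out.

The embedding potential felt by fragment A is the functional derivative of
E_nad with respect to rho_A, computed in the potential-difference form
v_F[rho_A + rho_B] - v_F[rho_A], which is exact for any semilocal functional.

The field that polarizes the classical dipoles retains only the classical
electrostatic part of the MM-side embedding potential (ionic + Hartree of the
QM density), evaluated at the grid point nearest each site.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .functionals import KineticConfig, kinetic_functional, xc_energy
from .grid import ScalarField, integrate, solve_hartree, spectral_gradient
from .mm_density import MMSite
from .units import HARTREE_TO_KCALMOL

__all__ = [
    "EnergyBreakdown",
    "nonadditive_energy",
    "embedding_potential_qm",
    "qm_field_at_mm_sites",
]


@dataclass
class EnergyBreakdown:
    """Additive + nonadditive energy components of a QM/MM state (Ha)."""

    T_s_nad: float = 0.0
    E_xc_nad: float = 0.0
    E_coul_cross: float = 0.0
    E_ext_cross_AonB: float = 0.0  # int rho_B v_A
    E_ext_cross_BonA: float = 0.0  # int rho_A v_B
    additive: dict = dc_field(default_factory=dict)  # per-subsystem components
    ion_ion: float = 0.0
    E_mm_classical: float = 0.0
    #: nonadditive coupling among multiple QM subsystems (zero for one subsystem)
    E_qm_internal_nad: float = 0.0

    @property
    def total_nad(self) -> float:
        return (
            self.T_s_nad
            + self.E_xc_nad
            + self.E_coul_cross
            + self.E_ext_cross_AonB
            + self.E_ext_cross_BonA
        )

    @property
    def total(self) -> float:
        add = sum(sum(comp.values()) for comp in self.additive.values())
        return (
            add
            + self.total_nad
            + self.E_qm_internal_nad
            + self.ion_ion
            + self.E_mm_classical
        )

    def to_report(self) -> str:
        """Flat key/value report with Ha and kcal/mol columns."""
        rows = [
            ("T_s_nad", self.T_s_nad),
            ("E_xc_nad", self.E_xc_nad),
            ("E_coul_cross", self.E_coul_cross),
            ("E_ext_cross_AonB", self.E_ext_cross_AonB),
            ("E_ext_cross_BonA", self.E_ext_cross_BonA),
            ("total_nad", self.total_nad),
            ("E_qm_internal_nad", self.E_qm_internal_nad),
            ("ion_ion", self.ion_ion),
            ("E_mm_classical", self.E_mm_classical),
        ]
        for name, comp in self.additive.items():
            for key, val in comp.items():
                rows.append((f"{name}.{key}", val))
        rows.append(("total", self.total))
        lines = [f"{'component':<24s} {'Ha':>18s} {'kcal/mol':>18s}"]
        for key, val in rows:
            lines.append(f"{key:<24s} {val:>18.10f} {val * HARTREE_TO_KCALMOL:>18.6f}")
        return "\n".join(lines)


def nonadditive_energy(
    rhoA: ScalarField,
    rhoB: ScalarField,
    vA: ScalarField,
    vB: ScalarField,
    cfg: KineticConfig,
) -> EnergyBreakdown:
    """Five-term nonadditive energy of two fragments on a shared grid.

    T_s^nad uses the configured (GGA by default) kinetic functional; E_xc^nad
    uses PBE.  Symmetric under exchange of (A, B).
    """
    from .exceptions import GridMismatchError

    for f in (rhoB, vA, vB):
        if not rhoA.grid.compatible_with(f.grid):
            raise GridMismatchError("nonadditive_energy requires a shared grid")
    rho_tot = rhoA + rhoB
    ts_nad = (
        kinetic_functional(rho_tot, cfg).energy
        - kinetic_functional(rhoA, cfg).energy
        - kinetic_functional(rhoB, cfg).energy
    )
    exc_nad = xc_energy(rho_tot).energy - xc_energy(rhoA).energy - xc_energy(rhoB).energy
    coul = integrate(rhoA * solve_hartree(rhoB))
    ext_AonB = integrate(rhoB * vA)
    ext_BonA = integrate(rhoA * vB)
    return EnergyBreakdown(
        T_s_nad=ts_nad,
        E_xc_nad=exc_nad,
        E_coul_cross=coul,
        E_ext_cross_AonB=ext_AonB,
        E_ext_cross_BonA=ext_BonA,
    )


def embedding_potential_qm(
    rhoQM: ScalarField,
    rhoMM: ScalarField,
    vMM: ScalarField,
    cfg: KineticConfig,
    include_kinetic: bool = True,
    include_xc: bool = True,
) -> ScalarField:
    """Embedding potential entering the QM Hamiltonian (Ha per electron).

    v_emb = v_MM + Hartree(rho_MM) + dT_s^nad/drho_QM + dE_xc^nad/drho_QM,
    with the nonadditive derivatives in potential-difference form
    v_F[rho_QM + rho_MM] - v_F[rho_QM].  ``include_kinetic=False`` omits the
    Pauli-repulsion term (the charge spill-out diagnostic).
    """
    from .exceptions import GridMismatchError

    if not (rhoQM.grid.compatible_with(rhoMM.grid) and rhoQM.grid.compatible_with(vMM.grid)):
        raise GridMismatchError("embedding_potential_qm requires a shared grid")
    v = vMM + solve_hartree(rhoMM)
    if include_kinetic or include_xc:
        rho_tot = rhoQM + rhoMM
        if include_kinetic:
            v = v + (
                kinetic_functional(rho_tot, cfg).potential
                - kinetic_functional(rhoQM, cfg).potential
            )
        if include_xc:
            v = v + (xc_energy(rho_tot).potential - xc_energy(rhoQM).potential)
    return v


def qm_field_at_mm_sites(
    rhoQM: ScalarField,
    vQM: ScalarField,
    sites: Sequence[MMSite],
) -> list[np.ndarray]:
    """Classical part of the QM embedding field at each MM site.

    Returns -grad[v_QM + Hartree(rho_QM)] (the electron-convention field; the
    energy-minimizing electron-displacement dipole is alpha times this)
    evaluated at the real-space grid point nearest each site position, ties
    broken toward the lower index.  Nonadditive kinetic/xc contributions are
    excluded by design: classical polarizabilities are parametrized for
    long-range (electrostatic) response only.
    """
    w = vQM + solve_hartree(rhoQM)
    grad = spectral_gradient(w)
    out = []
    for site in sites:
        idx = rhoQM.grid.nearest_index(site.position)
        out.append(-grad.at_index(idx).copy())
    return out
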