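"""Backward mapping: Gaussian site densities, dipole densities, ionic potential."""

import numpy as np
import pytest

from dfqmmm.exceptions import ResolutionError
from dfqmmm.grid import (
    SimulationCell,
    build_grid,
    integrate,
    solve_hartree,
)
from dfqmmm.mm_density import (
    InducedDipole,
    MMSite,
    assemble_mm_density,
    charge_density,
    dipole_density,
    ionic_charge_density,
    mm_ionic_potential,
)


@pytest.fixture
def o_site():
    return MMSite(
        position=[7.0, 7.0, 7.0], element="O", q=-0.834, N=6.0,
        sigma_q=1.1, sigma_mu=1.0, alpha=5.65,
    )


def min_image_dr(grid, center):
    dr = grid.coordinates - np.asarray(center, float).reshape(3, 1, 1, 1)
    inv = np.linalg.inv(grid.cell.lattice)
    frac = np.einsum("exyz,ed->dxyz", dr, inv.T)
    frac -= np.round(frac)
    return np.einsum("dxyz,de->exyz", frac, grid.cell.lattice)


class TestChargeDensity:
    def test_integrates_to_N_minus_q(self, small_grid, o_site):
        rho = charge_density(o_site, small_grid)
        assert integrate(rho) == pytest.approx(o_site.N - o_site.q, rel=1e-6)

    def test_lattice_translation_identity(self, small_grid, o_site):
        rho1 = charge_density(o_site, small_grid)
        shifted = MMSite(
            position=np.array(o_site.position) + small_grid.cell.lattice[0],
            element="O", q=o_site.q, N=o_site.N, sigma_q=o_site.sigma_q,
        )
        rho2 = charge_density(shifted, small_grid)
        assert np.max(np.abs(rho1.values - rho2.values)) < 1e-12

    def test_spherical_symmetry_no_dipole(self, small_grid, o_site):
        """The site electron density has zero dipole about its own center."""
        rho = charge_density(o_site, small_grid)
        dr = min_image_dr(small_grid, o_site.position)
        mom = np.sum(dr * rho.values[None], axis=(1, 2, 3)) * small_grid.dv
        assert np.max(np.abs(mom)) < 1e-7  # wrap-around tails only

    def test_underresolved_width_rejected(self, small_grid):
        bad = MMSite(position=[1.0, 1.0, 1.0], sigma_q=0.3)
        with pytest.raises(ResolutionError):
            charge_density(bad, small_grid)


class TestDipoleDensity:
    def test_zero_dipole_zero_field(self, small_grid, o_site):
        d = InducedDipole(0, [0.0, 0.0, 0.0])
        rho = dipole_density(d, o_site, small_grid)
        assert np.all(rho.values == 0.0)

    def test_integrates_to_zero(self, small_grid, o_site):
        d = InducedDipole(0, [0.2, -0.1, 0.05])
        assert abs(integrate(dipole_density(d, o_site, small_grid))) < 1e-8

    def test_first_moment_equals_mu(self, small_grid, o_site):
        """int (r - R) rho_mu dr = mu in the electron-density convention."""
        mu = np.array([0.12, -0.07, 0.03])
        rho = dipole_density(InducedDipole(0, mu), o_site, small_grid)
        dr = min_image_dr(small_grid, o_site.position)
        mom = np.sum(dr * rho.values[None], axis=(1, 2, 3)) * small_grid.dv
        assert np.allclose(mom, mu, atol=1e-8)

    def test_quadrupole_vanishes(self, small_grid, o_site):
        """Traceless second moments vanish about the site (odd x Gaussian)."""
        mu = np.array([0.1, 0.05, -0.02])
        rho = dipole_density(InducedDipole(0, mu), o_site, small_grid)
        dr = min_image_dr(small_grid, o_site.position)
        for a in range(3):
            for b in range(3):
                if a == b:
                    continue
                q_ab = np.sum(dr[a] * dr[b] * rho.values) * small_grid.dv
                assert abs(q_ab) < 1e-8


class TestAssemble:
    def test_single_site_equals_charge_density(self, small_grid, o_site):
        rho1 = assemble_mm_density([o_site], [], small_grid)
        rho2 = charge_density(o_site, small_grid)
        assert np.max(np.abs(rho1.values - rho2.values)) < 1e-14

    def test_linearity_over_disjoint_sets(self, small_grid, o_site):
        h = MMSite(position=[9.0, 7.5, 7.0], element="H", q=0.417, N=1.0,
                   sigma_q=0.9, sigma_mu=0.8)
        both = assemble_mm_density([o_site, h], [], small_grid)
        sep = (
            assemble_mm_density([o_site], [], small_grid)
            + assemble_mm_density([h], [], small_grid)
        )
        assert np.max(np.abs(both.values - sep.values)) < 1e-12

    def test_water_integral_independent_of_dipoles(self, small_grid):
        sites = [
            MMSite(position=[7.0, 7.0, 7.0], element="O", q=-0.834, N=6.0,
                   sigma_q=1.1, sigma_mu=1.0),
            MMSite(position=[8.5, 7.8, 7.0], element="H", q=0.417, N=1.0,
                   sigma_q=0.9, sigma_mu=0.8),
            MMSite(position=[5.7, 8.0, 7.2], element="H", q=0.417, N=1.0,
                   sigma_q=0.9, sigma_mu=0.8),
        ]
        expected = sum(s.N - s.q for s in sites)
        for mus in ([[0, 0, 0]] * 3, [[0.3, -0.2, 0.1], [0.05, 0, 0], [0, 0.1, -0.4]]):
            dips = [InducedDipole(i, m) for i, m in enumerate(mus)]
            rho = assemble_mm_density(sites, dips, small_grid)
            assert integrate(rho) == pytest.approx(expected, rel=1e-10)

    def test_permutation_invariance(self, small_grid, o_site):
        h = MMSite(position=[9.0, 7.5, 7.0], element="H", q=0.417, N=1.0,
                   sigma_q=0.9, sigma_mu=0.8)
        r1 = assemble_mm_density([o_site, h], [], small_grid)
        r2 = assemble_mm_density([h, o_site], [], small_grid)
        assert np.max(np.abs(r1.values - r2.values)) < 1e-14

    def test_dangling_dipole_reference(self, small_grid, o_site):
        with pytest.raises(IndexError):
            assemble_mm_density([o_site], [InducedDipole(3, [0.1, 0, 0])], small_grid)


class TestIonicPotential:
    def test_empty_sites_zero(self, small_grid):
        v = mm_ionic_potential([], small_grid)
        assert np.all(v.values == 0.0)

    def test_far_field_minus_N_over_r(self):
        """Spherically, v -> -N/r at r = 6 sigma_core (background-corrected)."""
        L = 40.0
        cell = SimulationCell.cubic(L)
        grid = build_grid(cell, 8.0)
        site = MMSite(position=[L / 2] * 3, element="O", q=0.0, N=6.0, sigma_q=1.6)
        v = mm_ionic_potential([site], grid)
        r = 6.0 * site.sigma_core
        # sample several directions at radius r; subtract the jelly quadratic
        # and the (constant-canceling) reference at a second radius
        vals = []
        for u in np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1] / np.sqrt(3)]):
            idx = grid.nearest_index(np.array([L / 2] * 3) + r * u)
            pt = grid.coordinates[:, idx[0], idx[1], idx[2]]
            rr = np.linalg.norm(pt - np.array([L / 2] * 3))
            # v = -phi(+N Gaussian): remove the (negated) jelly quadratic
            corr = 2.0 * np.pi * site.N * rr**2 / (3.0 * cell.volume)
            vals.append((v.values[idx] + corr, rr))
        idx0 = grid.nearest_index([L / 2 + 2.5 * r, L / 2, L / 2])
        pt0 = grid.coordinates[:, idx0[0], idx0[1], idx0[2]]
        rr0 = np.linalg.norm(pt0 - np.array([L / 2] * 3))
        ref = v.values[idx0] + 2.0 * np.pi * site.N * rr0**2 / (3.0 * cell.volume)
        for val, rr in vals:
            assert (val - ref) == pytest.approx(-6.0 / rr + 6.0 / rr0, rel=0.01)

    def test_superposition(self, small_grid, o_site):
        h = MMSite(position=[9.0, 7.5, 7.0], element="H", q=0.417, N=1.0, sigma_q=0.9)
        v_both = mm_ionic_potential([o_site, h], small_grid)
        v_sep = mm_ionic_potential([o_site], small_grid) + mm_ionic_potential(
            [h], small_grid
        )
        assert np.max(np.abs(v_both.values - v_sep.values)) < 1e-12

    def test_neutral_water_combined_potential_decays(self, small_grid):
        """Ionic + Hartree-of-electron potential of a neutral site set decays
        faster than a monopole: the total MM charge is sum(q_i) = 0."""
        sites = [
            MMSite(position=[7.0, 7.0, 7.0], element="O", q=-0.834, N=6.0,
                   sigma_q=1.1),
            MMSite(position=[8.5, 7.8, 7.0], element="H", q=0.417, N=1.0,
                   sigma_q=0.9),
            MMSite(position=[5.7, 8.0, 7.2], element="H", q=0.417, N=1.0,
                   sigma_q=0.9),
        ]
        rho_e = assemble_mm_density(sites, [], small_grid)
        rho_ion = ionic_charge_density(sites, small_grid)
        net = integrate(rho_ion) - integrate(rho_e)
        assert net == pytest.approx(sum(s.q for s in sites), abs=1e-8)
        assert abs(net) < 1e-8
        w = mm_ionic_potential(sites, small_grid) + solve_hartree(rho_e)
        # compare the spread of w on a far shell against a monopole's would-be
        # magnitude: a 1-electron monopole at 6 bohr would contribute ~0.17 Ha
        far = small_grid.min_image_distance([7.0, 7.5, 7.05]) > 6.0
        assert np.ptp(w.values[far]) < 0.05
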