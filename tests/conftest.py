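"""Shared fixtures: small grids, water fixtures, functional-derivative helper.

Problem sizes are deliberately small (cells of 12-14 bohr, cutoffs of
18-30 Ha) so the whole suite runs on one CPU in minutes while still resolving
every Gaussian width in the default water model.
"""

import numpy as np
import pytest

from dfqmmm.grid import ScalarField, SimulationCell, build_grid, integrate
from dfqmmm.mm_density import gaussian_density


@pytest.fixture(scope="session")
def small_grid():
    """14-bohr cube at 20 Ha: 30^3 points, resolves sigma >= 0.79 bohr."""
    return build_grid(SimulationCell.cubic(14.0), 20.0)


@pytest.fixture(scope="session")
def smooth_density(small_grid):
    """A strictly positive, structured density for functional tests."""
    g = small_grid
    c = np.full(3, 7.0)
    rho = gaussian_density(g, c, 6.0, 1.3) + gaussian_density(
        g, c + [1.5, 0.4, 0.2], 2.0, 1.0
    )
    return ScalarField(g, np.maximum(rho.values, 0.0) + 1e-7)


@pytest.fixture(scope="session")
def bump(small_grid):
    """Localized perturbation placed where the test density is substantial."""
    return gaussian_density(small_grid, np.full(3, 7.0) + [0.9, -0.7, 0.5], 1.0, 0.9)


def functional_derivative_error(fn, rho, bump, epsilons=(1e-3, 1e-4, 1e-5)):
    """Worst relative error of int(v * bump) vs centered finite differences."""
    res = fn(rho)
    pred = integrate(bump * res.potential)
    worst = 0.0
    for eps in epsilons:
        ep = fn(ScalarField(rho.grid, rho.values + eps * bump.values)).energy
        em = fn(
            ScalarField(rho.grid, np.maximum(rho.values - eps * bump.values, 0.0))
        ).energy
        fd = (ep - em) / (2.0 * eps)
        worst = max(worst, abs(fd / pred - 1.0))
    return worst


@pytest.fixture(scope="session")
def fd_error():
    return functional_derivative_error
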