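"""Shared fixtures: kinetic parameter sets, a cached lookup table, and
synthetic scaling-law constructions used as independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from spheroscale import (
    DimensionlessTable,
    radius_ladder,
    stem_cell_params,
)


@pytest.fixture(scope="session")
def stem_params():
    return stem_cell_params()


@pytest.fixture(scope="session")
def ladder():
    return radius_ladder()


@pytest.fixture(scope="session")
def stem_table(stem_params):
    """Dimensionless lookup table for the stem-cell kinetics (built once)."""
    return DimensionlessTable(stem_params)


def make_scaling_groups(
    delta0: float,
    n: int,
    mean_masses,
    seed: int,
    gamma0: float = 1.0,
    q2: float = 0.01,
    noise_sd: float = 0.2,
):
    """Synthetic populations that satisfy the scaling forms exactly.

    Masses are log-normal with Var(m) = q2·⟨m⟩^(2γ₀) around each
    conditioning mean (the canonical quadratic mass-variance law), and
    metabolic rates follow B = m^δ₀·ξ with iid positive multiplicative
    noise ξ of coefficient of variation ``noise_sd``.  By construction
    the joint law satisfies the generalized scaling form with exponents
    (γ₀, δ₀), and the B marginal satisfies the marginal form with δ₀.

    Returns a list of (m, B, mean_mass) tuples.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(q2))
    groups = []
    for M in mean_masses:
        mu = gamma0 * np.log(M) - sigma**2 / 2
        m = rng.lognormal(mu, sigma, n)
        xi = rng.normal(1.0, noise_sd, n)
        xi = np.where(xi > 1e-3, xi, 1e-3)
        B = m**delta0 * xi
        groups.append((m, B, M))
    return groups


#: mean masses spaced like three adjacent rungs of the default radius
#: ladder (mass ratio = (5000/31)^(3/16) per rung)
LADDER_MASS_TRIPLET = tuple(1e-9 * 2.594**k for k in range(3))


@pytest.fixture()
def scaling_groups_factory():
    return make_scaling_groups
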