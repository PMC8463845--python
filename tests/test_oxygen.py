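"""Oxygen solver: closed-form limits, conservation, lookup-table audit."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from spheroscale import (
    KineticParams,
    SizeDistributionSpec,
    build_population,
    metabolic_rate,
    nonviable_fraction,
    solve_population,
    solve_profile,
    stem_cell_params,
)
from spheroscale.oxygen import surface_flux_rate


def first_order_params():
    """c0 << k_M so the Michaelis-Menten sink is effectively linear."""
    return KineticParams(socr_mean=1e-17, k_M=200.0, D=3e-9, c0=0.2, C_crit=0.04)


def zeroth_order_params():
    """c0 >> k_M so the sink saturates at its maximal rate."""
    return KineticParams(socr_mean=1e-17, k_M=1e-6, D=3e-9, c0=0.2, C_crit=0.04)


class TestSolveProfile:
    def test_no_reaction_gives_flat_profile(self, stem_params):
        prof = solve_profile(200e-6, 0.0, stem_params)
        assert np.allclose(prof.conc, stem_params.c0)

    def test_profile_invariants(self, stem_params):
        prof = solve_profile(800e-6, stem_params.socr_mean, stem_params)
        assert prof.grid[0] == 0.0
        assert prof.grid[-1] == pytest.approx(800e-6)
        assert np.all(np.diff(prof.grid) > 0)
        assert np.all(np.diff(prof.conc) >= 0)  # c nondecreasing in r
        assert prof.conc[-1] == pytest.approx(stem_params.c0)
        assert np.all((prof.conc >= 0) & (prof.conc <= stem_params.c0 * (1 + 1e-12)))

    @pytest.mark.parametrize("R_um", [100, 500, 2000])
    def test_first_order_effectiveness_factor(self, R_um):
        # eta = (3/phi^2)(phi coth phi - 1) for a linear sink in a sphere
        p = first_order_params()
        R = R_um * 1e-6
        socr = 5e-14
        k1 = socr * p.rho_c / p.k_M
        phi = R * math.sqrt(k1 / p.D)
        eta = (3 / phi**2) * (phi / math.tanh(phi) - 1)
        prof = solve_profile(R, socr, p)
        B = metabolic_rate(prof, p, socr)
        B_exact = eta * k1 * p.c0 * (4 / 3) * math.pi * R**3
        assert B == pytest.approx(B_exact, rel=5e-3)

    def test_zeroth_order_center_drop(self):
        # without an anoxic core: c0 - c(0) = A R^2 / (6 D)
        p = zeroth_order_params()
        R, socr = 500e-6, 2e-17
        A = socr * p.rho_c
        prof = solve_profile(R, socr, p)
        drop = p.c0 - prof.conc[0]
        assert drop == pytest.approx(A * R**2 / (6 * p.D), rel=1e-2)

    def test_rejects_invalid_inputs(self, stem_params):
        with pytest.raises(ValueError):
            solve_profile(-1e-6, 1e-17, stem_params)
        with pytest.raises(ValueError):
            solve_profile(1e-4, -1e-18, stem_params)


class TestMetabolicRate:
    def test_zero_socr_gives_zero_rate(self, stem_params):
        prof = solve_profile(300e-6, 0.0, stem_params)
        assert metabolic_rate(prof, stem_params, 0.0) == 0.0

    @pytest.mark.parametrize(
        "R_um,socr", [(100, 9e-17), (700, 9e-17), (1500, 1.2e-16), (4000, 9e-17)]
    )
    def test_flux_equals_volume_integral(self, stem_params, R_um, socr):
        """Divergence theorem: surface flux == volume-integrated uptake."""
        prof = solve_profile(R_um * 1e-6, socr, stem_params)
        b_vol = metabolic_rate(prof, stem_params, socr)
        b_flux = surface_flux_rate(prof, stem_params)
        assert b_flux == pytest.approx(b_vol, rel=1e-3)

    def test_reaction_limited_limit_is_isometric(self, stem_params):
        # phi^2 <= 0.01: B -> socr rho_c (c0/(kM+c0)) V within 1%
        p = stem_params
        socr = p.socr_mean
        R = math.sqrt(0.01 * p.D * p.c0 / (socr * p.rho_c))
        prof = solve_profile(R, socr, p)
        B = metabolic_rate(prof, p, socr)
        B_iso = socr * p.rho_c * (p.c0 / (p.k_M + p.c0)) * (4 / 3) * math.pi * R**3
        assert B == pytest.approx(B_iso, rel=1e-2)

    def test_B_bounded_by_saturating_uptake(self, stem_params):
        socr = stem_params.socr_mean
        for R in [100e-6, 1000e-6, 4000e-6]:
            prof = solve_profile(R, socr, stem_params)
            B = metabolic_rate(prof, stem_params, socr)
            assert 0 <= B <= socr * stem_params.rho_c * (4 / 3) * math.pi * R**3


class TestNonviableFraction:
    def test_zero_when_center_above_threshold(self, stem_params):
        prof = solve_profile(100e-6, stem_params.socr_mean, stem_params)
        assert nonviable_fraction(prof, stem_params.C_crit) == 0.0

    def test_default_threshold_value(self, stem_params):
        assert stem_params.C_crit == 0.04

    def test_zeroth_order_core_closed_form(self):
        """Anoxic-core regime: r with c(r) = C_crit from the piecewise
        parabolic solution matches the solver within 1%."""
        p = zeroth_order_params()
        R, socr = 1500e-6, 4e-17
        A = socr * p.rho_c

        def conc(r, a):
            return (A / (6 * p.D)) * (r**2 - a**2) + (A * a**3 / (3 * p.D)) * (
                1 / r - 1 / a
            )

        a = brentq(lambda a: conc(R, a) - p.c0, 1e-9, R * 0.999)
        r_crit = brentq(lambda r: conc(r, a) - p.C_crit, a, R)
        phi_exact = 100 * (r_crit / R) ** 3
        prof = solve_profile(R, socr, p)
        assert nonviable_fraction(prof, p.C_crit) == pytest.approx(phi_exact, rel=1e-2)

    def test_phi_monotone_in_radius(self, stem_params, stem_table):
        radii = np.linspace(100e-6, 4000e-6, 30)
        socrs = np.full_like(radii, stem_params.socr_mean)
        _, phi = stem_table.evaluate(radii, socrs)
        assert np.all(np.diff(phi) >= 0)

    def test_B_strictly_increasing_in_radius(self, stem_params, stem_table):
        radii = np.linspace(100e-6, 4000e-6, 30)
        socrs = np.full_like(radii, stem_params.socr_mean)
        B, _ = stem_table.evaluate(radii, socrs)
        assert np.all(np.diff(B) > 0)


class TestAsymptoticScaling:
    def test_small_thiele_cubic_large_thiele_quadratic(self):
        """B ~ R^3 in the reaction-limited limit; B ~ R^2 under strong
        diffusion limitation with near-zeroth-order kinetics."""
        p = zeroth_order_params()

        def B_of(R, socr):
            prof = solve_profile(R, socr, p)
            return metabolic_rate(prof, p, socr)

        # small-phi pair
        B1, B2 = B_of(20e-6, 4e-17), B_of(40e-6, 4e-17)
        slope_small = math.log(B2 / B1) / math.log(2.0)
        assert slope_small == pytest.approx(3.0, abs=0.05)
        # large-phi pair (Phi_T ~ 4e3 and 1.6e4); the surface-limited
        # asymptote is approached slowly (consumption-shell thickness
        # falls only as 1/sqrt(reaction rate))
        B3, B4 = B_of(2500e-6, 4e-16), B_of(5000e-6, 4e-16)
        slope_large = math.log(B4 / B3) / math.log(2.0)
        assert slope_large == pytest.approx(2.0, abs=0.1)


class TestMeshConvergence:
    def test_refined_solve_changes_B_by_less_than_5e4(self, stem_params):
        socr = stem_params.socr_mean
        for R in [500e-6, 1200e-6]:
            prof_a = solve_profile(R, socr, stem_params, n_init=101)
            prof_b = solve_profile(R, socr, stem_params, n_init=201, tol=1e-8)
            Ba = metabolic_rate(prof_a, stem_params, socr)
            Bb = metabolic_rate(prof_b, stem_params, socr)
            assert Ba == pytest.approx(Bb, rel=5e-4)


class TestSolvePopulation:
    def _small_pop(self, params, n=50, seed=13, mean_radius=600e-6):
        spec = SizeDistributionSpec(
            index=9, mean_radius=mean_radius, q2=0.01, n_samples=n, seed=seed
        )
        return build_population(spec, params)

    def test_single_spheroid_population(self, stem_params, stem_table):
        pop = self._small_pop(stem_params, n=1)
        sol = solve_population(pop, stem_params, fast=True, table=stem_table)
        assert len(sol) == 1
        assert sol[0].B > 0

    def test_lookup_agrees_with_direct_solves(self, stem_params, stem_table):
        """Table-accelerated B within 0.5% of per-spheroid BVP solves."""
        pop = self._small_pop(stem_params, n=40, mean_radius=900e-6)
        fast = solve_population(pop, stem_params, fast=True, table=stem_table)
        direct = solve_population(pop, stem_params, fast=False)
        assert direct.n_failures == 0
        rel = np.abs(fast.B / direct.B - 1)
        assert rel.max() < 5e-3
        assert np.abs(fast.phi - direct.phi).max() < 0.5  # percentage points

    def test_internal_audit_passes(self, stem_params, stem_table):
        pop = self._small_pop(stem_params, n=30)
        sol = solve_population(
            pop, stem_params, fast=True, table=stem_table, audit_n=5
        )
        assert len(sol) == 30

    def test_large_spheroids_mostly_nonviable(self, stem_params, stem_table):
        """At the top of the size ladder the nonviable core dominates."""
        pop = self._small_pop(stem_params, n=200, mean_radius=5000e-6, seed=3)
        sol = solve_population(pop, stem_params, fast=True, table=stem_table)
        assert np.mean(sol.phi > 10.0) > 0.5
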