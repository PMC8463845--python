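"""Joint collapse: g properties, (gamma, delta) recovery, HZ and MANOVA."""

import numpy as np
import pytest

from spheroscale.collapse_joint import (
    g,
    hz_test,
    meanvec_test,
    optimize_gamma_delta,
    rescale_joint,
)
from spheroscale.collapse_marginal import DegenerateSampleError, optimize_delta

from conftest import LADDER_MASS_TRIPLET, make_scaling_groups


def joint_groups(delta0=0.8, n=3000, seed=0, gamma0=1.0, **kw):
    return make_scaling_groups(delta0, n, LADDER_MASS_TRIPLET, seed, gamma0=gamma0, **kw)


class TestRescaleJoint:
    def test_unit_exponents_leave_axes_raw(self):
        rng = np.random.default_rng(0)
        m = rng.lognormal(-20, 0.1, 2000)
        B = m * rng.normal(1, 0.1, 2000).clip(1e-3)
        jd = rescale_joint(m, B, mean_mass=1.0, gamma=0.0, delta=0.0)
        assert jd.x_bin_centers.min() >= m.min() * 0.99
        assert jd.x_bin_centers.max() <= m.max() * 1.01
        assert jd.n_samples == 2000
        assert jd.log_points.shape[1] == 3

    def test_cell_mass_sums_to_one(self):
        rng = np.random.default_rng(1)
        m = rng.lognormal(-20, 0.1, 5000)
        B = m * rng.normal(1, 0.1, 5000).clip(1e-3)
        x_edges = np.geomspace(m.min(), m.max() * (1 + 1e-12), 31)
        y_edges = np.geomspace(B.min(), B.max() * (1 + 1e-12), 31)
        jd = rescale_joint(
            m, B, mean_mass=2e-9, gamma=0.0, delta=0.0,
            x_edges=x_edges, y_edges=y_edges,
        )
        assert jd.density.shape == (30, 30)
        cell_mass = jd.density * np.outer(np.diff(x_edges), np.diff(y_edges))
        assert cell_mass.sum() == pytest.approx(1.0, abs=0.01)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DegenerateSampleError):
            rescale_joint(np.ones(100), np.ones(100), mean_mass=1.0)


class TestGFunctional:
    def test_identical_members_give_zero(self):
        rng = np.random.default_rng(2)
        m = rng.lognormal(-20, 0.1, 2000)
        B = m * rng.normal(1, 0.2, 2000).clip(1e-3)
        groups = [(m, B, 1e-9), (m.copy(), B.copy(), 1e-9)]
        for ga, de in [(1.0, 1.0), (0.9, 0.7)]:
            assert g(ga, de, groups) == pytest.approx(0.0, abs=1e-12)

    def test_order_invariance(self):
        groups = joint_groups(n=1000, seed=3)
        assert g(1.0, 0.8, groups) == pytest.approx(
            g(1.0, 0.8, groups[::-1]), rel=1e-9
        )

    def test_invariant_under_common_mass_rescaling(self):
        """Scaling all masses (samples and conditioning means) by a
        constant translates every cloud rigidly in log space."""
        groups = joint_groups(n=1000, seed=4)
        scaled = [(m * 10.0, B, M * 10.0) for m, B, M in groups]
        # gamma = 1 makes the translation identical for all members
        assert g(1.0, 0.8, scaled) == pytest.approx(g(1.0, 0.8, groups), rel=1e-6)

    def test_true_exponents_beat_wrong_ones(self):
        groups = joint_groups(delta0=0.8, n=10_000, seed=5)
        assert g(1.0, 0.8, groups) < g(1.0, 0.6, groups)
        assert g(1.0, 0.8, groups) < g(0.85, 0.8, groups)


@pytest.fixture(scope="module")
def recovered():
    groups = joint_groups(delta0=0.8, n=10_000, seed=6)
    return optimize_gamma_delta(groups, run_tests=False)


class TestOptimizeGammaDelta:
    def test_recovers_gamma_and_delta(self, recovered):
        assert recovered.gamma_hat == pytest.approx(1.0, abs=0.02)
        assert recovered.delta_hat == pytest.approx(0.8, abs=0.05)

    def test_intervals_contain_estimates(self, recovered):
        assert (
            recovered.gamma_interval[0]
            <= recovered.gamma_hat
            <= recovered.gamma_interval[1]
        )
        assert (
            recovered.delta_interval[0]
            <= recovered.delta_hat
            <= recovered.delta_interval[1]
        )
        assert recovered.g_min >= 0

    def test_zero_variability_reduces_to_exact_solve(self):
        Ms = list(LADDER_MASS_TRIPLET)
        groups = [
            (np.full(1, M), np.full(1, (M / Ms[0]) ** 0.85), M) for M in Ms
        ]
        res = optimize_gamma_delta(groups)
        assert res.exact
        assert res.gamma_hat == pytest.approx(1.0, abs=1e-9)
        assert res.delta_hat == pytest.approx(0.85, abs=1e-9)

    def test_marginalization_consistency(self):
        """delta from the joint collapse agrees with the marginal-only
        collapse of the same data within their joint uncertainty."""
        groups = joint_groups(delta0=0.8, n=10_000, seed=8)
        rj = optimize_gamma_delta(groups, run_tests=False)
        rm = optimize_delta([(B, M) for m, B, M in groups], run_ad_test=False)
        tol = (rj.delta_interval[1] - rj.delta_interval[0]) / 2 + max(
            (rm.delta_interval[1] - rm.delta_interval[0]) / 2, 0.01
        )
        assert abs(rj.delta_hat - rm.delta_hat) <= max(tol, 0.03)


class TestHenzeZirkler:
    def test_size_calibration_at_1_percent(self):
        """Bivariate normal null: rejection rate near the nominal 1%."""
        rng = np.random.default_rng(31)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(0, 1, 100)
            y = 0.5 * x + rng.normal(0, 1, 100)
            if hz_test(x, y) <= 0.01:
                rejections += 1
        rate = rejections / n_rep
        assert 0.0025 <= rate <= 0.025

    def test_contaminated_data_rejected(self):
        rng = np.random.default_rng(37)
        x = rng.normal(0, 1, 500)
        y = rng.normal(0, 1, 500)
        x[:50] *= 5.0
        y[:50] *= 5.0
        assert hz_test(x, y) < 0.01

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            hz_test(np.arange(10.0), np.arange(10.0) ** 2)


class TestMeanVectorEquality:
    @staticmethod
    def _null_groups(rng, shift=0.0):
        out = []
        for k in range(3):
            x = rng.normal(0, 1, 120)
            y = rng.normal(0, 1, 120)
            if k == 2:
                x = x + shift
            out.append((x, y))
        return out

    def test_size_calibration(self):
        rng = np.random.default_rng(41)
        n_rep = 400
        rej = sum(
            meanvec_test(self._null_groups(rng)) <= 0.05 for _ in range(n_rep)
        )
        assert 0.025 <= rej / n_rep <= 0.08

    def test_power_against_one_sd_shift(self):
        rng = np.random.default_rng(43)
        p = meanvec_test(self._null_groups(rng, shift=1.0))
        assert p < 1e-6

    def test_anova_variant_agrees_qualitatively(self):
        rng = np.random.default_rng(47)
        null_p = meanvec_test(self._null_groups(rng), method="anova")
        shift_p = meanvec_test(self._null_groups(rng, shift=1.0), method="anova")
        assert shift_p < 0.01 < null_p


def test_joint_dependence_not_product_of_marginals(stem_params, stem_table):
    """On solved populations, log m and log B are strongly correlated
    within a window (B depends on R and sOCR), so the joint density
    cannot factorize into its marginals."""
    from spheroscale import SizeDistributionSpec, build_population, solve_population

    spec = SizeDistributionSpec(index=9, mean_radius=394e-6, q2=0.01, n_samples=2000, seed=3)
    pop = build_population(spec, stem_params)
    sol = solve_population(pop, stem_params, fast=True, table=stem_table)
    r = np.corrcoef(np.log(pop.masses), np.log(sol.B))[0, 1]
    assert r > 0.5
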