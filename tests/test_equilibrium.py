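import numpy as np
import pytest
import scipy.linalg
from hypothesis import given
from hypothesis import strategies as st
from numpy.testing import assert_allclose
from scipy.optimize import brentq

from gmse import (
    MutationParams,
    SelectionParams,
    g_gaussian_drift,
    g_gaussian_infinite,
    g_hoc_drift,
    kappa,
    ne_from_kappa,
    params_from_cov,
    rho_g_hoc,
    shared_eigenvector_check,
    wishart_compare,
)

N_LOCI, MU = 20, 0.01

corr = st.floats(-0.95, 0.95)


def single_trait_fixed_point(vs, va, mu, ne, n):
    """Independent oracle: per-locus variance recursion at equilibrium.

    Solves 2*mu*va - v**2/vs - v/(2*ne) = 0 for the per-locus genetic
    variance and sums over loci.
    """
    v = brentq(lambda v: 2 * mu * va - v**2 / vs - v / (2 * ne), 0.0, 100.0, xtol=1e-15)
    return n * v


class TestRhoGHoc:
    def test_uncorrelated_inputs_give_zero(self):
        for phi in (0.1, 1.0, 7.3):
            assert rho_g_hoc(0.0, 0.0, phi) == 0.0

    @given(rho=corr)
    def test_equal_correlations_collapse(self, rho):
        assert rho_g_hoc(rho, rho, 1.0) == pytest.approx(rho, abs=1e-12)

    @given(rm=corr, rs=corr, phi=st.floats(0.01, 100.0))
    def test_ratio_inversion_symmetry(self, rm, rs, phi):
        assert rho_g_hoc(rm, rs, phi) == pytest.approx(rho_g_hoc(rm, rs, 1 / phi), rel=1e-12)

    def test_matches_matrix_equilibrium(self, base_M, base_V):
        pred = g_gaussian_infinite(base_M, base_V, n=N_LOCI, mu=MU)
        p = params_from_cov(base_M, base_V)
        assert rho_g_hoc(p.rho_m, p.rho_s, p.phi) == pytest.approx(pred.rho_g, abs=1e-10)

    @given(rm=corr, rs=corr)
    def test_phi_one_closed_form(self, rm, rs):
        cm, cs = np.sqrt(1 - rm**2), np.sqrt(1 - rs**2)
        assert rho_g_hoc(rm, rs, 1.0) == pytest.approx((rs * cm + rm * cs) / (cm + cs))

    @pytest.mark.parametrize("bad", [dict(rho_m=1.0), dict(rho_s=-1.2), dict(phi=0.0)])
    def test_domain_errors(self, bad):
        kwargs = dict(rho_m=0.1, rho_s=0.2, phi=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            rho_g_hoc(**kwargs)


class TestGaussianInfinite:
    def test_isotropic_inputs(self):
        pred = g_gaussian_infinite(0.01 * np.eye(2), 5.0 * np.eye(2), n=N_LOCI, mu=MU)
        assert pred.rho_g == pytest.approx(0.0, abs=1e-14)
        assert pred.G[0, 0] == pytest.approx(pred.G[1, 1])

    @given(rho=corr)
    def test_same_shape_inputs_inherit_correlation(self, rho):
        M = MutationParams(0.0025, rho, 1.0).matrix()
        V = SelectionParams(5.0, rho, 1.0).matrix()
        pred = g_gaussian_infinite(M, V, n=N_LOCI, mu=MU)
        assert pred.rho_g == pytest.approx(rho, abs=1e-12)

    def test_single_trait_scalar_value(self):
        vs, va = 20.0, 0.0025
        pred = g_gaussian_infinite([[va]], [[vs]], n=N_LOCI, mu=MU)
        assert pred.G[0, 0] == pytest.approx(N_LOCI * np.sqrt(2 * MU * va * vs), rel=1e-14)

    @pytest.mark.parametrize("c", [0.01, 0.5, 40.0])
    def test_selection_scale_only_resizes(self, c, base_M, base_V):
        """Rescaling Vs (or Va) alone changes G's size, never its shape."""
        ref = g_gaussian_infinite(base_M, base_V, n=N_LOCI, mu=MU)
        scaled = g_gaussian_infinite(base_M, c * base_V, n=N_LOCI, mu=MU)
        assert scaled.rho_g == pytest.approx(ref.rho_g, abs=1e-12)
        assert scaled.shape_summary().angle == pytest.approx(ref.shape_summary().angle)
        assert_allclose(scaled.G, np.sqrt(c) * ref.G, rtol=1e-10)

    def test_against_general_purpose_matrix_sqrt(self, base_M, base_V):
        """Cross-check the eigendecomposition square roots against scipy.sqrtm."""
        Vh = scipy.linalg.sqrtm(base_V)
        inner = scipy.linalg.sqrtm(np.linalg.inv(Vh) @ base_M @ np.linalg.inv(Vh))
        expected = N_LOCI * np.sqrt(2 * MU) * (Vh @ inner @ Vh)
        pred = g_gaussian_infinite(base_M, base_V, n=N_LOCI, mu=MU)
        assert_allclose(pred.G, np.real(expected), rtol=1e-10)

    def test_dimension_mismatch_rejected(self, base_M):
        with pytest.raises(ValueError):
            g_gaussian_infinite(base_M, np.eye(3), n=N_LOCI, mu=MU)


class TestGaussianDrift:
    def test_large_population_limit(self, base_M, base_V):
        """Deviation from the infinite-N balance is first order in kappa."""
        inf = g_gaussian_infinite(base_M, base_V, n=N_LOCI, mu=MU)
        ne = ne_from_kappa(1e-12, Vs=base_V[0, 0], mu=MU, Va=base_M[0, 0])
        near = g_gaussian_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=ne)
        assert_allclose(near.G, inf.G, rtol=1e-9)

    def test_drift_dominated_limit(self, base_M, base_V):
        ne = ne_from_kappa(1e6, Vs=base_V[0, 0], mu=MU, Va=base_M[0, 0])
        pred = g_gaussian_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=ne)
        assert pred.rho_g == pytest.approx(-0.7, abs=1e-4)
        assert_allclose(pred.G, 4 * ne * N_LOCI * MU * base_M, rtol=1e-3)

    @pytest.mark.parametrize("vs, ne", [(5.0, 150.0), (100.0, 600.0), (20.0, 37.0)])
    def test_single_trait_matches_recursion_fixed_point(self, vs, ne):
        va = 0.0025
        pred = g_gaussian_drift([[va]], [[vs]], n=N_LOCI, mu=MU, Ne=ne)
        expected = single_trait_fixed_point(vs, va, MU, ne, N_LOCI)
        assert pred.G[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_sign_symmetry(self, base_M, base_V):
        """Negating trait 2 negates the genetic correlation."""
        F = np.diag([1.0, -1.0])
        pred = g_gaussian_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=300.0)
        flipped = g_gaussian_drift(F @ base_M @ F, F @ base_V @ F, n=N_LOCI, mu=MU, Ne=300.0)
        assert flipped.rho_g == pytest.approx(-pred.rho_g, rel=1e-12)

    def test_interpolates_monotonically_between_limits(self, base_M, base_V):
        p = params_from_cov(base_M, base_V)
        lo = g_gaussian_infinite(base_M, base_V, n=N_LOCI, mu=MU).rho_g
        kappas = np.logspace(-3, 3, 25)
        rhos = []
        for kap in kappas:
            ne = ne_from_kappa(kap, Vs=p.v_s, mu=MU, Va=p.v_alpha)
            rhos.append(g_gaussian_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=ne).rho_g)
        assert np.all(np.diff(rhos) < 0)  # from the balance value down toward rho_m
        assert max(rhos) < lo
        assert min(rhos) > p.rho_m

    def test_kappa_attribute_recorded(self, base_M, base_V):
        pred = g_gaussian_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=150.0)
        assert pred.kappa == pytest.approx(np.sqrt(5.0 / 18.0))


class TestKappa:
    def test_value(self):
        assert kappa(5.0, 150.0, 0.01, 0.0025) == pytest.approx(np.sqrt(5.0 / 18.0))

    def test_monotonicities(self):
        base = kappa(5.0, 150.0, 0.01, 0.0025)
        assert kappa(10.0, 150.0, 0.01, 0.0025) > base
        assert kappa(5.0, 300.0, 0.01, 0.0025) == pytest.approx(base / 2)
        assert kappa(5.0, 150.0, 0.02, 0.0025) < base
        assert kappa(5.0, 150.0, 0.01, 0.005) < base

    def test_small_when_selection_dominates(self):
        ne, mu, va = 5000.0, 0.01, 0.0025
        vs = 1e-3 * (4 * ne) ** 2 * 2 * mu * va
        assert kappa(vs, ne, mu, va) < 0.1

    def test_ne_round_trip(self):
        kap = kappa(5.0, 150.0, 0.01, 0.0025)
        assert ne_from_kappa(kap, 5.0, 0.01, 0.0025) == pytest.approx(150.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kappa(0.0, 150.0, 0.01, 0.0025)

    def test_halfway_transition_is_deterministic(self, base_M, base_V):
        """Bisection for the kappa at which rho_G sits midway between limits."""

        def halfway_kappa():
            p = params_from_cov(base_M, base_V)
            hi = g_gaussian_infinite(base_M, base_V, n=N_LOCI, mu=MU).rho_g
            target = 0.5 * (hi + p.rho_m)

            def gap(log_kap):
                ne = ne_from_kappa(10**log_kap, p.v_s, MU, p.v_alpha)
                return g_gaussian_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=ne).rho_g - target

            return brentq(gap, -4, 4, xtol=1e-12)

        assert halfway_kappa() == halfway_kappa()


class TestHocDrift:
    def test_selection_dominated_limit_matches_closed_form(self, base_M, base_V):
        p = params_from_cov(base_M, base_V)
        ne = p.v_s / (1e-6 * p.v_alpha)
        pred = g_hoc_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=ne, n_draws=50_000, seed=21)
        assert pred.rho_g == pytest.approx(rho_g_hoc(p.rho_m, p.rho_s, p.phi), abs=0.01)

    def test_drift_dominated_limit_is_neutral(self, base_M, base_V):
        p = params_from_cov(base_M, base_V)
        ne = p.v_s / (1e6 * p.v_alpha)
        pred = g_hoc_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=ne, n_draws=50_000, seed=22)
        assert pred.rho_g == pytest.approx(p.rho_m, abs=0.01)
        assert_allclose(pred.G, 4 * ne * N_LOCI * MU * base_M, rtol=0.02)

    def test_isotropic_inputs_give_zero_correlation(self):
        pred = g_hoc_drift(np.eye(2), 5 * np.eye(2), n=N_LOCI, mu=MU, Ne=100.0,
                           n_draws=20_000, seed=23)
        assert abs(pred.rho_g) <= 3 * pred.mc_se

    def test_monte_carlo_consistency_across_draw_counts(self, base_M, base_V):
        a = g_hoc_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=150.0, n_draws=10_000, seed=24)
        b = g_hoc_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=150.0, n_draws=40_000, seed=25)
        assert abs(a.rho_g - b.rho_g) <= 3 * np.hypot(a.mc_se, b.mc_se)

    def test_deterministic_for_fixed_seed(self, base_M, base_V):
        a = g_hoc_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=150.0, seed=26)
        b = g_hoc_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=150.0, seed=26)
        assert np.array_equal(a.G, b.G)

    def test_too_few_draws_rejected(self, base_M, base_V):
        with pytest.raises(ValueError, match="draws"):
            g_hoc_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=150.0, n_draws=10, seed=0)

    def test_seed_required(self, base_M, base_V):
        with pytest.raises(ValueError, match="seed"):
            g_hoc_drift(base_M, base_V, n=N_LOCI, mu=MU, Ne=150.0)


class TestWishartCompare:
    def test_regimes_agree_on_random_pairs(self):
        table = wishart_compare(50, seed=11)
        assert len(table) == 50
        assert table["abs_diff"].max() <= 1e-8

    def test_equal_matrices_inherit_input_correlation(self):
        M = V = SelectionParams(3.0, 0.4, 1.5).matrix()
        pred = g_gaussian_infinite(M, V, n=1, mu=0.5)
        p = params_from_cov(M, V)
        assert pred.rho_g == pytest.approx(0.4, abs=1e-12)
        assert rho_g_hoc(p.rho_m, p.rho_s, p.phi) == pytest.approx(0.4, abs=1e-12)

    def test_fixed_seed_is_bit_identical(self):
        a = wishart_compare(20, seed=5)
        b = wishart_compare(20, seed=5)
        assert a.equals(b)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            wishart_compare(5, df=2, seed=0)


class TestSharedEigenvectors:
    def test_commuting_inputs_never_rotate(self):
        M = MutationParams(0.0025, -0.5, 1.0).matrix()
        V = SelectionParams(6.0, 0.8, 1.0).matrix()
        nes = [ne_from_kappa(k, 6.0, MU, 0.0025) for k in np.logspace(-3, 3, 13)]
        assert shared_eigenvector_check(M, V, nes, n=N_LOCI, mu=MU) <= 1e-8

    def test_identical_matrices_trivially_shared(self, base_V):
        assert shared_eigenvector_check(base_V, base_V, [100.0, 1e6]) <= 1e-8

    def test_non_commuting_rejected(self, base_M, base_V):
        with pytest.raises(ValueError, match="commute"):
            shared_eigenvector_check(base_M, base_V, [100.0])
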