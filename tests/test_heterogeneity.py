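"""Score algebra, kernel spectra, Davies tail probabilities, permutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.linalg import eigvalsh
from scipy.stats import chi2

from deephtl import (
    CrossFitNuisances,
    SimulationConfig,
    compute_scores,
    davies_pvalue,
    estimate_tau0,
    estimate_tau_star_global,
    kernel_score_test,
    observed_loss,
    permutation_test,
    projection_matrix,
    rbf_kernel_matrix,
    simulate_dataset,
)
from deephtl.nuisance import make_folds


def scores_from(ds, e, mu_star, tau0):
    tau_star = estimate_tau_star_global(ds.Y, ds.Z, mu_star, e, tau0)
    return compute_scores(ds.Y, ds.Z, e, mu_star, tau0, tau_star)


@pytest.fixture(scope="module")
def null_scores():
    ds = simulate_dataset(SimulationConfig(n=5000, p=5,
                                           tau_scenario="zero", seed=61))
    mu_star = ds.tau_true * ds.e_true + ds.f_true
    u, s, w, sig2 = scores_from(ds, ds.e_true, mu_star, tau0=0.0)
    return ds, u, s, w, sig2


class TestScores:
    def test_raw_scores_sum_to_zero(self, null_scores):
        _, u, _, _, _ = null_scores
        assert abs(u.sum()) < 1e-8 * np.abs(u).sum()

    def test_constraint_direction_annihilated(self, null_scores):
        _, _, s, w, _ = null_scores
        assert abs(np.sqrt(w) @ s) < 1e-8 * len(s)

    def test_studentized_scores_unit_variance_under_null(self, null_scores):
        ds, _, s, _, sig2 = null_scores
        # true noise variance is 1; scores built from exact nuisances
        assert sig2 == pytest.approx(1.0, rel=0.1)
        assert np.var(s) == pytest.approx(1.0, rel=0.1)

    def test_zero_weight_rejected(self):
        Y = np.zeros(4)
        Z = np.array([1, 0, 1, 0], float)
        e = np.array([0.5, 0.5, 1.0, 0.5])  # w3 = 0
        with pytest.raises(ValueError):
            compute_scores(Y, Z, e, np.zeros(4), 0.0, 0.0)


class TestProjection:
    @given(arrays(float, st.integers(2, 30),
                  elements=st.floats(0.05, 10)))
    @settings(max_examples=30, deadline=None)
    def test_projector_properties(self, a):
        P = projection_matrix(a)
        n = len(a)
        np.testing.assert_allclose(P, P.T, atol=1e-10)
        np.testing.assert_allclose(P @ P, P, atol=1e-10)
        assert np.linalg.norm(P @ a) < 1e-8 * np.linalg.norm(a)
        assert np.trace(P) == pytest.approx(n - 1, abs=1e-8)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            projection_matrix(np.zeros(5))


class TestRbfKernel:
    def test_unit_diagonal_and_identical_rows(self, rng):
        X = rng.standard_normal((20, 4))
        X[5] = X[3]
        K = rbf_kernel_matrix(X, bandwidth=1.0)
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert K[3, 5] == pytest.approx(1.0)

    def test_positive_semidefinite_on_random_input(self, rng):
        X = rng.standard_normal((50, 5))
        K = rbf_kernel_matrix(X)
        lam = eigvalsh(K)
        assert lam.min() >= -1e-8 * lam.max()

    def test_nonfinite_rows_rejected(self):
        X = np.ones((5, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValueError):
            rbf_kernel_matrix(X)

    def test_bad_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError):
            rbf_kernel_matrix(rng.standard_normal((5, 2)), bandwidth=-1.0)


class TestDavies:
    def test_single_weight_matches_chi2_closed_form(self):
        assert davies_pvalue(3.8415, [1.0]) == pytest.approx(
            chi2.sf(3.8415, 1), abs=1e-4)

    def test_two_equal_weights_match_chi2_two_df(self):
        assert davies_pvalue(5.9915, [1.0, 1.0]) == pytest.approx(
            chi2.sf(5.9915, 2), abs=1e-4)

    def test_zero_statistic_gives_one(self):
        assert davies_pvalue(0.0, [0.3, 0.7]) == 1.0

    def test_matches_monte_carlo_mixture(self, rng):
        for _ in range(6):
            k = int(rng.integers(1, 6))
            lam = rng.uniform(0.05, 3.0, size=k)
            draws = (lam * rng.chisquare(1, size=(400_000, k))).sum(axis=1)
            q = float(np.quantile(draws, 0.95))
            p_mc = float((draws >= q).mean())
            assert davies_pvalue(q, lam) == pytest.approx(p_mc, abs=0.005)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            davies_pvalue(1.0, [1.0, -0.5])
        with pytest.raises(ValueError):
            davies_pvalue(1.0, [])


def exact_null_nuisances(ds, n_folds=3):
    mu = ds.tau_true * ds.e_true + ds.f_true
    nuis = CrossFitNuisances(
        fold_of=make_folds(ds.n, n_folds, seed=17, stratify=ds.Z),
        e_hat=ds.e_true,
        mu_hat=mu,
    )
    nuis.mu_star_hat = mu - np.mean(ds.tau_true) * ds.e_true
    return nuis


@pytest.fixture(scope="module")
def null_result():
    ds = simulate_dataset(SimulationConfig(n=300, p=5,
                                           tau_scenario="zero", seed=71))
    nuis = exact_null_nuisances(ds)
    return ds, nuis, kernel_score_test(ds, nuis, variant="revised")


class TestKernelScoreTest:
    def test_statistic_equals_projected_quadratic_form(self, null_result):
        ds, nuis, res = null_result
        P = projection_matrix(np.sqrt(res.w))
        K = rbf_kernel_matrix(ds.X, res.bandwidth)
        s_tilde = P @ res.s
        q_alt = float(s_tilde @ K @ s_tilde)
        assert res.Q == pytest.approx(q_alt, rel=1e-8)

    def test_eigenvalues_nonnegative_and_keff_consistent(self, null_result):
        _, _, res = null_result
        assert (res.lambdas > 0).all()
        k_eff = res.lambdas.sum() ** 2 / (res.lambdas**2).sum()
        assert res.k_eff == pytest.approx(k_eff)
        assert 0 <= res.p_value <= 1
        assert res.Q >= 0

    def test_unrevised_variant_runs_from_mu_only(self, null_result):
        ds, nuis, _ = null_result
        res = kernel_score_test(ds, nuis, variant="unrevised")
        assert 0 <= res.p_value <= 1
        # unrevised scores also satisfy the sum-to-zero constraint
        assert abs(res.u.sum()) < 1e-8 * np.abs(res.u).sum()

    def test_detects_overt_heterogeneity(self):
        ds = simulate_dataset(SimulationConfig(n=500, p=5,
                                               tau_scenario="simple_hte",
                                               seed=72))
        nuis = exact_null_nuisances(ds)
        res = kernel_score_test(ds, nuis, variant="revised")
        assert res.p_value < 1e-4


class TestObservedLoss:
    def test_hand_computation_four_rows(self):
        ds = simulate_dataset(SimulationConfig(n=4, p=5,
                                               tau_scenario="zero", seed=73))
        nuis = CrossFitNuisances(
            fold_of=np.array([0, 0, 1, 1]),
            e_hat=np.full(4, 0.5),
            mu_hat=np.zeros(4),
        )
        tau_pred = np.array([1.0, -1.0, 0.5, 0.0])
        d = ds.Z - 0.5
        expected = float(np.mean((ds.Y - tau_pred * d) ** 2))
        got = observed_loss(ds, nuis, tau_pred, variant="unrevised")
        assert got == pytest.approx(expected)

    def test_exact_solution_gives_zero_loss(self):
        ds = simulate_dataset(SimulationConfig(n=6, p=5,
                                               tau_scenario="zero", seed=74))
        nuis = CrossFitNuisances(
            fold_of=np.zeros(6, int),
            e_hat=np.full(6, 0.25),
            mu_hat=np.zeros(6),
        )
        tau_pred = ds.Y / (ds.Z - 0.25)
        assert observed_loss(ds, nuis, tau_pred, "unrevised") == pytest.approx(0.0)

    def test_revised_requires_tau0_and_mu_star(self, small_null_dataset,
                                               small_null_nuisances):
        with pytest.raises(ValueError, match="tau0"):
            observed_loss(small_null_dataset, small_null_nuisances,
                          np.zeros(small_null_dataset.n), variant="revised")


@pytest.fixture(scope="module")
def null_setup():
    ds = simulate_dataset(SimulationConfig(n=400, p=5,
                                           tau_scenario="zero", seed=75))
    return ds, exact_null_nuisances(ds)


class TestPermutationTest:
    def test_constant_predictions_give_p_one(self, null_setup):
        ds, nuis = null_setup
        res = permutation_test(ds, nuis, np.full(ds.n, 1.3), B=99, seed=1,
                               variant="unrevised")
        assert res.p_value == 1.0
        np.testing.assert_allclose(res.L_perm, res.L_obs, rtol=1e-12)

    def test_same_seed_reproducible_p_in_unit_interval(self, null_setup, rng):
        ds, nuis = null_setup
        tau_pred = rng.standard_normal(ds.n)
        r1 = permutation_test(ds, nuis, tau_pred, B=99, seed=5, variant="unrevised")
        r2 = permutation_test(ds, nuis, tau_pred, B=99, seed=5, variant="unrevised")
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1

    def test_detects_overt_heterogeneity_with_oracle_predictions(self):
        ds = simulate_dataset(SimulationConfig(n=1000, p=5,
                                               tau_scenario="simple_hte",
                                               seed=76))
        nuis = exact_null_nuisances(ds)
        tau0 = float(np.mean(ds.tau_true))
        res = permutation_test(ds, nuis, ds.tau_true, B=999, seed=2,
                               variant="revised", tau0=tau0)
        assert res.p_value <= 0.01

    def test_zero_permutations_warns_and_returns_one(self, null_setup):
        ds, nuis = null_setup
        with pytest.warns(RuntimeWarning):
            res = permutation_test(ds, nuis, np.zeros(ds.n), B=0, seed=0,
                                   variant="unrevised")
        assert res.p_value == 1.0

    def test_uninformative_predictions_give_uniform_p(self, null_setup, rng):
        """Exchangeability: shuffled predictions yield ~uniform p-values."""
        ds, nuis = null_setup
        base = rng.standard_normal(ds.n)
        ps = []
        for b in range(60):
            shuffled = rng.permutation(base)
            res = permutation_test(ds, nuis, shuffled, B=39, seed=100 + b,
                                   variant="unrevised")
            ps.append(res.p_value)
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01
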