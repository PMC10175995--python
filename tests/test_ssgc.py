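"""Pooled VAR estimation and state-space Granger causality."""

import numpy as np
import pytest

from gcherit.diagnostics import random_stable_var1, true_model_gc
from gcherit.ssgc import (
    GCMatrix,
    VARModel,
    aggregate_connectome,
    bivariate_gc_yule_walker,
    fit_var_pooled,
    gc_from_source,
    gc_matrix,
    gc_matrix_from_model,
    var_to_state_space,
)


def simulate_var(coefs, sigma_chol, T, rng, burn=300):
    p, N, _ = coefs.shape
    y = np.zeros((T + burn, N))
    eps = rng.standard_normal((T + burn, N)) @ sigma_chol.T
    for t in range(p, T + burn):
        y[t] = sum(coefs[k] @ y[t - k - 1] for k in range(p)) + eps[t]
    return y[burn:]


class TestPooledFit:
    def test_single_session_matches_statsmodels(self):
        """Pooling over one segment equals the standard least-squares VAR."""
        from statsmodels.tsa.api import VAR

        rng = np.random.default_rng(0)
        A = np.array([[[0.5, 0.1], [0.2, 0.4]]])
        y = simulate_var(A, np.eye(2), 2000, rng)
        y = y - y.mean(axis=0)
        ours = fit_var_pooled([y], order=1)
        ref = VAR(y).fit(1, trend="n")
        np.testing.assert_allclose(ours.coefs[0], ref.coefs[0], atol=1e-8)
        np.testing.assert_allclose(ours.sigma, ref.sigma_u, atol=1e-8)

    def test_recovers_coefficients_from_four_sessions(self):
        rng = np.random.default_rng(1)
        A = np.array([[[0.5, 0.0], [0.4, 0.5]]])
        sessions = [simulate_var(A, np.eye(2), 1200, rng) for _ in range(4)]
        model = fit_var_pooled(sessions, order=1)
        np.testing.assert_allclose(model.coefs[0], A[0], atol=0.03)

    def test_no_row_spans_session_boundary(self):
        """Pooled fit of two short sessions != fit of their concatenation."""
        rng = np.random.default_rng(2)
        A = np.array([[[0.6]]])
        s1 = simulate_var(A, np.eye(1), 150, rng)
        s2 = simulate_var(A, np.eye(1), 150, rng)
        pooled = fit_var_pooled([s1, s2], order=1)
        concat = fit_var_pooled([np.vstack([s1, s2])], order=1)
        assert not np.allclose(pooled.coefs, concat.coefs)

    def test_bic_recovers_generating_order(self):
        """Order-3 data, selection over 1..8, >= 90% correct over 50 seeds."""
        hits = 0
        base = np.zeros((3, 2, 2))
        base[0] = [[0.4, 0.1], [0.0, 0.3]]
        base[2] = [[0.0, 0.0], [0.35, 0.0]]
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = simulate_var(base, np.eye(2), 1500, rng)
            model = fit_var_pooled([y], order="bic", p_max=8)
            hits += model.order == 3
        assert hits >= 45

    def test_insufficient_rows_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="insufficient"):
            fit_var_pooled([rng.standard_normal((30, 4))], order=2)

    def test_unstable_fit_warns_but_returns(self):
        rng = np.random.default_rng(4)
        t = np.arange(400.0)
        y = np.column_stack([1.02**t + 0.01 * rng.standard_normal(400),
                             rng.standard_normal(400)])
        with pytest.warns(RuntimeWarning):
            model = fit_var_pooled([y], order=1)
        assert not model.stable


class TestStateSpace:
    def test_var1_state_space_is_direct(self):
        A = np.array([[[0.5, 0.2], [0.1, 0.3]]])
        var = VARModel(order=1, coefs=A, sigma=np.eye(2), nobs=100)
        ss = var_to_state_space(var)
        np.testing.assert_array_equal(ss.A, A[0])
        np.testing.assert_array_equal(ss.C, A[0])
        np.testing.assert_array_equal(ss.V, np.eye(2))

    def test_innovations_covariance_equals_sigma(self):
        rng = np.random.default_rng(0)
        A, sigma = random_stable_var1(rng, 3)
        var = VARModel(order=1, coefs=A[None], sigma=sigma, nobs=100)
        np.testing.assert_array_equal(var_to_state_space(var).V, sigma)

    def test_var2_autocovariance_matches_simulation(self):
        """State-space autocovariance recursion vs a long simulated record."""
        coefs = np.zeros((2, 2, 2))
        coefs[0] = [[0.4, 0.1], [0.0, 0.3]]
        coefs[1] = [[0.0, 0.2], [0.25, 0.0]]
        var = VARModel(order=2, coefs=coefs, sigma=np.eye(2), nobs=100)
        ss = var_to_state_space(var)
        acov = ss.autocovariance(3)
        rng = np.random.default_rng(1)
        y = simulate_var(coefs, np.eye(2), 400_000, rng)
        for h in range(4):
            emp = (y[h:].T @ y[: len(y) - h]) / (len(y) - h)
            np.testing.assert_allclose(acov[h], emp, atol=0.03)

    def test_unstable_var_rejected(self):
        A = np.array([[[1.05]]])
        var = VARModel(order=1, coefs=A, sigma=np.eye(1), nobs=10)
        with pytest.raises(ValueError):
            var_to_state_space(var)


class TestGrangerCausality:
    def test_decoupled_system_has_zero_gc(self):
        var = VARModel(order=1, coefs=np.diag([0.5, 0.3, 0.7])[None],
                       sigma=np.eye(3), nobs=100)
        ss = var_to_state_space(var)
        for src in range(3):
            np.testing.assert_allclose(gc_from_source(ss, src), 0, atol=1e-10)

    def test_matches_reduced_ar_oracle(self):
        """Model-based F vs Yule-Walker on the exact reduced autocovariance."""
        A = np.array([[0.5, 0.0], [0.4, 0.5]])
        f_model = true_model_gc(A, np.eye(2), 0)[0]
        f_oracle = bivariate_gc_yule_walker(A, np.eye(2), 0, 1)
        assert abs(f_model - f_oracle) <= 1e-3
        assert f_model > 0.1

    def test_absent_edge_gives_zero(self):
        A = np.array([[0.5, 0.0], [0.4, 0.5]])
        assert abs(true_model_gc(A, np.eye(2), 1)[0]) <= 1e-10

    def test_oracle_agreement_over_random_systems(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            A, sigma = random_stable_var1(rng)
            for src in (0, 1):
                f_model = true_model_gc(A, sigma, src)[0]
                f_oracle = bivariate_gc_yule_walker(A, sigma, src, 1 - src)
                assert abs(f_model - f_oracle) <= 1e-3

    def test_chain_recovers_true_edges(self):
        """1 -> 2 -> 3 chain: the two true edges carry the largest F."""
        coefs = np.array([[[0.5, 0.0, 0.0],
                           [0.45, 0.5, 0.0],
                           [0.0, 0.45, 0.5]]])
        rng = np.random.default_rng(11)
        y = simulate_var(coefs, np.eye(3), 8000, rng)
        M = gc_matrix([y], order=1).values
        off = [(s, t) for s in range(3) for t in range(3) if s != t]
        ranked = sorted(off, key=lambda st: -M[st])
        assert set(ranked[:2]) == {(0, 1), (1, 2)}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        coefs = np.array([[[0.5, 0.0, 0.2],
                           [0.3, 0.4, 0.0],
                           [0.0, 0.2, 0.3]]])
        y = simulate_var(coefs, np.eye(3), 3000, rng)
        perm = [2, 0, 1]
        M1 = gc_matrix([y], order=1).values
        M2 = gc_matrix([y[:, perm]], order=1).values
        np.testing.assert_allclose(M1[np.ix_(perm, perm)], M2, atol=1e-8)

    def test_single_node_matrix_is_zero(self):
        rng = np.random.default_rng(13)
        M = gc_matrix([rng.standard_normal((300, 1))], order=1)
        assert M.values.shape == (1, 1) and M.values[0, 0] == 0

    def test_nonnegative_after_clipping(self):
        rng = np.random.default_rng(14)
        y = simulate_var(np.array([[[0.5, 0.1], [0.2, 0.4]]]), np.eye(2),
                         2000, rng)
        M = gc_matrix([y], order="aic", p_max=5)
        assert np.all(M.values >= 0)

    def test_bivariate_mode_positive_on_true_edge(self):
        A = np.array([[0.5, 0.0], [0.4, 0.5]])
        var = VARModel(order=1, coefs=A[None], sigma=np.eye(2), nobs=100)
        ss = var_to_state_space(var)
        M = gc_matrix_from_model(ss, mode="bivariate").values
        assert M[0, 1] > 0.05
        assert M[1, 0] <= 1e-8


class TestAggregation:
    def test_single_subject_median_is_identity(self):
        m = GCMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])
        med, _ = aggregate_connectome([m])
        np.testing.assert_array_equal(med.values, m.values)

    def test_median_of_three(self):
        mats = [GCMatrix(np.array([[0.0, v], [v + 1, 0.0]]), ["a", "b"])
                for v in (1.0, 2.0, 9.0)]
        med, _ = aggregate_connectome(mats)
        assert med.values[0, 1] == 2.0

    def test_upper_quartile_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        mats = [GCMatrix(np.abs(rng.standard_normal((5, 5))),
                         [f"n{i}" for i in range(5)]) for _ in range(7)]
        for m in mats:
            np.fill_diagonal(m.values, 0)
        med, report = aggregate_connectome(mats)
        stack = np.stack([m.values for m in mats])
        expect_med = np.median(stack, axis=0)
        off = [(s, t) for s in range(5) for t in range(5) if s != t]
        vals = [expect_med[st] for st in off]
        thr = np.percentile(vals, 75)
        expect = {(f"n{s}", f"n{t}") for (s, t) in off if expect_med[s, t] >= thr}
        got = set(zip(report["source"], report["target"]))
        assert got == expect
        assert list(report["median_gc"]) == sorted(report["median_gc"],
                                                   reverse=True)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            aggregate_connectome([])

    def test_csv_round_trip(self, tmp_path):
        m = GCMatrix(np.array([[0.0, 0.5], [0.25, 0.0]]), ["a", "b"])
        path = tmp_path / "gc.csv"
        m.to_csv(path)
        back = GCMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, m.values)
        assert back.labels == m.labels
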