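"""Variance-component heritability: preprocessing, likelihood, inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import ndtri

from gcherit.pedigree import build_household, build_kinship
from gcherit.simulate import SimConfig, simulate_ace_traits, simulate_pedigree
from gcherit.varcomp import (
    TraitTable,
    adjust_covariates,
    fdr_bh,
    fit_null,
    fit_variance_components,
    heritability_scan,
    inverse_normal_transform,
    loglik_components,
    lrt_heritability,
    replication_overlap,
)

from conftest import random_pedigree


def _traits(values, ids):
    cols = [("a", "b")] if np.ndim(values) == 1 else \
        [(f"s{j}", f"t{j}") for j in range(np.shape(values)[1])]
    vals = np.atleast_2d(np.asarray(values, float))
    if vals.shape[0] == 1 and len(ids) > 1:
        vals = vals.T
    return TraitTable(vals, cols, list(ids))


class TestCovariateAdjustment:
    def test_trait_linear_in_age_residualizes_to_zero(self):
        ids = [f"i{k}" for k in range(6)]
        age = np.array([20, 25, 30, 35, 28, 22.0])
        cov = pd.DataFrame(dict(id=ids, age=age, sex=[0, 1, 0, 1, 0, 1],
                                handedness=[1, 1, 0, 1, 0, 1],
                                education=[12, 13, 14, 15, 16, 17.0]))
        tt = _traits(3.0 * age - 7.0, ids)
        out = adjust_covariates(tt, cov)
        np.testing.assert_allclose(out.values, 0, atol=1e-9)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(0)
        ids = [f"i{k}" for k in range(40)]
        cov = pd.DataFrame(dict(id=ids, age=rng.uniform(22, 36, 40),
                                sex=rng.integers(0, 2, 40),
                                handedness=rng.integers(0, 2, 40),
                                education=rng.uniform(11, 17, 40)))
        tt = _traits(rng.standard_normal((40, 3)), ids)
        out = adjust_covariates(tt, cov)
        X = np.column_stack([np.ones(40), cov["age"], cov["sex"],
                             cov["handedness"], cov["education"]])
        assert np.max(np.abs(X.T @ out.values)) <= 1e-8

    def test_three_subject_projection_matches_hand_solution(self):
        """Residual against [1, age] computed from the normal equations."""
        ids = ["a", "b", "c"]
        age = np.array([20.0, 30.0, 40.0])
        y = np.array([1.0, 4.0, 5.0])
        X = np.column_stack([np.ones(3), age])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        expected = y - X @ beta
        # constant sex/handedness/education would be collinear; vary them
        # minimally but orthogonally to keep the hand solution valid
        cov = pd.DataFrame(dict(id=ids, age=age, sex=[0, 0, 0],
                                handedness=[1, 1, 1], education=[15, 15, 15]))
        with pytest.raises(ValueError):
            adjust_covariates(_traits(y, ids), cov)  # collinear -> error
        cov2 = pd.DataFrame(dict(id=ids + ["d", "e"],
                                 age=np.append(age, [25.0, 35.0]),
                                 sex=[0, 1, 0, 1, 0],
                                 handedness=[1, 0, 1, 1, 0],
                                 education=[15, 14, 16, 13, 17]))
        # full-rank case: residuals orthogonal to age column
        tt = _traits(np.append(y, [2.0, 3.0]), list(cov2["id"]))
        out = adjust_covariates(tt, cov2)
        assert abs(out.values[:, 0] @ cov2["age"].to_numpy()) <= 1e-8

    def test_collinear_design_names_columns(self):
        ids = ["a", "b", "c", "d"]
        cov = pd.DataFrame(dict(id=ids, age=[30] * 4, sex=[0, 1, 0, 1],
                                handedness=[1, 0, 1, 0],
                                education=[15] * 4))
        with pytest.raises(ValueError, match="age|education"):
            adjust_covariates(_traits([1.0, 2, 3, 4], ids), cov)


class TestInverseNormal:
    def test_median_maps_to_zero(self):
        out = inverse_normal_transform(np.array([3.0, 1.0, 2.0, 5.0, 4.0]))
        assert out[np.argsort([3.0, 1, 2, 5, 4])[2]] == pytest.approx(0.0)

    def test_blom_scores_for_n5(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        expected = ndtri((np.arange(1, 6) - 0.375) / 5.25)
        np.testing.assert_allclose(inverse_normal_transform(x), expected)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, seed):
        """Any strictly monotone input transformation leaves output unchanged."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(30)
        a = inverse_normal_transform(x)
        b = inverse_normal_transform(np.exp(2 * x) + 5)
        np.testing.assert_allclose(a, b)
        order = np.argsort(x)
        assert np.all(np.diff(a[order]) >= 0)

    def test_ties_get_mean_ranks(self):
        out = inverse_normal_transform(np.array([1.0, 2.0, 2.0, 3.0]))
        assert out[1] == out[2]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            inverse_normal_transform(np.array([1.0, 2.0]))


class TestLikelihood:
    @pytest.mark.parametrize("seed", range(6))
    def test_blockwise_equals_dense_oracle(self, seed):
        """Small random pedigrees: blockwise LL == dense MVN logpdf to 1e-8."""
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, max_families=4)
        if ped.n > 12 or ped.n < 2:
            ped = random_pedigree(np.random.default_rng(seed + 50), 3)
        kin = build_kinship(ped)
        house = build_household(ped)
        y = rng.standard_normal(ped.n)
        sg2, sc2, se2 = 0.4, 0.25, 0.5
        ours = loglik_components(y, kin, house, sg2, sc2, se2)
        omega = sg2 * kin.values + sc2 * house.values + se2 * np.eye(ped.n)
        dense = stats.multivariate_normal(np.zeros(ped.n), omega).logpdf(y)
        assert ours == pytest.approx(dense, abs=1e-8)

    def test_single_family_of_three_dense_equality(self):
        rows = [("a", "F1", "M", "SIB", None, "F1"),
                ("b", "F1", "F", "SIB", None, "F1"),
                ("c", "F1", "M", "SIB", None, "F1")]
        from gcherit.pedigree import Pedigree

        ped = Pedigree(pd.DataFrame(rows, columns=["id", "famid", "sex",
                                                   "group", "twinpair", "hhid"]))
        kin, house = build_kinship(ped), build_household(ped)
        y = np.array([0.3, -1.2, 0.7])
        ours = loglik_components(y, kin, house, 0.5, 0.1, 0.4)
        omega = 0.5 * kin.values + 0.1 * house.values + 0.4 * np.eye(3)
        dense = stats.multivariate_normal(np.zeros(3), omega).logpdf(y)
        assert ours == pytest.approx(dense, abs=1e-8)

    def test_fit_loglik_consistent_with_loglik_components(self, tiny_pedigree):
        rng = np.random.default_rng(3)
        kin = build_kinship(tiny_pedigree)
        house = build_household(tiny_pedigree)
        y = rng.standard_normal(tiny_pedigree.n)
        fit = fit_variance_components(y, kin, house, model="ACE")
        direct = loglik_components(y, kin, house, fit.sigma_g2, fit.sigma_c2,
                                   fit.sigma_e2)
        assert fit.loglik == pytest.approx(direct, abs=1e-6)


class TestVarianceComponentFit:
    def test_all_singletons_flagged_unidentifiable(self):
        from gcherit.pedigree import Pedigree

        rows = [(f"s{i}", f"F{i}", "F", "SINGLETON", None, f"F{i}")
                for i in range(20)]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "famid", "sex",
                                                   "group", "twinpair", "hhid"]))
        kin = build_kinship(ped)
        y = np.random.default_rng(0).standard_normal(20)
        fit = fit_variance_components(y, kin, model="AE")
        assert fit.flag == "unidentifiable"
        assert fit.sigma_g2 == 0.0

    def test_ae_recovery_on_twin_cohort(self):
        """100 MZ + 100 DZ pairs, true h2 = 0.4: mean estimate within 0.05."""
        cfg = SimConfig(n_mz_pairs=100, n_dz_pairs=100, sibling_set_sizes=(),
                        n_singletons=0, n_networks=15, h2=0.4, c2=0.0, seed=5)
        ped, _ = simulate_pedigree(cfg)
        traits = simulate_ace_traits(ped, cfg)
        kin = build_kinship(ped)
        h_hats = [fit_variance_components(traits.values[:, j], kin,
                                          model="AE").h2
                  for j in range(100)]
        assert np.mean(h_hats) == pytest.approx(0.4, abs=0.05)

    def test_ace_on_ae_data_keeps_c2_small(self):
        """ACE reduces to AE when the data carry no shared-environment
        variance. Tested on a twin-rich design (300 MZ + 300 DZ pairs);
        boundary truncation of sigma_c2 >= 0 inflates the mean estimate
        on smaller, less informative cohorts."""
        cfg = SimConfig(n_mz_pairs=300, n_dz_pairs=300, sibling_set_sizes=(),
                        n_singletons=0, n_networks=8, h2=0.4, c2=0.0, seed=6)
        ped, _ = simulate_pedigree(cfg)
        traits = simulate_ace_traits(ped, cfg)
        kin, house = build_kinship(ped), build_household(ped)
        c_hats = [fit_variance_components(traits.values[:, j], kin, house,
                                          model="ACE").c2
                  for j in range(traits.values.shape[1])]
        assert np.mean(c_hats) <= 0.05

    def test_zero_variance_trait_rejected(self, tiny_pedigree):
        kin = build_kinship(tiny_pedigree)
        with pytest.raises(ValueError):
            fit_variance_components(np.zeros(tiny_pedigree.n), kin)

    def test_ace_requires_household(self, tiny_pedigree):
        kin = build_kinship(tiny_pedigree)
        y = np.random.default_rng(1).standard_normal(tiny_pedigree.n)
        with pytest.raises(ValueError):
            fit_variance_components(y, kin, None, model="ACE")


class TestLRT:
    def test_zero_statistic_gives_half(self):
        from gcherit.varcomp import VarianceComponents

        full = VarianceComponents(0.0, 0.0, 1.0, -10.0)
        lam, p, _ = lrt_heritability(full, -10.0)
        assert lam == 0.0 and p == 0.5

    def test_boundary_mixture_quantile(self):
        """Lambda = 2.706 sits at p ~ 0.05 for the 50:50 mixture."""
        from gcherit.varcomp import VarianceComponents

        full = VarianceComponents(0.5, 0.0, 0.5, -10.0 + 2.706 / 2)
        _, p, _ = lrt_heritability(full, -10.0)
        assert p == pytest.approx(0.05, abs=0.001)

    def test_monotone_in_statistic(self):
        from gcherit.varcomp import VarianceComponents

        p_prev = 1.0
        for lam in (0.5, 1.0, 2.0, 4.0):
            full = VarianceComponents(0.5, 0.0, 0.5, lam / 2)
            _, p, _ = lrt_heritability(full, 0.0)
            assert p < p_prev
            p_prev = p

    def test_optimizer_regression_flagged(self):
        from gcherit.varcomp import VarianceComponents

        full = VarianceComponents(0.5, 0.0, 0.5, -11.0)
        _, _, flag = lrt_heritability(full, -10.0)
        assert flag


class TestFDR:
    def test_all_at_half_alpha_all_significant(self):
        q, rej = fdr_bh(np.full(10, 0.025), alpha=0.05)
        assert rej.all()

    def test_single_small_p(self):
        q, rej = fdr_bh(np.array([0.04]), alpha=0.05)
        assert rej[0] and q[0] == pytest.approx(0.04)

    def test_empty_input(self):
        q, rej = fdr_bh(np.array([]))
        assert len(q) == 0 and len(rej) == 0

    @given(seed=st.integers(0, 500), n=st.integers(1, 40))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_exhaustive_step_up_oracle(self, seed, n):
        """Brute-force step-up over all ranks reproduces the flags."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, n)
        alpha = 0.05
        _, rej = fdr_bh(p, alpha)
        order = np.argsort(p)
        k_star = 0
        for k in range(1, n + 1):
            if p[order[k - 1]] <= alpha * k / n:
                k_star = k
        expect = np.zeros(n, dtype=bool)
        expect[order[:k_star]] = True
        np.testing.assert_array_equal(rej, expect)

    def test_example_vector_flags(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        _, rej = fdr_bh(p, 0.05)
        np.testing.assert_array_equal(rej, [True, True, True, False])


class TestScanAndReplication:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        cfg = SimConfig(n_mz_pairs=100, n_dz_pairs=50, sibling_set_sizes=(2,) * 20,
                        n_singletons=20, n_networks=5, seed=7)
        ped, cov = simulate_pedigree(cfg)
        return cfg, ped, cov

    def test_null_traits_yield_no_discoveries(self, small_cohort):
        cfg, ped, cov = small_cohort
        null_cfg = SimConfig(**{**cfg.__dict__, "h2": 0.0, "c2": 0.0})
        traits = simulate_ace_traits(ped, null_cfg)
        tt = TraitTable(traits.values, traits.columns, traits.subject_ids)
        scan = heritability_scan(tt, ped, cov, model="AE")
        assert scan["significant"].sum() <= 1

    def test_heritable_traits_mostly_detected(self, small_cohort):
        cfg, ped, cov = small_cohort
        h_cfg = SimConfig(**{**cfg.__dict__, "h2": 0.6, "c2": 0.0})
        traits = simulate_ace_traits(ped, h_cfg)
        tt = TraitTable(traits.values, traits.columns, traits.subject_ids)
        scan = heritability_scan(tt, ped, cov, model="AE")
        assert scan["significant"].mean() > 0.5

    def test_empty_trait_table(self, small_cohort):
        _, ped, cov = small_cohort
        tt = TraitTable(np.empty((ped.n, 0)), [], ped.ids)
        scan = heritability_scan(tt, ped, cov)
        assert len(scan) == 0

    def test_replication_percentages_from_flag_sets(self):
        def fake_scan(n_sig, total=400):
            src = np.repeat(np.arange(20), 20)
            tgt = np.tile(np.arange(20), 20)
            sig = np.zeros(total, dtype=bool)
            sig[:n_sig] = True
            return pd.DataFrame(dict(source=src, target=tgt, significant=sig))

        def overlap(a_sig, b_sig, both):
            a = fake_scan(a_sig)
            b = fake_scan(b_sig)
            b["significant"] = False
            b.loc[: both - 1, "significant"] = True
            b.loc[a_sig : a_sig + (b_sig - both) - 1, "significant"] = True
            return replication_overlap(a, b)

        s = overlap(152, 241, 58)
        assert (s.n_discovery, s.n_both, s.pct_of_discovery) == (152, 58, 38)
        s = overlap(56, 79, 8)
        assert s.pct_of_discovery == 14

    def test_disjoint_significance_gives_zero(self):
        a = pd.DataFrame(dict(source=[0, 1], target=[1, 0],
                              significant=[True, False]))
        b = pd.DataFrame(dict(source=[0, 1], target=[1, 0],
                              significant=[False, True]))
        s = replication_overlap(a, b)
        assert s.n_both == 0 and s.pct_of_discovery == 0

    def test_key_mismatch_rejected(self):
        a = pd.DataFrame(dict(source=[0], target=[1], significant=[True]))
        b = pd.DataFrame(dict(source=[1], target=[0], significant=[True]))
        with pytest.raises(ValueError):
            replication_overlap(a, b)
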