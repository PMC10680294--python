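"""Cis association scan, effective-test correction, permutation FDR,
LD clumping and cross-cell-type summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cellcis import io_features as io
from cellcis import qtl
from cellcis.simulate import (
    PlantedEffect, SimulationConfig, simulate_genotypes, simulate_pseudobulk,
    add_duplicate_variant,
)
from cellcis.types import FeatureMatrix


class TestOlsScan:
    def test_perfect_fit_gives_exact_beta_and_floor_p(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        y = 2.0 * g
        beta, se, p = qtl.ols_scan(y, g[:, None])
        assert beta[0] == pytest.approx(2.0)
        assert p[0] == np.nextafter(0, 1)

    def test_matches_full_regression_with_covariates(self):
        rng = np.random.default_rng(0)
        n = 30
        g = rng.integers(0, 3, n).astype(float)
        c = rng.standard_normal((n, 2))
        y = 1.5 * g + c @ [0.5, -1.0] + rng.standard_normal(n)
        beta, se, p = qtl.ols_scan(y, g[:, None], c)
        import statsmodels.api as sm
        X = sm.add_constant(np.column_stack([g, c]))
        fit = sm.OLS(y, X).fit()
        assert beta[0] == pytest.approx(fit.params[1])
        assert se[0] == pytest.approx(fit.bse[1])
        assert p[0] == pytest.approx(fit.pvalues[1])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        n = 20
        ps = []
        for _ in range(1000):
            g = rng.integers(0, 3, n).astype(float)
            if g.std() == 0:
                continue
            y = rng.standard_normal(n)
            _, _, p = qtl.ols_scan(y, g[:, None])
            ps.append(p[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_covariate_restores_confounded_beta(self):
        recovered = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = 40
            g = rng.integers(0, 3, n).astype(float)
            conf = g + rng.standard_normal(n)  # correlated confounder
            y = 2.0 * g + 3.0 * conf + 0.5 * rng.standard_normal(n)
            beta, se, _ = qtl.ols_scan(y, g[:, None], conf[:, None])
            recovered += abs(beta[0] - 2.0) <= 2 * se[0]
        assert recovered >= 27

    def test_beta_invariant_to_monotone_transform_after_int(self):
        rng = np.random.default_rng(2)
        n = 20
        g = rng.integers(0, 3, n).astype(float)
        y = g + rng.standard_normal(n)
        raw = pd.DataFrame([y], index=["f"])
        same = io.inverse_normal_transform(raw)
        warped = io.inverse_normal_transform(np.exp(raw))
        b1, _, _ = qtl.ols_scan(same.iloc[0].to_numpy(), g[:, None])
        b2, _, _ = qtl.ols_scan(warped.iloc[0].to_numpy(), g[:, None])
        assert b1[0] == pytest.approx(b2[0])


class TestEffectiveTests:
    def test_independent_variants_give_full_count(self):
        rng = np.random.default_rng(0)
        D = pd.DataFrame(rng.integers(0, 3, (2000, 5)).astype(float))
        # near-identity correlation at this sample size
        assert qtl.effective_tests(D) == 5

    def test_identical_columns_collapse_to_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
        D = pd.DataFrame({i: col for i in range(6)})
        assert qtl.effective_tests(D) == 1

    def test_matches_independent_eigendecomposition(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            D = pd.DataFrame(rng.integers(0, 3, (40, 20)).astype(float))
            D = D.loc[:, D.std() > 0]
            corr = np.corrcoef(D.to_numpy().T)
            eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
            cum = np.cumsum(eig)
            expected = int(np.searchsorted(cum, 0.99 * cum[-1]) + 1)
            assert qtl.effective_tests(D) == expected

    def test_invariant_to_order_and_scaling(self):
        rng = np.random.default_rng(4)
        D = pd.DataFrame(rng.integers(0, 3, (30, 12)).astype(float))
        m = qtl.effective_tests(D)
        perm = D.sample(frac=1.0, axis=1, random_state=0)
        assert qtl.effective_tests(perm) == m
        assert qtl.effective_tests(D * 7.5) == m

    def test_windowing_sums_over_windows(self):
        rng = np.random.default_rng(5)
        D = pd.DataFrame(rng.integers(0, 3, (25, 30)).astype(float))
        total = qtl.effective_tests(D, window=10)
        parts = sum(
            qtl.effective_tests(D.iloc[:, i:i + 10]) for i in range(0, 30, 10)
        )
        assert total == parts


class TestCorrections:
    def test_bonferroni_on_m_eff(self):
        rec = pd.DataFrame({
            "feature": ["f"] * 3, "variant": ["a", "b", "c"],
            "beta": [1, 1, 1], "se": [1, 1, 1], "p": [0.001, 0.5, 0.9],
        })
        out = qtl.feature_and_study_correction(rec, {"f": 10})
        assert out.loc["f", "p_feature"] == pytest.approx(0.01)

    def test_p_feature_capped_at_one(self):
        rec = pd.DataFrame({
            "feature": ["f"], "variant": ["a"], "beta": [0], "se": [1],
            "p": [0.5],
        })
        out = qtl.feature_and_study_correction(rec, {"f": 10})
        assert out.loc["f", "p_feature"] == 1.0

    def test_bh_across_features(self):
        rec = pd.DataFrame({
            "feature": list("abcd"), "variant": ["v"] * 4,
            "beta": [0] * 4, "se": [1] * 4, "p": [0.01, 0.02, 0.03, 0.5],
        })
        out = qtl.feature_and_study_correction(rec, {f: 1 for f in "abcd"},
                                               fdr=0.10)
        assert list(out["significant"]) == [True, True, True, False]


class TestPermutationFdr:
    @staticmethod
    def brute_force(true_p, null_p, fdr):
        best = None
        for t in sorted(set(true_p)):
            n_null = (null_p <= t).sum()
            n_true = (true_p <= t).sum()
            if (1 + n_null) / max(1, n_true) <= fdr:
                best = t
        if best is None:
            return 0.0, np.zeros(len(true_p), bool)
        return best, true_p <= best

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            true_p = rng.random(60)
            true_p[:10] *= 1e-3
            null_p = rng.random(60)
            t1, c1 = qtl.permutation_fdr_threshold(true_p, null_p)
            t2, c2 = self.brute_force(true_p, null_p, 0.10)
            assert t1 == pytest.approx(t2)
            np.testing.assert_array_equal(c1, c2)

    def test_planted_features_called(self):
        rng = np.random.default_rng(1)
        true_p = np.concatenate([np.full(10, 1e-4), rng.uniform(0.05, 1, 90)])
        null_p = rng.uniform(0.011, 1, 100)
        _, calls = qtl.permutation_fdr_threshold(true_p, null_p)
        assert calls[:10].all()
        assert calls.sum() == 10

    def test_complete_separation_calls_everything(self):
        t, calls = qtl.permutation_fdr_threshold(
            np.zeros(20), np.ones(20)
        )
        assert calls.all()

    def test_pure_null_rarely_calls(self):
        rng = np.random.default_rng(0)
        excess = 0
        for _ in range(100):
            _, calls = qtl.permutation_fdr_threshold(
                rng.random(100), rng.random(100)
            )
            excess += calls.sum() > 2
        assert excess <= 5

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            qtl.permutation_fdr_threshold(np.array([]), np.array([0.5]))


class TestLdClump:
    def test_spec_example_structure(self, genotypes):
        gm = add_duplicate_variant(genotypes, "var00010", "var_dup",
                                   pos=int(genotypes.variants.loc["var00010", "pos"]) + 10)
        rec = pd.DataFrame({
            "feature": "f",
            "variant": ["var00010", "var_dup", "var00050"],
            "beta": [1, 1, 1], "se": [1, 1, 1],
            "p": [1e-5, 1e-4, 0.2],
        })
        clumps = qtl.ld_clump(rec, gm, anchor_pos=0)
        assert len(clumps) == 1
        assert clumps[0]["index"] == "var00010"
        assert set(clumps[0]["members"]) == {"var00010", "var_dup"}

    def test_tie_broken_by_distance_to_anchor(self, genotypes):
        rec = pd.DataFrame({
            "feature": "f", "variant": ["var00010", "var00050"],
            "beta": [1, 1], "se": [1, 1], "p": [1e-3, 1e-3],
        })
        anchor = int(genotypes.variants.loc["var00050", "pos"]) - 1
        clumps = qtl.ld_clump(rec, genotypes, anchor_pos=anchor)
        assert clumps[0]["index"] == "var00050"

    def test_single_variant_singleton_clump(self, genotypes):
        rec = pd.DataFrame({
            "feature": "f", "variant": ["var00010"],
            "beta": [1], "se": [1], "p": [1e-3],
        })
        clumps = qtl.ld_clump(rec, genotypes, anchor_pos=0)
        assert clumps == [{"index": "var00010", "members": ["var00010"]}]

    def test_no_significant_variants_empty(self, genotypes):
        rec = pd.DataFrame({
            "feature": "f", "variant": ["var00010"],
            "beta": [1], "se": [1], "p": [0.6],
        })
        assert qtl.ld_clump(rec, genotypes, anchor_pos=0) == []


class TestEndToEndMapping:
    def test_planted_effects_called_and_nulls_controlled(self):
        cfg = SimulationConfig(n_samples=20, seed=21, noise_sd=0.5)
        gm = simulate_genotypes(cfg, 100, spacing_bp=1000)
        effects = [
            PlantedEffect(f"g{k:04d}", gm.variants.index[k * 10 + 5], "Rod", 3.0)
            for k in range(3)
        ]
        expr, truth = simulate_pseudobulk(gm, effects, cfg, ("Rod",),
                                          n_features=30)
        fm = io.normalize_transform(expr["Rod"], "int")
        uni = io.build_test_universe(gm, fm.features, ocrs=None)
        _, corr = qtl.map_qtl_eigen_bh(fm, gm, uni)
        called = set(corr.index[corr["significant"]])
        planted = set(truth.query("is_causal")["entity"])
        assert planted <= called
        assert len(called - planted) <= 3

    def test_permutation_scheme_on_null_data_calls_nothing(self):
        cfg = SimulationConfig(n_samples=20, seed=22)
        gm = simulate_genotypes(cfg, 100, spacing_bp=1000)
        expr, _ = simulate_pseudobulk(gm, [], cfg, ("Rod",), n_features=50)
        fm = io.normalize_transform(expr["Rod"], "int")
        uni = io.build_test_universe(gm, fm.features, ocrs=None)
        _, corr, _ = qtl.map_qtl_permutation(fm, gm, uni, perm_seed=1)
        assert corr["significant"].sum() <= 2


class TestCrossCellType:
    def test_identical_calls_give_unit_correlation(self):
        rec = pd.DataFrame({
            "feature": ["f1", "f2", "f3"],
            "variant": ["a", "b", "c"],
            "beta": [1.0, -2.0, 0.5], "se": [1, 1, 1], "p": [1e-4] * 3,
        })
        calls = {"Rod": {"a", "b", "c"}, "Cone": {"a", "b", "c"}}
        spec, corr = qtl.cross_celltype_summary(
            calls, {"Rod": rec, "Cone": rec.copy()}
        )
        assert corr.loc["Rod", "Cone"] == pytest.approx(1.0)
        assert (spec["n_cell_types"] == 2).all()

    def test_independent_null_betas_uncorrelated(self):
        rng = np.random.default_rng(0)
        n = 200
        base = {
            "feature": [f"f{i}" for i in range(n)],
            "variant": [f"v{i}" for i in range(n)],
            "se": [1.0] * n, "p": [1e-4] * n,
        }
        rec_a = pd.DataFrame({**base, "beta": rng.standard_normal(n)})
        rec_b = pd.DataFrame({**base, "beta": rng.standard_normal(n)})
        calls = {"Rod": set(base["variant"]), "Cone": set(base["variant"])}
        _, corr = qtl.cross_celltype_summary(
            calls, {"Rod": rec_a, "Cone": rec_b}
        )
        assert abs(corr.loc["Rod", "Cone"]) < 3 / np.sqrt(n)
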