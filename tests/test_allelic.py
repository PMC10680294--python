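"""Allele-specific accessibility (Fisher + weighted Stouffer meta) and
haplotype-based allele-specific expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cellcis import allelic
from cellcis.pipeline import _asca_genotypes
from cellcis.simulate import SimulationConfig, simulate_allelic_counts


class TestSampleTest:
    def test_matches_scipy_fisher_on_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            aa, ar, wa, wr = rng.integers(0, 13, 4)
            table = [[aa, ar], [wa, wr]]
            for direction, alt in [("greater", "greater"), ("less", "less")]:
                ours = allelic.asca_sample_test(wr, wa, ar, aa, direction)
                ref = stats.fisher_exact(table, alternative=alt)[1]
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_identical_ratios_are_not_significant(self):
        pg = allelic.asca_sample_test(5, 5, 5, 5, "greater")
        pl = allelic.asca_sample_test(5, 5, 5, 5, "less")
        assert pg >= 0.5 and pl >= 0.5

    def test_swapping_alleles_swaps_directions(self):
        p1 = allelic.asca_sample_test(5, 5, 1, 9, "greater")
        p2 = allelic.asca_sample_test(5, 5, 9, 1, "less")
        assert p1 == pytest.approx(p2, abs=1e-14)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            allelic.asca_sample_test(-1, 5, 5, 5)

    def test_null_binomial_model_is_conservative(self):
        rng = np.random.default_rng(1)
        n = 4000
        wgs_alt = rng.binomial(30, 0.5, n)
        atac_alt = rng.binomial(30, 0.5, n)
        p = allelic.asca_sample_test(30 - wgs_alt, wgs_alt,
                                     30 - atac_alt, atac_alt, "greater")
        frac = (p < 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


class TestMeta:
    def test_closed_form_equal_weights(self):
        expected = stats.norm.sf(np.sqrt(3) * stats.norm.isf(0.05))
        assert allelic.asca_meta([0.05] * 3, [1, 1, 1]) == pytest.approx(expected)

    def test_single_sample_identity(self):
        assert allelic.asca_meta([0.123], [10]) == pytest.approx(0.123)

    @given(st.floats(0.5, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_weight_scaling_invariance(self, scale):
        p = [0.01, 0.2, 0.7]
        w = np.array([30.0, 90.0, 45.0])
        assert allelic.asca_meta(p, w) == pytest.approx(
            allelic.asca_meta(p, w * scale)
        )

    def test_sample_order_invariance(self):
        p = [0.01, 0.2, 0.7]
        w = [30.0, 90.0, 45.0]
        assert allelic.asca_meta(p, w) == pytest.approx(
            allelic.asca_meta(p[::-1], w[::-1])
        )

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            allelic.asca_meta([0.5], [0.0])


def _counts_row(variant, sample, source, ref, alt, ct="Rod"):
    return {"variant": variant, "sample": sample, "cell_type": ct,
            "source": source, "ref_count": ref, "alt_count": alt}


class TestAscaCall:
    def test_min_het_and_min_reads_filters(self):
        gm = _asca_genotypes(1, n_het=3)
        rows = []
        # S00, S01 qualify; S02 has only 8 WGS reads
        for s, wgs in [("S00", 20), ("S01", 20), ("S02", 8)]:
            rows.append(_counts_row("v00000", s, "WGS", wgs // 2, wgs - wgs // 2))
            rows.append(_counts_row("v00000", s, "ATAC", 5, 15))
        res = allelic.asca_call(pd.DataFrame(rows), gm, min_het=3)
        assert res.empty  # only 2 qualifying hets
        res2 = allelic.asca_call(pd.DataFrame(rows), gm, min_het=2)
        assert len(res2) == 1 and res2.loc[0, "n_het"] == 2

    def test_meta_equals_reference_stouffer(self):
        gm = _asca_genotypes(1, n_het=3)
        rows = []
        tables = [(12, 8, 4, 16), (10, 10, 6, 14), (15, 10, 5, 20)]
        for (wr, wa, ar, aa), s in zip(tables, ["S00", "S01", "S02"]):
            rows.append(_counts_row("v00000", s, "WGS", wr, wa))
            rows.append(_counts_row("v00000", s, "ATAC", ar, aa))
        res = allelic.asca_call(pd.DataFrame(rows), gm, min_het=3)
        ps, ws = [], []
        for wr, wa, ar, aa in tables:
            ps.append(allelic.asca_sample_test(wr, wa, ar, aa, "greater"))
            ws.append(wr + wa + ar + aa)
        expected = allelic.asca_meta(ps, ws)
        assert res.loc[0, "direction"] == "greater"
        assert res.loc[0, "meta_p"] == pytest.approx(expected)
        # effect size: read-weighted mean of fraction differences
        d = [(aa / (aa + ar)) - (wa / (wa + wr)) for wr, wa, ar, aa in tables]
        w = np.array(ws, float)
        assert res.loc[0, "effect_size"] == pytest.approx((w * d).sum() / w.sum())

    def test_universe_restriction(self):
        gm = _asca_genotypes(2, n_het=3)
        rows = []
        for v in ["v00000", "v00001"]:
            for s in ["S00", "S01", "S02"]:
                rows.append(_counts_row(v, s, "WGS", 10, 10))
                rows.append(_counts_row(v, s, "ATAC", 4, 16))
        res = allelic.asca_call(pd.DataFrame(rows), gm,
                                universe_variants={"v00000"})
        assert set(res["variant"]) == {"v00000"}

    def test_null_simulation_rarely_calls(self):
        gm = _asca_genotypes(500, n_het=5)
        cfg = SimulationConfig(n_samples=10, seed=5, wgs_depth=50,
                               atac_depth=50)
        counts, _ = simulate_allelic_counts(
            gm, {v: 0.5 for v in gm.variants.index}, cfg
        )
        res = allelic.asca_call(counts, gm)
        assert res["significant"].sum() <= 2


class TestAse:
    @pytest.fixture
    def gm6(self):
        return _asca_genotypes(1, n_het=6, n_hom=0)

    def test_identical_haplotype_counts_are_null(self, gm6):
        df = pd.DataFrame({
            "gene": "g1", "variant": "v00000",
            "sample": [f"S{i:02d}" for i in range(6)],
            "ref_hap": 20, "alt_hap": 20,
        })
        res = allelic.ase_effect_test(df, gm6)
        assert res.loc[0, "effect_size"] == 0.0
        assert res.loc[0, "p"] == 1.0

    def test_effect_formula_and_exact_signed_rank(self, gm6):
        df = pd.DataFrame({
            "gene": "g1", "variant": "v00000",
            "sample": [f"S{i:02d}" for i in range(6)],
            "ref_hap": 10, "alt_hap": 40,
        })
        res = allelic.ase_effect_test(df, gm6)
        assert res.loc[0, "effect_size"] == pytest.approx(np.log2(41 / 11) / 2)
        # six identical positive values: exact two-sided signed-rank p
        lr = np.full(6, np.log2(41 / 11))
        expected = stats.wilcoxon(lr, alternative="two-sided").pvalue
        assert res.loc[0, "p"] == pytest.approx(expected)

    def test_swapping_alleles_flips_sign_keeps_p(self, gm6):
        base = pd.DataFrame({
            "gene": "g1", "variant": "v00000",
            "sample": [f"S{i:02d}" for i in range(6)],
            "ref_hap": [10, 12, 9, 30, 11, 8],
            "alt_hap": [40, 35, 20, 60, 42, 25],
        })
        flipped = base.rename(columns={"ref_hap": "alt_hap",
                                       "alt_hap": "ref_hap"})
        r1 = allelic.ase_effect_test(base, gm6)
        r2 = allelic.ase_effect_test(flipped, gm6)
        assert r1.loc[0, "effect_size"] == pytest.approx(-r2.loc[0, "effect_size"])
        assert r1.loc[0, "p"] == pytest.approx(r2.loc[0, "p"])

    def test_min_het_exclusion(self):
        gm = _asca_genotypes(1, n_het=3, n_hom=0)
        df = pd.DataFrame({
            "gene": "g1", "variant": "v00000",
            "sample": ["S00", "S01", "S02"],
            "ref_hap": 10, "alt_hap": 40,
        })
        assert allelic.ase_effect_test(df, gm, min_het=4).empty


class TestConcordance:
    def test_identical_effects_fully_concordant(self):
        qtls = pd.DataFrame({
            "variant": ["a", "b", "c", "d"], "cell_type": "Rod",
            "beta": [1.0, -1.0, 0.5, 2.0],
        })
        asca = pd.DataFrame({
            "variant": ["a", "b", "c", "d"], "cell_type": "Rod",
            "effect_size": [0.3, -0.2, 0.1, 0.4],
        })
        out = allelic.qtl_allelic_concordance(qtls, asca)
        assert out["direction_concordance"] == 1.0
        assert out["pearson_r"] > 0.9

    def test_single_overlap_reports_missing_r(self):
        qtls = pd.DataFrame({"variant": ["a"], "cell_type": ["Rod"],
                             "beta": [1.0]})
        asca = pd.DataFrame({"variant": ["a"], "cell_type": ["Rod"],
                             "effect_size": [0.3]})
        out = allelic.qtl_allelic_concordance(qtls, asca)
        assert np.isnan(out["pearson_r"])
        assert out["n_overlap"] == 1

    def test_independent_signs_near_half_concordant(self):
        rng = np.random.default_rng(0)
        n = 500
        qtls = pd.DataFrame({"variant": [f"v{i}" for i in range(n)],
                             "cell_type": "Rod",
                             "beta": rng.standard_normal(n)})
        asca = pd.DataFrame({"variant": [f"v{i}" for i in range(n)],
                             "cell_type": "Rod",
                             "effect_size": rng.standard_normal(n)})
        out = allelic.qtl_allelic_concordance(qtls, asca)
        assert abs(out["direction_concordance"] - 0.5) < 3 / (2 * np.sqrt(n))
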