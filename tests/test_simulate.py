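"""The synthetic cohort generator: determinism, LD structure, planted
effects, allelic counts, MPRA counts and GWAS summary statistics."""

import numpy as np
import pandas as pd
import pytest

from cellcis.simulate import (
    PlantedEffect,
    SimulationConfig,
    add_duplicate_variant,
    simulate_allelic_counts,
    simulate_genotypes,
    simulate_dependency_architecture,
    simulate_gwas_block,
    simulate_mpra,
    simulate_pseudobulk,
)


class TestConfig:
    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            SimulationConfig(n_samples=3)

    @pytest.mark.parametrize("kw", [
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.4, 0.2)},
        {"wgs_depth": 0.0},
        {"ld_decay": 1.5},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)


class TestGenotypes:
    def test_same_seed_identical(self):
        a = simulate_genotypes(SimulationConfig(seed=11), 50)
        b = simulate_genotypes(SimulationConfig(seed=11), 50)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_dosage_values_and_maf_range(self, genotypes):
        vals = genotypes.dosages.to_numpy()
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}
        # population MAF in [0.1, 0.5]; sample MAF within sampling error
        assert (genotypes.maf() >= 0.025).all()

    def test_ld_decay_zero_gives_uncorrelated_variants(self):
        cfg = SimulationConfig(n_samples=500, seed=3, ld_decay=0.0,
                               ld_block_size=50)
        gm = simulate_genotypes(cfg, n_variants=100)
        D = gm.dosages.to_numpy()
        r = np.corrcoef(D.T)
        pairs = [r[i, j] ** 2 for i in range(100) for j in range(i + 1, 100)]
        assert np.mean(pairs[:1000]) < 3.0 / 500

    def test_ld_decays_with_distance(self):
        cfg = SimulationConfig(n_samples=400, seed=5, ld_decay=0.9,
                               ld_block_size=10)
        gm = simulate_genotypes(cfg, n_variants=100)
        D = gm.dosages.to_numpy()
        r = np.corrcoef(D.T)
        r2_d1 = np.mean([r[i, i + 1] ** 2 for i in range(99) if i % 10 < 9])
        r2_d5 = np.mean([r[i, i + 5] ** 2 for i in range(95) if i % 10 < 5])
        assert r2_d1 > r2_d5 > 0
        # blocks independent
        across = np.mean([r[i * 10 + 9, i * 10 + 10] ** 2 for i in range(9)])
        assert across < 0.1

    def test_duplicate_variant_has_r2_one(self, genotypes):
        gm = add_duplicate_variant(genotypes, "var00000", "var_dup")
        r = gm.dosages["var00000"].corr(gm.dosages["var_dup"])
        assert r ** 2 == pytest.approx(1.0)


class TestPseudobulk:
    def test_null_slopes_give_null_correlations(self, genotypes, config):
        out, truth = simulate_pseudobulk(genotypes, [], config, ("Rod",),
                                         n_features=30)
        fm = out["Rod"]
        corrs = [
            fm.values.loc[f].corr(genotypes.dosages["var00000"])
            for f in fm.values.index
        ]
        assert abs(np.mean(corrs)) < 3.0 / np.sqrt(30 * 20)
        assert (truth["effect_size"] == 0).all()

    def test_planted_slope_recovered_by_ols(self):
        hits = 0
        for seed in range(40):
            cfg = SimulationConfig(n_samples=20, seed=seed, noise_sd=0.1)
            gm = simulate_genotypes(cfg, 20)
            eff = [PlantedEffect("g0000", "var00005", "Rod", 2.0)]
            out, _ = simulate_pseudobulk(gm, eff, cfg, ("Rod",), n_features=10)
            y = out["Rod"].values.loc["g0000"]
            g = gm.dosages["var00005"]
            beta = np.polyfit(g, y, 1)[0]
            hits += 1.8 <= beta <= 2.2
        assert hits >= 38  # 95% of replicates at this noise level

    def test_effect_in_one_cell_type_leaves_other_untouched(self, genotypes, config):
        eff = [PlantedEffect("g0000", "var00005", "Rod", 3.0)]
        with_eff, _ = simulate_pseudobulk(genotypes, eff, config, ("Rod", "Cone"))
        without, _ = simulate_pseudobulk(genotypes, [], config, ("Rod", "Cone"))
        pd.testing.assert_frame_equal(with_eff["Cone"].values, without["Cone"].values)
        assert not with_eff["Rod"].values.equals(without["Rod"].values)

    def test_variant_outside_cis_window_rejected(self, config):
        gm = simulate_genotypes(config, 600, spacing_bp=1000)  # spans 600 kb
        eff = [PlantedEffect("g0000", gm.variants.index[-1], "Rod", 1.0)]
        with pytest.raises(ValueError, match="not cis"):
            simulate_pseudobulk(gm, eff, config, ("Rod",), n_features=10)


class TestDependencyArchitecture:
    def test_strong_positive_coupling_gives_high_correlation(self, genotypes):
        cfg = SimulationConfig(n_samples=20, seed=1, noise_sd=0.1)
        fm, truth = simulate_dependency_architecture(
            genotypes, "var00030", coupling_signs=(1,), config=cfg, beta=2.0,
        )
        r = fm.values.loc["master"].corr(fm.values.loc["dep0"])
        assert r > 0.9

    def test_negative_coupling_flips_effect_sign(self, genotypes):
        cfg = SimulationConfig(n_samples=20, seed=1, noise_sd=0.2)
        fm, _ = simulate_dependency_architecture(
            genotypes, "var00030", coupling_signs=(-1,), config=cfg, beta=2.0,
        )
        g = genotypes.dosages["var00030"]
        bm = np.polyfit(g, fm.values.loc["master"], 1)[0]
        bd = np.polyfit(g, fm.values.loc["dep0"], 1)[0]
        assert bm > 0 > bd

    def test_zero_coupling_is_null(self, genotypes, config):
        fm, _ = simulate_dependency_architecture(
            genotypes, "var00030", coupling_signs=(0,), config=config,
        )
        g = genotypes.dosages["var00030"]
        r = fm.values.loc["dep0"].corr(g)
        assert abs(r) < 0.5

    def test_distant_dependent_rejected(self, genotypes, config):
        with pytest.raises(ValueError, match="250 kb"):
            simulate_dependency_architecture(
                genotypes, "var00030", coupling_signs=(1,), config=config,
                dependent_offsets_bp=(250_001,),
            )


class TestAllelicCounts:
    def test_balanced_fraction_centres_at_half(self, genotypes, config):
        counts, _ = simulate_allelic_counts(genotypes, {"var00000": 0.5}, config)
        het = genotypes.dosages["var00000"] == 1
        atac = counts.query("source == 'ATAC'").set_index("sample")
        atac = atac.loc[het[het].index]
        prop = atac["alt_count"] / (atac["alt_count"] + atac["ref_count"])
        se = np.sqrt(0.25 / 50 / len(prop))
        assert abs(prop.mean() - 0.5) < 3 * se + 1e-9

    def test_planted_fraction_within_binomial_range(self):
        ok = 0
        n_sites = 100
        cfg = SimulationConfig(n_samples=20, seed=2, atac_depth=100,
                               wgs_depth=100)
        gm = simulate_genotypes(cfg, n_sites)
        counts, _ = simulate_allelic_counts(
            gm, {v: 0.8 for v in gm.variants.index}, cfg
        )
        atac = counts.query("source == 'ATAC'")
        for v, grp in atac.groupby("variant"):
            het = gm.dosages[v] == 1
            grp = grp[grp["sample"].isin(het[het].index)]
            if len(grp) == 0:
                n_sites -= 1
                continue
            prop = grp["alt_count"].sum() / (
                grp["alt_count"].sum() + grp["ref_count"].sum()
            )
            ok += 0.72 <= prop <= 0.88
        assert ok >= 0.95 * n_sites

    def test_homozygous_ref_emits_no_alt_reads(self, genotypes, config):
        counts, _ = simulate_allelic_counts(genotypes, {"var00000": 0.7}, config)
        hom_ref = genotypes.dosages["var00000"] == 0
        sub = counts[counts["sample"].isin(hom_ref[hom_ref].index)]
        assert (sub["alt_count"] == 0).all()

    def test_invalid_fraction_rejected(self, genotypes, config):
        with pytest.raises(ValueError, match="alt-fraction"):
            simulate_allelic_counts(genotypes, {"var00000": 1.0}, config)


class TestMpra:
    def test_basal_gets_25_barcodes_per_replicate(self, config):
        counts, _ = simulate_mpra({"e1": 0.0}, config, replicates=3)
        basal = counts.query("element == 'basal'")
        assert basal.groupby("replicate").size().eq(25).all()

    def test_replicate_and_barcode_minimums(self, config):
        with pytest.raises(ValueError):
            simulate_mpra({"e1": 0.0}, config, replicates=1)
        with pytest.raises(ValueError):
            simulate_mpra({"e1": 0.0}, config, barcodes_per_element=0)

    def test_planted_activity_recovered_in_log2_ratio(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, mpra_depth=100.0)
            counts, _ = simulate_mpra({"e1": 2.0}, cfg, replicates=4)
            lr = np.log2((counts["rna_count"] + 0.5) / (counts["dna_count"] + 0.5))
            basal = lr[counts["element"] == "basal"].mean()
            elem = lr[counts["element"] == "e1"].mean()
            hits += 1.6 <= elem - basal <= 2.4
        assert hits >= 19

    def test_null_activities_centre_log2fc_at_zero(self, config):
        counts, _ = simulate_mpra({f"e{i}": 0.0 for i in range(30)}, config)
        lr = np.log2((counts["rna_count"] + 0.5) / (counts["dna_count"] + 0.5))
        basal = lr[counts["element"] == "basal"].mean()
        fcs = [
            lr[counts["element"] == f"e{i}"].mean() - basal for i in range(30)
        ]
        assert abs(np.mean(fcs)) < 0.1


class TestGwasBlock:
    def test_null_effect_rarely_reaches_genome_wide_significance(self):
        hits = 0
        for seed in range(40):
            cfg = SimulationConfig(seed=seed)
            gm = simulate_genotypes(cfg, 50)
            g, _, _ = simulate_gwas_block(
                gm, gm.variants.index[25], cfg, z_causal=0.0
            )
            hits += g["p"].min() > 5e-8
        assert hits >= 38

    def test_strong_causal_attains_block_minimum_p(self):
        hits = 0
        for seed in range(30):
            cfg = SimulationConfig(seed=seed, ld_decay=0.3)
            gm = simulate_genotypes(cfg, 50)
            causal = gm.variants.index[25]
            g, _, _ = simulate_gwas_block(gm, causal, cfg, z_causal=10.0)
            hits += g.loc[g["p"].idxmin(), "variant_id"] == causal
        assert hits >= 27

    def test_beta_se_consistent_with_p(self, genotypes, config):
        g, _, _ = simulate_gwas_block(genotypes, "var00030", config)
        from scipy import stats
        z = g["beta"] / g["se"]
        np.testing.assert_allclose(g["p"], 2 * stats.norm.sf(np.abs(z)),
                                   rtol=1e-10)

    def test_distinct_mode_needs_low_ld_partner(self):
        cfg = SimulationConfig(seed=0, ld_decay=1.0, ld_block_size=10)
        gm = simulate_genotypes(cfg, 10)  # one fully correlated block
        with pytest.raises(ValueError, match="r"):
            simulate_gwas_block(gm, gm.variants.index[5], cfg,
                                paired_qtl="distinct")

    def test_shared_mode_uses_same_causal(self, genotypes, config):
        _, qtl, truth = simulate_gwas_block(
            genotypes, "var00030", config, paired_qtl="shared"
        )
        assert truth["qtl_causal"].iloc[0] == "var00030"
        assert qtl is not None
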