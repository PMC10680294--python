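"""End-to-end pipeline on synthetic data with known ground truth.

Runs every stage — genotype simulation, pseudobulk phenotypes, cis QTL
mapping for expression and accessibility, allele-specific accessibility,
regulatory-element linking, master/dependent peak detection, motif
perturbation, MPRA scoring, and GWAS fine-mapping/colocalization — on a
single synthetic cohort, and reports truth-recovery metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import allelic, gwas, io_features, linking, masterdep, motif, mpra, qtl
from .simulate import (
    PlantedEffect,
    SimulationConfig,
    simulate_allelic_counts,
    simulate_dependency_architecture,
    simulate_genotypes,
    simulate_gwas_block,
    simulate_mpra,
    simulate_pseudobulk,
)
__all__ = [
    "run_end_to_end",
    "qtl_recovery_study",
    "asca_study",
    "enrichment_recovery_study",
]

CELL_TYPES = ("Rod", "Cone")


def _block_center_variants(n_features: int, block_size: int) -> list[int]:
    return [i * block_size + block_size // 2 for i in range(n_features)]


def _make_features(genotypes, variant_idx, width, prefix):
    v = genotypes.variants
    rows = []
    for k, i in enumerate(variant_idx):
        pos0 = int(v["pos"].iloc[i]) - 1
        rows.append({
            "id": f"{prefix}{k:04d}",
            "chrom": v["chrom"].iloc[i],
            "start": max(pos0 - width // 2, 0),
            "end": pos0 + width // 2 + 1,
            "strand": "+",
            "anchor": pos0,
        })
    return pd.DataFrame(rows).set_index("id")


def run_end_to_end(
    seed: int = 0,
    n_samples: int = 20,
    n_blocks: int = 40,
    block_size: int = 10,
    n_planted_eqtl: int = 8,
    n_planted_caqtl: int = 20,
    slope: float = 3.0,
    fdr: float = 0.10,
) -> dict:
    """Run all pipeline stages on one synthetic cohort; return metrics."""
    config = SimulationConfig(n_samples=n_samples, seed=seed, noise_sd=1.0)
    n_variants = n_blocks * block_size
    # 50 kb between variants: the 250 kb cis window then selects roughly
    # one LD block of candidates per gene, as in a sparse OCR landscape
    genotypes = simulate_genotypes(config, n_variants=n_variants, spacing_bp=50_000)
    centers = _block_center_variants(n_blocks, block_size)
    center_ids = [genotypes.variants.index[i] for i in centers]

    # features: one gene (TSS two variants before the block center) and
    # one peak (on the block center variant) per LD block
    gene_feats = _make_features(
        genotypes, [i * block_size + 3 for i in range(n_blocks)], 1000, "gene"
    )
    peak_feats = _make_features(genotypes, centers, 500, "peak")

    # every variant sits in an OCR accessible in both cell types
    all_var_bed = pd.DataFrame({
        "chrom": genotypes.variants["chrom"].to_numpy(),
        "start": genotypes.variants["pos"].to_numpy() - 251,
        "end": genotypes.variants["pos"].to_numpy() + 250,
    })
    ocrs = io_features.merge_peak_sets({ct: all_var_bed for ct in CELL_TYPES})

    # --- expression with planted cis effects (Rod; half shared with Cone)
    eqtl_effects = []
    for k in range(n_planted_eqtl):
        eqtl_effects.append(PlantedEffect(f"gene{k:04d}", center_ids[k], "Rod", slope))
        if k < n_planted_eqtl // 2:
            eqtl_effects.append(
                PlantedEffect(f"gene{k:04d}", center_ids[k], "Cone", slope)
            )
    expr, expr_truth = simulate_pseudobulk(
        genotypes, eqtl_effects, config, CELL_TYPES,
        kind="gene", features=gene_feats,
    )

    # --- accessibility with planted caQTLs (Rod)
    caqtl_effects = [
        PlantedEffect(f"peak{k:04d}", center_ids[k], "Rod", slope)
        for k in range(n_planted_caqtl)
    ]
    acc, acc_truth = simulate_pseudobulk(
        genotypes, caqtl_effects, config, CELL_TYPES,
        kind="peak", features=peak_feats,
    )

    metrics: dict = {}

    # --- sc-eQTL mapping: INT + covariates + eigen-Bonferroni + BH
    eqtl_records, eqtl_calls = {}, {}
    uni_gene = io_features.build_test_universe(
        genotypes, gene_feats, ocrs, cell_type="Rod", mode="window"
    )
    for ct in CELL_TYPES:
        fm = io_features.normalize_transform(expr[ct], "int")
        cov = qtl.default_covariates(fm, genotypes)
        rec, corr = qtl.map_qtl_eigen_bh(fm, genotypes, uni_gene, cov, fdr)
        eqtl_records[ct] = rec
        eqtl_calls[ct] = corr
    truth_rod = expr_truth.query("cell_type == 'Rod' and is_causal")["entity"]
    called_rod = set(eqtl_calls["Rod"].index[eqtl_calls["Rod"]["significant"]])
    metrics["eqtl_recall"] = float(
        np.mean([g in called_rod for g in truth_rod])
    )
    null_rod = set(expr_truth.query("cell_type == 'Rod' and ~is_causal")["entity"])
    n_false = len(called_rod & null_rod)
    metrics["eqtl_fdp"] = n_false / max(1, len(called_rod))

    # cross-cell-type summary on index variants
    calls_by_ct = {
        ct: set(eqtl_calls[ct].loc[eqtl_calls[ct]["significant"], "lead_variant"])
        for ct in CELL_TYPES
    }
    spec_table, beta_corr = qtl.cross_celltype_summary(
        calls_by_ct, eqtl_records, genotypes
    )
    metrics["eqtl_rod_cone_beta_corr"] = float(beta_corr.loc["Rod", "Cone"])

    # LD clumping for the strongest eGene
    if len(called_rod):
        top_gene = eqtl_calls["Rod"].loc[sorted(called_rod)]["p_feature"].idxmin()
        rec = eqtl_records["Rod"].query("feature == @top_gene")
        clumps = qtl.ld_clump(
            rec, genotypes, anchor_pos=int(gene_feats.loc[top_gene, "anchor"]),
        )
        metrics["eqtl_top_gene_clumps"] = len(clumps)

    # --- sc-caQTL mapping: permutation empirical FDR
    uni_peak = io_features.build_test_universe(
        genotypes, peak_feats, ocrs, cell_type="Rod", mode="within"
    )
    fm_acc = io_features.normalize_transform(acc["Rod"], "int")
    cov_acc = qtl.default_covariates(fm_acc, genotypes)
    ca_rec, ca_corr, t_star = qtl.map_qtl_permutation(
        fm_acc, genotypes, uni_peak, cov_acc, fdr, perm_seed=seed,
    )
    truth_ca = set(acc_truth.query("cell_type == 'Rod' and is_causal")["entity"])
    called_ca = set(ca_corr.index[ca_corr["significant"]])
    tested_planted = truth_ca & set(ca_corr.index)
    metrics["caqtl_recall"] = float(
        np.mean([p in called_ca for p in tested_planted])
    ) if tested_planted else np.nan
    metrics["caqtl_threshold"] = t_star

    # --- sc-ASCA on the caQTL variants (alt fraction 0.7) among nulls
    imbalance = {vid: 0.7 for vid in center_ids[:n_planted_caqtl]}
    imbalance.update({vid: 0.5 for vid in center_ids[n_planted_caqtl:2 * n_planted_caqtl]})
    counts, asca_truth = simulate_allelic_counts(genotypes, imbalance, config)
    asca = allelic.asca_call(
        counts, genotypes, set(uni_gene.all_variants()), fdr=fdr
    )
    planted = set(asca_truth.query("is_causal")["entity"])
    tested = set(asca["variant"])
    hits = asca[asca["significant"]]
    metrics["asca_recall"] = float(
        np.mean([v in set(hits["variant"]) for v in planted & tested])
    ) if planted & tested else np.nan
    planted_hits = hits[hits["variant"].isin(planted)]
    metrics["asca_direction_agreement"] = float(
        np.mean(planted_hits["direction"] == "greater")
    ) if len(planted_hits) else np.nan

    # caQTL / ASCA concordance
    ca_sig = ca_corr[ca_corr["significant"]].reset_index()
    ca_sig = ca_sig.rename(columns={"lead_variant": "variant", "lead_beta": "beta"})
    ca_sig["cell_type"] = "Rod"
    metrics["caqtl_asca_concordance"] = allelic.qtl_allelic_concordance(
        ca_sig[["variant", "cell_type", "beta"]], hits
    )["direction_concordance"]

    # --- regulatory-element linking with one planted enhancer and one
    # promoter-coupled peak
    groups = [f"{s}:{ct}" for ct in CELL_TYPES for s in genotypes.samples]
    expr_agg = pd.concat(
        [expr[ct].values for ct in CELL_TYPES], axis=1
    )
    expr_agg.columns = groups
    acc_agg = pd.concat([acc[ct].values for ct in CELL_TYPES], axis=1)
    acc_agg.columns = groups
    rng = config.rng("linking")
    # promoter peak for gene0001 plus an enhancer peak tied to gene0000
    prom_peak = peak_feats.iloc[[1]].copy()
    prom_peak.index = ["peakProm1"]
    g1 = gene_feats.loc["gene0001"]
    prom_peak.loc["peakProm1", ["start", "end", "anchor"]] = [
        max(g1["anchor"] - 200, 0), g1["anchor"] + 201, g1["anchor"]
    ]
    acc_meta = pd.concat([peak_feats, prom_peak])
    acc_agg = pd.concat([
        acc_agg,
        pd.DataFrame(
            [10 + 0.2 * rng.standard_normal(len(groups))],
            index=["peakProm1"], columns=groups,
        ),
    ])
    acc_agg.loc["peak0000"] = (
        expr_agg.loc["gene0000"] + 0.2 * rng.standard_normal(len(groups))
    )
    acc_agg.loc["peak0001"] = (
        acc_agg.loc["peakProm1"] + 0.1 * rng.standard_normal(len(groups))
    )
    p2g = linking.correlate_links(
        acc_agg, acc_meta, expr_agg, gene_feats, mode="peak2gene"
    )
    coacc = linking.correlate_links(
        acc_agg, acc_meta, acc_agg, acc_meta, mode="coaccessibility"
    )
    promoters = io_features.annotate_promoters(gene_feats)
    prom_class, prom_pairs = io_features.classify_promoter_peaks(acc_meta, promoters)
    lcres = linking.lcre_assemble(p2g, coacc, prom_class, prom_pairs)
    pairs = set(map(tuple, lcres[["gene", "peak"]].to_numpy()))
    metrics["lcre_enhancer_recovered"] = float(("gene0000", "peak0000") in pairs)
    metrics["lcre_coaccessible_recovered"] = float(("gene0001", "peak0001") in pairs)

    # --- master/dependent architecture
    dep_variant = center_ids[n_blocks // 2]
    dep_fm, dep_truth = simulate_dependency_architecture(
        genotypes, dep_variant, coupling_signs=(1, 1, -1),
        config=SimulationConfig(n_samples=n_samples, seed=seed, noise_sd=0.3),
    )
    g = genotypes.dosages[dep_variant].fillna(genotypes.dosages[dep_variant].mean())
    beta_m, _, _ = qtl.ols_scan(
        dep_fm.values.loc["master"].to_numpy(), g.to_numpy()[:, None]
    )
    call = pd.DataFrame(
        [{"variant": dep_variant, "feature": "master", "beta": beta_m[0]}]
    )
    dep_rec = masterdep.scan_dependents(call, dep_fm, genotypes)
    found = set(dep_rec["dependent"])
    planted_deps = set(dep_truth.query("role == 'dependent'")["entity"])
    metrics["masterdep_edge_recall"] = float(
        np.mean([d in found for d in planted_deps])
    )
    metrics["masterdep_spurious"] = len(found - planted_deps)
    # LD decoy: a dependent whose own resident caQTL is in perfect LD
    # with the tested variant must be filtered
    from .simulate import add_duplicate_variant

    gm_decoy = add_duplicate_variant(genotypes, dep_variant, "var_decoy")
    filtered = masterdep.confound_filter(
        dep_rec, {"dep0": ["var_decoy"]}, gm_decoy
    )
    metrics["masterdep_decoy_removed"] = float("dep0" not in set(filtered["dependent"]))
    metrics["masterdep_same_direction"] = masterdep.dependency_summary(dep_rec)[
        "same_direction_fraction"
    ]

    # --- motif perturbation at a planted site
    # 8-mer with one highly informative position (motif position 4, 'T');
    # the variant breaks that base, so the allele difference is dominated
    # by the informative position's score range
    consensus = "TAGGTGCC"
    base_to_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = np.full((8, 4), 0.2)
    probs[np.arange(8), [base_to_idx[b] for b in consensus]] = 0.4
    probs[4] = [0.01, 0.01, 0.01, 0.97]
    pwm = motif.Pwm.from_probabilities("TF1", probs)
    alt_win = "AAA" + consensus + "AAAA"           # intact consensus
    ref_win = alt_win[:7] + "C" + alt_win[8:]      # informative base broken
    hits = motif.variant_motif_effect(ref_win, alt_win, [pwm])
    metrics["motif_strong_detected"] = float((hits["effect"] == "strong").any())
    tf_expr = pd.DataFrame(
        {
            "Rod": 120 + 20 * rng.standard_normal(10),
            "Cone": 55 + 10 * rng.standard_normal(10),
        },
        index=[f"TF{i}" for i in range(10)],
    ).clip(lower=1.0)
    strong = pd.DataFrame({"tf": tf_expr.index})
    _, p_ctx = motif.tf_context_test(strong, tf_expr, "Rod", "Cone")
    metrics["tf_context_p"] = p_ctx

    # --- MPRA
    activities = {f"e{k}": a for k, a in enumerate([2.0] * 5 + [0.0] * 5 + [-2.0] * 5)}
    mpra_counts, mpra_truth = simulate_mpra(activities, config)
    act = mpra.score_elements(mpra_counts)
    classes = mpra.classify_elements(act)
    expected = {f"e{k}": c for k, c in enumerate(
        ["enhancer"] * 5 + ["inactive"] * 5 + ["silencer"] * 5
    )}
    metrics["mpra_accuracy"] = float(
        np.mean([classes[e] == c for e, c in expected.items()])
    )

    # --- GWAS fine-mapping + colocalization on the LD blocks
    block_results = []
    covered = 0
    fn_ge_unif = 0
    for b in range(10):
        sub = genotypes.subset_variants(
            genotypes.variants.index[b * block_size:(b + 1) * block_size]
        )
        causal = sub.variants.index[block_size // 2]
        ann = {causal: 2}
        gsum, _, gtruth = simulate_gwas_block(
            sub, causal, config, z_causal=6.0, annotations=ann,
            block_id=f"block{b}",
        )
        labf = pd.Series(
            gwas.wakefield_abf(gsum["beta"], gsum["se"]),
            index=pd.Index(gsum["variant_id"]),
        )
        cats = gtruth.set_index("entity")["category"]
        block_results.append((labf, cats, causal))
    enr = gwas.estimate_annotation_enrichment(
        [(l.to_numpy(), c.to_numpy()) for l, c, _ in block_results]
    )
    metrics["gwas_alpha_lcre"] = float(enr.alpha[2])
    for labf, cats, causal in block_results:
        prior = gwas.category_priors(cats, enr.alpha)
        fm_res = gwas.finemap_block(labf, prior)
        if causal in fm_res.credible_set:
            covered += 1
        i = list(fm_res.variants).index(causal)
        if fm_res.pip[i] >= fm_res.pip_uniform[i]:
            fn_ge_unif += 1
    metrics["finemap_coverage"] = covered / len(block_results)
    metrics["finemap_functional_ge_uniform"] = fn_ge_unif / len(block_results)

    # span two LD blocks so a low-LD partner exists for the distinct mode
    sub = genotypes.subset_variants(genotypes.variants.index[:2 * block_size])
    causal = sub.variants.index[block_size // 2]
    gshare, qshare, _ = simulate_gwas_block(
        sub, causal, config, z_causal=8.0, paired_qtl="shared", block_id="coloc_s"
    )
    res_s = gwas.coloc_abf(gshare.rename(columns={"variant_id": "variant_id"}), qshare)
    gdist, qdist, _ = simulate_gwas_block(
        sub, causal, config, z_causal=8.0, paired_qtl="distinct", block_id="coloc_d"
    )
    res_d = gwas.coloc_abf(gdist, qdist)
    metrics["coloc_pp4_shared"] = res_s["PP4"]
    metrics["coloc_pp3_distinct"] = res_d["PP3"]

    return metrics


def qtl_recovery_study(
    seed: int = 0,
    n_genes: int = 200,
    n_samples: int = 20,
    block_size: int = 10,
    planted_fraction: float = 0.1,
    slope: float = 3.0,
    fdr: float = 0.10,
    use_covariates: bool = False,
) -> dict:
    """Planted cis-eQTL recovery at study scale.

    No hidden confounding is simulated here, so the association model is
    run without hidden-factor covariates; covariate handling is
    exercised separately with an explicitly planted confounder.

    One LD block of ``block_size`` variants per gene (the gene's TSS at
    the block center, so the 250 kb window selects its own block);
    ``planted_fraction`` of genes receive a cis effect on the block
    center variant with per-allele ``slope`` (noise sd 1, so the effect
    explains at least half of the phenotypic variance across the MAF
    range).  Returns recall of planted genes and the false-discovery
    proportion at study FDR 0.10.
    """
    config = SimulationConfig(n_samples=n_samples, seed=seed, noise_sd=1.0)
    genotypes = simulate_genotypes(
        config, n_variants=n_genes * block_size, spacing_bp=50_000,
    )
    centers = _block_center_variants(n_genes, block_size)
    center_ids = [genotypes.variants.index[i] for i in centers]
    gene_feats = _make_features(genotypes, centers, 1000, "gene")

    n_planted = int(round(planted_fraction * n_genes))
    rng = config.rng("qtl_recovery:assignment")
    planted_genes = sorted(rng.choice(n_genes, size=n_planted, replace=False))
    effects = [
        PlantedEffect(f"gene{k:04d}", center_ids[k], "Rod", slope)
        for k in planted_genes
    ]
    expr, truth = simulate_pseudobulk(
        genotypes, effects, config, ("Rod",), features=gene_feats,
    )
    universe = io_features.build_test_universe(
        genotypes, gene_feats, ocrs=None, mode="window"
    )
    fm = io_features.normalize_transform(expr["Rod"], "int")
    cov = qtl.default_covariates(fm, genotypes) if use_covariates else None
    _, corr = qtl.map_qtl_eigen_bh(fm, genotypes, universe, cov, fdr)
    called = set(corr.index[corr["significant"]])
    planted_set = set(truth.query("is_causal")["entity"])
    recall = float(np.mean([g in called for g in planted_set]))
    n_false = len(called - planted_set)
    return {
        "recall": recall,
        "fdp": n_false / max(1, len(called)),
        "n_called": len(called),
    }


def _asca_genotypes(n_variants: int, n_het: int, n_hom: int = 5):
    """Genotype matrix with a fixed number of heterozygotes per variant."""
    from .types import GenotypeMatrix

    samples = [f"S{i:02d}" for i in range(n_het + n_hom)]
    ids = [f"v{i:05d}" for i in range(n_variants)]
    dos = np.zeros((len(samples), n_variants))
    dos[:n_het, :] = 1.0
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": 1000 * (np.arange(n_variants) + 1),
         "ref": "A", "alt": "G"},
        index=pd.Index(ids, name="variant"),
    )
    return GenotypeMatrix(variants, pd.DataFrame(dos, index=samples, columns=ids))


def asca_study(
    seed: int = 0,
    n_variants: int = 10_000,
    n_het: int = 5,
    depth: float = 50.0,
    planted_fraction: float = 0.0,
    planted_frac_alt: float = 0.7,
    fdr: float = 0.10,
) -> dict:
    """Null calibration / power of the ASCA caller at study scale.

    Every variant has exactly ``n_het`` heterozygotes sequenced at
    ``depth`` reads per source; a ``planted_fraction`` of variants carry
    an ATAC alternative-allele fraction of ``planted_frac_alt`` (the
    rest are balanced at 0.5).  Returns the number of calls, recall of
    planted variants and the fraction of planted calls in the planted
    direction.
    """
    genotypes = _asca_genotypes(n_variants, n_het)
    config = SimulationConfig(
        n_samples=n_het + 5, seed=seed, wgs_depth=depth, atac_depth=depth,
    )
    n_planted = int(round(planted_fraction * n_variants))
    imbalance = {
        vid: (planted_frac_alt if i < n_planted else 0.5)
        for i, vid in enumerate(genotypes.variants.index)
    }
    counts, truth = simulate_allelic_counts(genotypes, imbalance, config)
    res = allelic.asca_call(counts, genotypes, fdr=fdr)
    called = set(res.loc[res["significant"], "variant"])
    out = {"n_calls": len(called)}
    planted = set(truth.loc[truth["is_causal"], "entity"])
    if planted:
        out["recall"] = float(np.mean([v in called for v in planted]))
        hits = res[res["significant"] & res["variant"].isin(planted)]
        expected_dir = "greater" if planted_frac_alt > 0.5 else "less"
        out["direction_agreement"] = (
            float(np.mean(hits["direction"] == expected_dir)) if len(hits) else np.nan
        )
        out["n_false"] = len(called - planted)
    return out


def enrichment_recovery_study(
    seed: int = 0,
    n_blocks: int = 50,
    block_size: int = 20,
    alpha_true: float = 2.0,
    cat_fraction: float = 0.2,
    category: int = 2,
    z_causal: float = 6.0,
    ld_decay: float = 0.3,
) -> float:
    """Recover a planted annotation log-enrichment coefficient.

    A ``cat_fraction`` of variants per block carry the annotation
    ``category``; the causal variant of each block is drawn with prior
    weight exp(alpha_true) for annotated variants (1 otherwise).  The
    EM estimate of alpha for that category is returned.  Mild LD is
    used by default so the causal variant is statistically identifiable
    within its block; under strong LD the posterior spreads over LD
    partners and the coefficient is attenuated toward zero.
    """
    config = SimulationConfig(seed=seed, ld_decay=ld_decay)
    genotypes = simulate_genotypes(
        config, n_variants=n_blocks * block_size, spacing_bp=1000,
    )
    rng = config.rng("enrichment_study")
    blocks = []
    for b in range(n_blocks):
        sub = genotypes.subset_variants(
            genotypes.variants.index[b * block_size:(b + 1) * block_size]
        )
        cats = (rng.random(block_size) < cat_fraction).astype(int) * category
        w = np.exp(alpha_true * (cats == category))
        causal_i = rng.choice(block_size, p=w / w.sum())
        gsum, _, _ = simulate_gwas_block(
            sub, sub.variants.index[causal_i], config, z_causal=z_causal,
            block_id=f"b{b}",
        )
        labf = gwas.wakefield_abf(gsum["beta"].to_numpy(), gsum["se"].to_numpy())
        blocks.append((labf, cats))
    res = gwas.estimate_annotation_enrichment(blocks)
    return float(res.alpha[category])
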