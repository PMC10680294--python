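"""Allele-specific chromatin accessibility (ASCA) and expression (ASE).

The ASCA statistic compares, within each heterozygous sample, the
alternative-allele fraction of ATAC reads against the WGS read fraction
at the same site with a one-sided Fisher exact test, then combines the
per-sample p-values across heterozygotes with a read-weighted Stouffer
meta-analysis.  Both directions are tested and the more significant one
kept; BH is applied per cell type.  The ASE estimator tests per-
heterozygote haplotype log-ratios with a Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "asca_sample_test",
    "asca_meta",
    "asca_call",
    "ase_effect_test",
    "qtl_allelic_concordance",
]

P_CLIP_LO = 1e-300
P_CLIP_HI = 1.0 - 1e-16


def _het_mask(genotypes: GenotypeMatrix, variants, samples) -> np.ndarray:
    """Vectorized heterozygosity lookup for (variant, sample) pairs."""
    stacked = genotypes.dosages.stack()
    idx = pd.MultiIndex.from_arrays([np.asarray(samples), np.asarray(variants)])
    return stacked.reindex(idx).to_numpy() == 1


def asca_sample_test(
    wgs_ref, wgs_alt, atac_ref, atac_alt, direction: str = "greater"
):
    """One-sided Fisher exact p for ATAC vs WGS allelic ratios.

    The 2x2 table is [[atac_alt, atac_ref], [wgs_alt, wgs_ref]];
    ``greater`` tests whether the ATAC alt fraction exceeds the WGS alt
    fraction.  Conditional on the margins the table count is
    hypergeometric, so the one-sided Fisher p equals its tail
    probability; the computation is vectorized over arrays of tables.
    """
    aa = np.asarray(atac_alt, dtype=np.int64)
    ar = np.asarray(atac_ref, dtype=np.int64)
    wa = np.asarray(wgs_alt, dtype=np.int64)
    wr = np.asarray(wgs_ref, dtype=np.int64)
    if (aa < 0).any() or (ar < 0).any() or (wa < 0).any() or (wr < 0).any():
        raise ValueError("counts must be non-negative")
    total = aa + ar + wa + wr
    n_alt = aa + wa
    n_atac = aa + ar
    if direction == "greater":
        p = stats.hypergeom.sf(aa - 1, total, n_alt, n_atac)
    elif direction == "less":
        p = stats.hypergeom.cdf(aa, total, n_alt, n_atac)
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    p = np.where(total == 0, 1.0, p)  # an empty table carries no evidence
    return p if p.ndim else float(p)


def asca_meta(p_values, weights) -> float:
    """Read-weighted Stouffer combination of one-direction p-values.

    Z_i = Phi^{-1}(1 - p_i), Z = sum(w_i Z_i) / sqrt(sum w_i²),
    meta p = 1 - Phi(Z).  Weights are the per-sample total read counts
    (WGS + ATAC); the result is invariant to rescaling them.
    """
    p = np.clip(np.asarray(p_values, dtype=float), P_CLIP_LO, P_CLIP_HI)
    w = np.asarray(weights, dtype=float)
    if p.size == 0:
        raise ValueError("at least one sample required")
    if not (w > 0).any():
        raise ValueError("all-zero weights")
    z = stats.norm.isf(p)
    Z = (w * z).sum() / np.sqrt((w * w).sum())
    return float(np.clip(stats.norm.sf(Z), P_CLIP_LO, 1.0))


def asca_call(
    counts: pd.DataFrame,
    genotypes: GenotypeMatrix,
    universe_variants: set[str] | None = None,
    min_reads: int = 10,
    min_het: int = 3,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Call allele-specific chromatin accessibility per variant/cell type.

    ``counts`` holds (variant, sample, cell_type, source, ref_count,
    alt_count) records for WGS and ATAC.  Per variant, heterozygous
    samples with >= ``min_reads`` in both sources are tested in both
    directions; the per-sample Fisher p's are combined with the
    read-weighted Stouffer meta and the more significant direction is
    kept.  Variants with fewer than ``min_het`` qualifying heterozygotes
    (or outside the tested-variant universe) are excluded.  BH across
    variants per cell type; significance at FDR <= ``fdr``.  The effect
    size is the read-weighted mean over heterozygotes of (ATAC alt
    fraction - WGS alt fraction).
    """
    wide = counts.pivot_table(
        index=["variant", "sample", "cell_type"],
        columns="source",
        values=["ref_count", "alt_count"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b.lower()}" for a, b in wide.columns]
    wide = wide.reset_index()
    req = ["alt_count_atac", "ref_count_atac", "alt_count_wgs", "ref_count_wgs"]
    wide = wide.dropna(subset=req)
    for c in req:
        wide[c] = wide[c].astype(np.int64)

    wide = wide[_het_mask(genotypes, wide["variant"], wide["sample"])]
    wide = wide.copy()
    wide["wgs_total"] = wide["alt_count_wgs"] + wide["ref_count_wgs"]
    wide["atac_total"] = wide["alt_count_atac"] + wide["ref_count_atac"]
    wide = wide[(wide["wgs_total"] >= min_reads) & (wide["atac_total"] >= min_reads)]
    if universe_variants is not None:
        wide = wide[wide["variant"].isin(universe_variants)]

    wide = wide.copy()
    wide["p_greater"] = asca_sample_test(
        wide["ref_count_wgs"], wide["alt_count_wgs"],
        wide["ref_count_atac"], wide["alt_count_atac"], "greater",
    )
    wide["p_less"] = asca_sample_test(
        wide["ref_count_wgs"], wide["alt_count_wgs"],
        wide["ref_count_atac"], wide["alt_count_atac"], "less",
    )
    wide["weight"] = wide["wgs_total"] + wide["atac_total"]
    wide["d_frac"] = (
        wide["alt_count_atac"] / wide["atac_total"]
        - wide["alt_count_wgs"] / wide["wgs_total"]
    )

    # read-weighted Stouffer per (variant, cell type), vectorized over
    # groups; identical to asca_meta applied group by group
    w = wide["weight"].to_numpy(dtype=float)
    z_g = stats.norm.isf(np.clip(wide["p_greater"], P_CLIP_LO, P_CLIP_HI))
    z_l = stats.norm.isf(np.clip(wide["p_less"], P_CLIP_LO, P_CLIP_HI))
    agg = pd.DataFrame({
        "variant": wide["variant"].to_numpy(),
        "cell_type": wide["cell_type"].to_numpy(),
        "wz_g": w * z_g,
        "wz_l": w * z_l,
        "w2": w * w,
        "w": w,
        "wd": w * wide["d_frac"].to_numpy(),
    }).groupby(["variant", "cell_type"], sort=True).agg(
        wz_g=("wz_g", "sum"), wz_l=("wz_l", "sum"), w2=("w2", "sum"),
        w=("w", "sum"), wd=("wd", "sum"), n_het=("w", "size"),
    )
    n_excluded = int((agg["n_het"] < min_het).sum())
    if n_excluded:
        log.info("excluded %d variant/cell-type groups below filters", n_excluded)
    agg = agg[agg["n_het"] >= min_het]
    sqrt_w2 = np.sqrt(agg["w2"].to_numpy())
    p_g = np.clip(stats.norm.sf(agg["wz_g"].to_numpy() / sqrt_w2), P_CLIP_LO, 1.0)
    p_l = np.clip(stats.norm.sf(agg["wz_l"].to_numpy() / sqrt_w2), P_CLIP_LO, 1.0)
    greater = p_g <= p_l
    out = pd.DataFrame({
        "variant": agg.index.get_level_values(0),
        "cell_type": agg.index.get_level_values(1),
        "direction": np.where(greater, "greater", "less"),
        "meta_p": np.where(greater, p_g, p_l),
        "effect_size": agg["wd"].to_numpy() / agg["w"].to_numpy(),
        "n_het": agg["n_het"].to_numpy(),
    })
    if out.empty:
        return pd.DataFrame(
            columns=["variant", "cell_type", "direction", "meta_p",
                     "effect_size", "n_het", "q", "significant"]
        )
    out["q"] = np.nan
    for ct, grp in out.groupby("cell_type"):
        _, q, _, _ = multipletests(grp["meta_p"], method="fdr_bh")
        out.loc[grp.index, "q"] = q
    out["significant"] = out["q"] <= fdr
    return out.reset_index(drop=True)


def ase_effect_test(
    hap_expr: pd.DataFrame,
    genotypes: GenotypeMatrix,
    min_het: int = 4,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Haplotype-based allele-specific expression per variant-gene pair.

    ``hap_expr`` holds (gene, variant, sample, ref_hap, alt_hap)
    haplotype read counts.  For each pair with >= ``min_het``
    heterozygotes: effect = mean log2((alt+1)/(ref+1)) / 2 (halved so it
    compares to a per-allele slope); p from a two-sided Wilcoxon
    signed-rank test of per-het log-ratios against 0; BH across pairs
    (per cell type when a ``cell_type`` column is present).
    """
    df = hap_expr.copy()
    df = df[_het_mask(genotypes, df["variant"], df["sample"])]
    group_cols = ["gene", "variant"]
    if "cell_type" in df.columns:
        group_cols.append("cell_type")
    rows = []
    for key, grp in df.groupby(group_cols, sort=True):
        if len(grp) < min_het:
            continue
        lr = np.log2((grp["alt_hap"] + 1.0) / (grp["ref_hap"] + 1.0))
        effect = float(lr.mean() / 2.0)
        nz = lr[lr != 0]
        if len(nz) == 0:
            p = 1.0
        else:
            p = float(stats.wilcoxon(nz, alternative="two-sided").pvalue)
        rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        rec.update({"effect_size": effect, "p": p, "n_het": len(grp)})
        rows.append(rec)
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=group_cols + ["effect_size", "p", "n_het",
                                                  "q", "significant"])
    out["q"] = np.nan
    if "cell_type" in out.columns:
        for ct, grp in out.groupby("cell_type"):
            _, q, _, _ = multipletests(grp["p"], method="fdr_bh")
            out.loc[grp.index, "q"] = q
    else:
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
    out["significant"] = out["q"] <= fdr
    return out.reset_index(drop=True)


def qtl_allelic_concordance(
    qtl_calls: pd.DataFrame, allelic_calls: pd.DataFrame,
    keys: tuple[str, ...] = ("variant", "cell_type"),
) -> dict:
    """Overlap, effect correlation and direction concordance of QTL vs
    allelic calls keyed by (variant, cell type).

    ``qtl_calls`` must carry a ``beta`` column, ``allelic_calls`` an
    ``effect_size`` column.  The Pearson r is reported as NaN when fewer
    than 3 overlapped pairs exist.
    """
    merged = qtl_calls.merge(allelic_calls, on=list(keys), suffixes=("_qtl", "_al"))
    n_overlap = len(merged)
    denom = max(1, min(len(qtl_calls), len(allelic_calls)))
    out = {
        "n_overlap": n_overlap,
        "overlap_fraction": n_overlap / denom,
        "pearson_r": np.nan,
        "direction_concordance": np.nan,
    }
    if n_overlap:
        same = np.sign(merged["beta"]) == np.sign(merged["effect_size"])
        out["direction_concordance"] = float(same.mean())
        if n_overlap >= 3:
            out["pearson_r"] = float(
                np.corrcoef(merged["beta"], merged["effect_size"])[0, 1]
            )
    return out
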