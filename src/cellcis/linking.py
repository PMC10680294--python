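"""Linked cis-regulatory element (LCRE) identification.

Two link channels feed the LCRE set: peak-to-gene correlation (OCR
accessibility vs gene expression across pseudobulk groups) and peak
co-accessibility with a gene's promoter peak.  A gene's LCREs are the
union of non-promoter peaks linked by either channel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["correlate_links", "lcre_assemble"]

DEFAULTS = {
    "peak2gene": {"r_min": 0.45, "fdr_max": 1e-4},
    "coaccessibility": {"r_min": 0.2, "fdr_max": 0.05},
}


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation matrix between two value tables."""
    def standardize(X):
        Xc = X - X.mean(axis=1, keepdims=True)
        sd = Xc.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return Xc / sd
    Za, Zb = standardize(A), standardize(B)
    return (Za @ Zb.T) / A.shape[1]


def correlate_links(
    peak_values: pd.DataFrame,
    peak_meta: pd.DataFrame,
    target_values: pd.DataFrame,
    target_meta: pd.DataFrame,
    mode: str = "peak2gene",
    window_kb: float = 250.0,
    r_min: float | None = None,
    fdr_max: float | None = None,
    binarize: bool = False,
) -> pd.DataFrame:
    """Correlation links between peaks and targets within the cis window.

    Rows of ``peak_values`` / ``target_values`` are features, columns
    are matched aggregate groups (sample x cell-type pseudobulk).  The
    candidate set is every (peak, target) pair on the same chromosome
    with anchors within ``window_kb``; for co-accessibility the target
    set is the peak set itself and self-pairs are skipped.  Pearson r
    across groups, p from the t-distribution with n-2 df, BH per mode,
    and a link is kept iff r >= r_min and q <= fdr_max.
    """
    if mode not in DEFAULTS:
        raise ValueError("mode must be 'peak2gene' or 'coaccessibility'")
    if list(peak_values.columns) != list(target_values.columns):
        raise ValueError("aggregate columns must match")
    n = peak_values.shape[1]
    if n < 3:
        raise ValueError("at least 3 aggregate columns required")
    r_min = DEFAULTS[mode]["r_min"] if r_min is None else r_min
    fdr_max = DEFAULTS[mode]["fdr_max"] if fdr_max is None else fdr_max

    P = peak_values.to_numpy(dtype=float)
    T = target_values.to_numpy(dtype=float)
    if binarize:
        P = (P > 0).astype(float)
        if mode == "coaccessibility":
            T = (T > 0).astype(float)
    R = _pearson_matrix(P, T)

    window = window_kb * 1000.0
    pa = peak_meta.loc[peak_values.index, "anchor"].to_numpy()
    pc = peak_meta.loc[peak_values.index, "chrom"].to_numpy()
    ta = target_meta.loc[target_values.index, "anchor"].to_numpy()
    tc = target_meta.loc[target_values.index, "chrom"].to_numpy()
    cand = (pc[:, None] == tc[None, :]) & (
        np.abs(pa[:, None] - ta[None, :]) <= window
    )
    if mode == "coaccessibility":
        same = np.asarray(peak_values.index)[:, None] == np.asarray(
            target_values.index
        )[None, :]
        cand &= ~same

    ii, jj = np.nonzero(cand)
    r = R[ii, jj]
    valid = np.isfinite(r)
    if (~valid).any():
        log.warning("skipped %d pairs with zero-variance columns", (~valid).sum())
    ii, jj, r = ii[valid], jj[valid], r[valid]
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    out = pd.DataFrame({
        "peak": peak_values.index[ii],
        "target": target_values.index[jj],
        "r": r,
        "p": p,
        "link_type": mode,
    })
    if out.empty:
        out["q"] = []
        out["linked"] = []
        return out
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    out["linked"] = (out["r"] >= r_min) & (out["q"] <= fdr_max)
    return out[out["linked"]].drop(columns="linked").reset_index(drop=True)


def lcre_assemble(
    peak2gene: pd.DataFrame,
    coaccessibility: pd.DataFrame,
    promoter_class: pd.Series,
    promoter_pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble each gene's LCRE set from the two link channels.

    A gene's LCREs are the non-promoter peaks directly correlated with
    the gene (peak2gene channel) plus the non-promoter peaks
    co-accessible with any promoter peak of the gene; duplicates are
    merged with combined evidence.  ``promoter_pairs`` maps promoter-
    class peaks to the genes whose promoter they overlap.
    """
    prom_peaks_by_gene: dict[str, set[str]] = {}
    for _, row in promoter_pairs.iterrows():
        prom_peaks_by_gene.setdefault(row["gene"], set()).add(row["peak"])

    evidence: dict[tuple[str, str], set[str]] = {}
    for _, row in peak2gene.iterrows():
        if promoter_class.get(row["peak"], False):
            continue
        evidence.setdefault((row["target"], row["peak"]), set()).add("peak2gene")

    coacc_by_peak: dict[str, set[str]] = {}
    for _, row in coaccessibility.iterrows():
        coacc_by_peak.setdefault(row["target"], set()).add(row["peak"])
        coacc_by_peak.setdefault(row["peak"], set()).add(row["target"])

    genes = set(prom_peaks_by_gene) | {g for g, _ in evidence}
    for gene in sorted(genes):
        proms = prom_peaks_by_gene.get(gene, set())
        if not proms:
            log.info("gene %s has no promoter peak; co-accessibility channel empty", gene)
        for prom in proms:
            for peak in coacc_by_peak.get(prom, set()):
                if promoter_class.get(peak, False):
                    continue
                evidence.setdefault((gene, peak), set()).add("coaccessibility")

    rows = [
        {"gene": g, "peak": p, "evidence": frozenset(ev)}
        for (g, p), ev in sorted(evidence.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "peak", "evidence"])
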