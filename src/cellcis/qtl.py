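"""Cis association scans and multiple-testing control.

The association model is ordinary least squares of the transformed
phenotype on variant dosage plus covariates and an intercept, with a
two-sided p-value from the t statistic.  Feature-level correction is a
Bonferroni on the effective number of independent tests (eigenvalue
decomposition of the variant correlation matrix), followed by
Benjamini-Hochberg across features; alternatively an empirical FDR
threshold is derived from one permutation pass of the identical scan.
LD clumping reproduces the greedy plink procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .io_features import TestUniverse
from .types import FeatureMatrix, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ols_scan",
    "cis_nominal_scan",
    "effective_tests",
    "feature_and_study_correction",
    "permutation_fdr_threshold",
    "default_covariates",
    "map_qtl_eigen_bh",
    "map_qtl_permutation",
    "ld_clump",
    "cross_celltype_summary",
]

P_FLOOR = np.nextafter(0, 1)  # smallest positive float, reported for exact fits


# ---------------------------------------------------------------------------
# nominal scan
# ---------------------------------------------------------------------------

def _residual_projector(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of the covariate space (including intercept)."""
    q, _ = np.linalg.qr(C)
    return q


def ols_scan(
    y: np.ndarray, G: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant OLS of y on dosage + covariates + intercept.

    Uses the Frisch-Waugh projection: both phenotype and dosages are
    residualized against the covariate block, which gives slopes,
    standard errors and t p-values identical to the full regression with
    residual df = n - n_covariates - 2.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = len(y)
    C = np.ones((n, 1))
    if covariates is not None and covariates.size:
        C = np.column_stack([C, covariates])
    k = C.shape[1]
    df = n - k - 1
    if df < 1:
        raise ValueError("need at least 2 more samples than covariates + 2")
    Q = _residual_projector(C)
    ry = y - Q @ (Q.T @ y)
    rG = G - Q @ (Q.T @ G)
    gg = (rG * rG).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (rG * ry[:, None]).sum(axis=0) / gg
        rss = (ry * ry).sum() - beta**2 * gg
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / gg)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)  # exact fits report the smallest positive float
    p = np.where(gg > 0, p, np.nan)  # zero-variance dosage: undefined
    return beta, se, p


def cis_nominal_scan(
    fm: FeatureMatrix,
    genotypes: GenotypeMatrix,
    universe: TestUniverse,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Association records for every (feature, candidate variant) pair.

    Missing dosages are mean-imputed per variant; dosage columns with
    zero variance after imputation are dropped with a warning.
    """
    samples = fm.samples
    D = genotypes.dosages.loc[samples]
    D = D.fillna(D.mean())
    cov = None
    if covariates is not None:
        cov = covariates.loc[samples].to_numpy(dtype=float)
    rows = []
    for fid, cands in universe.items():
        if fid not in fm.values.index or not cands:
            continue
        G = D[cands].to_numpy()
        keep = G.std(axis=0) > 0
        if not keep.all():
            dropped = [c for c, k in zip(cands, keep) if not k]
            log.warning("dropping zero-variance dosages for %s: %s", fid, dropped)
        cands = [c for c, k in zip(cands, keep) if k]
        if not cands:
            continue
        y = fm.values.loc[fid].to_numpy(dtype=float)
        beta, se, p = ols_scan(y, G[:, keep], cov)
        for c, b, s, pv in zip(cands, beta, se, p):
            rows.append((fid, c, b, s, pv))
    out = pd.DataFrame(rows, columns=["feature", "variant", "beta", "se", "p"])
    out["cell_type"] = fm.cell_type
    return out


def default_covariates(
    fm: FeatureMatrix, genotypes: GenotypeMatrix, n_phenotype_pcs: int = 3
) -> pd.DataFrame:
    """Top phenotype principal components plus genotype PC1.

    Three phenotype PCs stand in for the hidden-confounder factors and
    the leading genotype PC for the ancestry axis, matching the four
    covariates used in the association model.
    """
    Y = fm.values.to_numpy(dtype=float)
    Yc = (Y - Y.mean(axis=1, keepdims=True))
    # samples x features SVD; columns of V are sample-space components
    _, _, vt = np.linalg.svd(Yc, full_matrices=False)
    pcs = vt[:n_phenotype_pcs].T
    D = genotypes.dosages.loc[fm.samples].fillna(genotypes.dosages.mean())
    Dc = D.to_numpy() - D.to_numpy().mean(axis=0, keepdims=True)
    _, _, vt_g = np.linalg.svd(Dc.T, full_matrices=False)
    gpc1 = vt_g[0]
    cols = {f"phenoPC{i+1}": pcs[:, i] for i in range(pcs.shape[1])}
    cols["genoPC1"] = gpc1
    return pd.DataFrame(cols, index=fm.samples)


# ---------------------------------------------------------------------------
# effective number of tests
# ---------------------------------------------------------------------------

def effective_tests(
    dosages: pd.DataFrame | np.ndarray,
    var_explained: float = 0.99,
    window: int = 200,
) -> int:
    """Effective number of independent variants in a candidate set.

    Eigenvalues of the variant-variant Pearson correlation matrix
    (pairwise-complete, zero-variance variants removed) are accumulated
    in descending order; M_eff is the smallest k whose eigenvalues reach
    ``var_explained`` of the total.  Sets larger than ``window`` are
    partitioned into consecutive windows and the window M_eff summed.
    """
    D = pd.DataFrame(dosages)
    D = D.loc[:, D.std(skipna=True) > 0]
    m = D.shape[1]
    if m == 0:
        return 1
    if m == 1:
        return 1
    if m > window:
        total = 0
        for i in range(0, m, window):
            total += effective_tests(D.iloc[:, i:i + window], var_explained, window)
        return total
    corr = D.corr().to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    eig = np.linalg.eigvalsh((corr + corr.T) / 2.0)[::-1]
    eig = np.clip(eig, 0.0, None)
    cum = np.cumsum(eig)
    k = int(np.searchsorted(cum, var_explained * cum[-1]) + 1)
    return min(k, m)


# ---------------------------------------------------------------------------
# feature- and study-level correction
# ---------------------------------------------------------------------------

def feature_and_study_correction(
    records: pd.DataFrame,
    m_eff: dict[str, int] | pd.Series,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Bonferroni on M_eff within feature, Benjamini-Hochberg across.

    p_feature = min(1, min nominal p x M_eff); features with BH q <=
    ``fdr`` are flagged significant.  The lead variant (smallest nominal
    p) is recorded per feature.
    """
    if records.empty:
        raise ValueError("no association records")
    m_eff = pd.Series(m_eff)
    rows = []
    for fid, grp in records.groupby("feature", sort=True):
        i = grp["p"].idxmin()
        p_min = grp.loc[i, "p"]
        m = int(grp["variant"].nunique())
        me = int(m_eff.get(fid, m))
        rows.append({
            "feature": fid, "m": m, "m_eff": me,
            "lead_variant": grp.loc[i, "variant"],
            "lead_beta": grp.loc[i, "beta"],
            "p_min": p_min,
            "p_feature": min(1.0, p_min * me),
        })
    out = pd.DataFrame(rows).set_index("feature")
    _, q, _, _ = multipletests(out["p_feature"], method="fdr_bh")
    out["q"] = q
    out["significant"] = out["q"] <= fdr
    return out


def permutation_fdr_threshold(
    true_p: np.ndarray, null_p: np.ndarray, fdr: float = 0.10
) -> tuple[float, np.ndarray]:
    """Empirical FDR threshold from permuted-label feature-level p's.

    t* is the largest observed true p such that
    (1 + #{null p <= t}) / max(1, #{true p <= t}) <= fdr; calls are the
    features with true p <= t* (none if no threshold qualifies).  The +1
    in the numerator is the standard conservative permutation-FDR
    estimator; without it a handful of features slip through on pure
    null data whenever the extreme order statistics happen to fall on
    the observed side.
    """
    true_p = np.asarray(true_p, dtype=float)
    null_p = np.asarray(null_p, dtype=float)
    if true_p.size == 0 or null_p.size == 0:
        raise ValueError("empty p-value inputs")
    null_sorted = np.sort(null_p)
    cand = np.sort(np.unique(true_p))
    n_true = np.searchsorted(np.sort(true_p), cand, side="right")
    n_null = np.searchsorted(null_sorted, cand, side="right")
    ok = (1 + n_null) / np.maximum(1, n_true) <= fdr
    if not ok.any():
        return 0.0, np.zeros_like(true_p, dtype=bool)
    t_star = cand[np.nonzero(ok)[0].max()]
    return float(t_star), true_p <= t_star


# ---------------------------------------------------------------------------
# high-level mapping drivers
# ---------------------------------------------------------------------------

def map_qtl_eigen_bh(
    fm: FeatureMatrix,
    genotypes: GenotypeMatrix,
    universe: TestUniverse,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nominal scan + eigen-Bonferroni + BH (the sc-eQTL scheme)."""
    records = cis_nominal_scan(fm, genotypes, universe, covariates)
    D = genotypes.dosages.loc[fm.samples]
    m_eff = {
        fid: effective_tests(D[cands])
        for fid, cands in universe.items() if cands and fid in fm.values.index
    }
    corr = feature_and_study_correction(records, m_eff, fdr)
    return records, corr


def map_qtl_permutation(
    fm: FeatureMatrix,
    genotypes: GenotypeMatrix,
    universe: TestUniverse,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.10,
    perm_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Nominal scan + eigen-Bonferroni + permutation empirical FDR.

    The identical scan is rerun once with sample labels permuted
    (seeded); feature-level Bonferroni p's of the true and permuted runs
    are compared to pick the p threshold controlling FDR at ``fdr``
    (the sc-caQTL scheme).
    """
    records = cis_nominal_scan(fm, genotypes, universe, covariates)
    D = genotypes.dosages.loc[fm.samples]
    m_eff = {
        fid: effective_tests(D[cands])
        for fid, cands in universe.items() if cands and fid in fm.values.index
    }
    rng = substream(perm_seed, "permutation_fdr")
    perm = rng.permutation(len(fm.samples))
    perm_values = pd.DataFrame(
        fm.values.to_numpy()[:, perm], index=fm.values.index, columns=fm.samples
    )
    perm_fm = fm.with_values(perm_values)
    null_records = cis_nominal_scan(perm_fm, genotypes, universe, covariates)
    corr = feature_and_study_correction(records, m_eff, fdr)
    null_corr = feature_and_study_correction(null_records, m_eff, fdr)
    t_star, calls = permutation_fdr_threshold(
        corr["p_feature"].to_numpy(), null_corr["p_feature"].to_numpy(), fdr
    )
    corr = corr.copy()
    corr["significant"] = calls
    return records, corr, t_star


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def ld_clump(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    anchor_pos: int,
    p1: float = 0.05,
    p2: float = 0.05,
    r2_min: float = 0.5,
    kb: float = 250.0,
) -> list[dict]:
    """Greedy plink-style clumping of one feature's associations.

    Repeatedly take the unassigned variant with the smallest p <= p1 as
    index and absorb unassigned variants with p <= p2 within ``kb`` of
    it and r² >= ``r2_min`` with it.  Ties on p are broken by distance
    to ``anchor_pos`` (gene TSS or peak summit, 0-based), then by the
    smaller coordinate.
    """
    recs = records.drop_duplicates("variant").set_index("variant")
    v = genotypes.variants
    pos0 = (v["pos"] - 1).to_dict()
    D = genotypes.dosages
    window = kb * 1000.0

    def order_key(vid):
        return (recs.loc[vid, "p"], abs(pos0[vid] - anchor_pos), pos0[vid])

    unassigned = set(recs.index)
    clumps = []
    while True:
        pool = [vid for vid in unassigned if recs.loc[vid, "p"] <= p1]
        if not pool:
            break
        index = min(pool, key=order_key)
        unassigned.discard(index)
        members = [index]
        gi = D[index]
        for vid in sorted(unassigned):
            if recs.loc[vid, "p"] > p2:
                continue
            if abs(pos0[vid] - pos0[index]) > window:
                continue
            r = gi.corr(D[vid])
            if np.isnan(r) or r * r < r2_min:
                continue
            members.append(vid)
        for vid in members[1:]:
            unassigned.discard(vid)
        clumps.append({"index": index, "members": members})
    return clumps


# ---------------------------------------------------------------------------
# cross-cell-type summaries
# ---------------------------------------------------------------------------

def cross_celltype_summary(
    calls: dict[str, set[str]],
    records: dict[str, pd.DataFrame],
    genotypes: GenotypeMatrix | None = None,
    r2_proxy: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-type specificity counts and effect-size correlation matrix.

    For each index QTL variant, count the cell types where it (or an
    r² > ``r2_proxy`` proxy) is called; correlate betas pairwise over
    the union of index QTLs tested in both cell types.
    """
    cts = sorted(records)
    if len(cts) < 2:
        raise ValueError("at least 2 cell types required")
    all_calls = sorted(set().union(*calls.values())) if calls else []
    D = genotypes.dosages if genotypes is not None else None

    def called_in(vid, ct):
        if vid in calls.get(ct, set()):
            return True
        if D is None or vid not in D.columns:
            return False
        for other in calls.get(ct, set()):
            if other in D.columns:
                r = D[vid].corr(D[other])
                if not np.isnan(r) and r * r > r2_proxy:
                    return True
        return False

    spec = pd.DataFrame(
        {
            "variant": all_calls,
            "n_cell_types": [
                sum(called_in(v, ct) for ct in cts) for v in all_calls
            ],
        }
    )

    beta_tables = {}
    for ct in cts:
        r = records[ct]
        idx = r.loc[r["variant"].isin(all_calls)]
        # per variant keep the strongest association's beta
        idx = idx.sort_values("p").drop_duplicates("variant")
        beta_tables[ct] = idx.set_index("variant")["beta"]
    corr = pd.DataFrame(np.eye(len(cts)), index=cts, columns=cts)
    for i, a in enumerate(cts):
        for b in cts[i + 1:]:
            common = beta_tables[a].index.intersection(beta_tables[b].index)
            if len(common) >= 3:
                r = np.corrcoef(beta_tables[a][common], beta_tables[b][common])[0, 1]
            else:
                r = np.nan
            corr.loc[a, b] = corr.loc[b, a] = r
    return spec, corr
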