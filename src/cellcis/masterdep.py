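"""Master/dependent peak detection for multi-region caQTLs.

A called caQTL variant's residing OCR is the master peak; every other
peak within 250 kb of the variant is scanned with the same linear model
used for caQTL mapping, and associations at nominal p < 0.005 define
dependent peaks.  Candidate dependents that are themselves master peaks
whose resident caQTL is in LD (r² > 0.5) with the tested variant are
removed as LD confounds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qtl import ols_scan
from .types import FeatureMatrix, GenotypeMatrix

__all__ = ["scan_dependents", "confound_filter", "dependency_summary"]


def scan_dependents(
    caqtl_calls: pd.DataFrame,
    accessibility: FeatureMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    window_kb: float = 250.0,
    p_sig: float = 0.005,
) -> pd.DataFrame:
    """Dependency records for each called caQTL variant.

    ``caqtl_calls`` needs columns ``variant``, ``feature`` (the residing
    master peak) and ``beta`` (the master effect).  Every other peak
    whose interval lies within ``window_kb`` of the variant is regressed
    on the variant dosage (same covariates as the caQTL model); records
    with nominal p < ``p_sig`` are kept.
    """
    feats = accessibility.features
    vals = accessibility.values
    samples = accessibility.samples
    D = genotypes.dosages.loc[samples]
    D = D.fillna(D.mean())
    cov = covariates.loc[samples].to_numpy(dtype=float) if covariates is not None else None
    window = window_kb * 1000.0

    rows = []
    for _, call in caqtl_calls.iterrows():
        vid, master = call["variant"], call["feature"]
        vpos0 = genotypes.variants.loc[vid, "pos"] - 1
        vchrom = genotypes.variants.loc[vid, "chrom"]
        g = D[vid].to_numpy()
        in_window = (
            (feats["chrom"] == vchrom)
            & (feats["anchor"] >= vpos0 - window)
            & (feats["anchor"] <= vpos0 + window)
            & (feats.index != master)
        )
        peaks = feats.index[in_window]
        if len(peaks) == 0:
            continue
        Y = vals.loc[peaks].to_numpy(dtype=float)
        for pid, y in zip(peaks, Y):
            beta, se, p = ols_scan(y, g[:, None], cov)
            if np.isnan(p[0]) or p[0] >= p_sig:
                continue
            rows.append({
                "variant": vid,
                "master": master,
                "dependent": pid,
                "beta_master": call["beta"],
                "beta_dependent": beta[0],
                "p_dependent": p[0],
                "same_direction": bool(np.sign(call["beta"]) == np.sign(beta[0])),
            })
    return pd.DataFrame(
        rows,
        columns=["variant", "master", "dependent", "beta_master",
                 "beta_dependent", "p_dependent", "same_direction"],
    )


def confound_filter(
    records: pd.DataFrame,
    resident_caqtls: dict[str, list[str]],
    genotypes: GenotypeMatrix,
    r2_max: float = 0.5,
) -> pd.DataFrame:
    """Drop dependents explained by their own resident caQTL in LD.

    A candidate dependent peak that is itself a master peak with a
    resident caQTL whose dosage r² with the tested variant exceeds
    ``r2_max`` is removed.  Pure subset operation; idempotent.
    """
    if records.empty:
        return records
    D = genotypes.dosages
    keep = []
    for _, rec in records.iterrows():
        residents = resident_caqtls.get(rec["dependent"], [])
        confounded = False
        for res in residents:
            if res not in D.columns or rec["variant"] not in D.columns:
                continue
            r = D[rec["variant"]].corr(D[res])
            if not np.isnan(r) and r * r > r2_max:
                confounded = True
                break
        keep.append(not confounded)
    return records[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def dependency_summary(
    records: pd.DataFrame,
    coaccessibility: pd.DataFrame | None = None,
    eqtl_variants: set[str] | None = None,
) -> dict:
    """Per-variant dependency counts and direction/co-accessibility rates.

    Reports the number of dependents per variant, the fraction of
    dependency edges with matching master/dependent effect signs, the
    fraction of masters co-accessible with at least one dependent
    (using the supplied significant co-accessibility links), and eQTL
    overlap rates stratified by same-direction vs mixed-direction
    multi-peak variants.
    """
    out: dict = {
        "n_variants": 0, "n_edges": 0, "same_direction_fraction": np.nan,
        "coaccessible_master_fraction": np.nan,
        "eqtl_overlap_same_direction": np.nan,
        "eqtl_overlap_mixed_direction": np.nan,
    }
    if records.empty:
        return out
    out["n_edges"] = len(records)
    out["n_variants"] = records["variant"].nunique()
    out["same_direction_fraction"] = float(records["same_direction"].mean())

    if coaccessibility is not None and not coaccessibility.empty:
        pairs = set(map(tuple, coaccessibility[["peak", "target"]].to_numpy()))
        pairs |= {(b, a) for a, b in pairs}
        frac = []
        for master, grp in records.groupby("master"):
            deps = grp["dependent"].unique()
            frac.append(any((master, d) in pairs for d in deps))
        out["coaccessible_master_fraction"] = float(np.mean(frac))

    if eqtl_variants is not None:
        per_var = records.groupby("variant")["same_direction"].agg(["all", "count"])
        same = per_var.index[per_var["all"]]
        mixed = per_var.index[~per_var["all"]]
        if len(same):
            out["eqtl_overlap_same_direction"] = float(
                np.mean([v in eqtl_variants for v in same])
            )
        if len(mixed):
            out["eqtl_overlap_mixed_direction"] = float(
                np.mean([v in eqtl_variants for v in mixed])
            )
    return out
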