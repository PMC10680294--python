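"""MPRA activity scoring and enhancer/silencer classification.

Element activity is the mean log2 RNA/DNA ratio over barcode-replicate
units, normalized to the basal promoter's mean ratio; significance is a
Welch t-test of element units against basal units with BH correction.
Elements at least twofold above (below) basal with q < 0.05 are called
enhancers (silencers); everything else is inactive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["score_elements", "classify_elements", "annotation_enrichment"]


def score_elements(
    counts: pd.DataFrame,
    basal_element: str = "basal",
    dna_min: int = 10,
    pseudocount: float = 0.5,
    replicate_mean: bool = False,
) -> pd.DataFrame:
    """Per-element log2 fold change vs the basal promoter, with p and q.

    Barcode-replicate units with DNA count below ``dna_min`` are
    dropped; the unit log-ratio is log2((rna + pc)/(dna + pc)).  With
    ``replicate_mean`` units are first averaged within replicate.
    Elements with no usable unit are reported with missing activity.
    """
    df = counts.copy()
    df = df[df["dna_count"] >= dna_min]
    df["log_ratio"] = np.log2(
        (df["rna_count"] + pseudocount) / (df["dna_count"] + pseudocount)
    )
    if replicate_mean:
        df = (
            df.groupby(["element", "replicate"], as_index=False)["log_ratio"]
            .mean()
        )
    basal = df.loc[df["element"] == basal_element, "log_ratio"].to_numpy()
    if len(basal) < 2:
        raise ValueError("basal element needs at least 2 usable units")
    basal_mean = basal.mean()

    rows = []
    all_elements = counts["element"].unique()
    for elem in all_elements:
        if elem == basal_element:
            continue
        units = df.loc[df["element"] == elem, "log_ratio"].to_numpy()
        if len(units) == 0:
            log.warning("element %s has no usable units; activity missing", elem)
            rows.append({"element": elem, "log2fc": np.nan, "p": np.nan,
                         "n_units": 0})
            continue
        log2fc = units.mean() - basal_mean
        if len(units) >= 2 and (units.std() > 0 or basal.std() > 0):
            p = float(stats.ttest_ind(units, basal, equal_var=False).pvalue)
        elif np.isclose(log2fc, 0.0):
            p = 1.0
        else:
            p = np.nan
        rows.append({"element": elem, "log2fc": float(log2fc), "p": p,
                     "n_units": len(units)})
    out = pd.DataFrame(rows).set_index("element")
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        _, q, _, _ = multipletests(out.loc[mask, "p"], method="fdr_bh")
        out.loc[mask, "q"] = q
    return out


def classify_elements(
    activity: pd.DataFrame, fold: float = 2.0, q_max: float = 0.05
) -> pd.Series:
    """Enhancer / silencer / inactive classes from activity and q.

    Enhancer: log2FC >= log2(fold) and q < q_max; silencer: log2FC <=
    -log2(fold) and q < q_max; otherwise (including q >= q_max at any
    fold change) inactive.
    """
    lfc_min = np.log2(fold)
    cls = pd.Series("inactive", index=activity.index, name="class")
    sig = activity["q"] < q_max
    cls[sig & (activity["log2fc"] >= lfc_min)] = "enhancer"
    cls[sig & (activity["log2fc"] <= -lfc_min)] = "silencer"
    cls[activity["log2fc"].isna()] = "missing"
    return cls


def annotation_enrichment(
    classes: pd.Series,
    annotations: dict[str, set[str]],
    target_class: str = "enhancer",
    background_class: str = "inactive",
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of annotations in a class vs background.

    For each annotation set, the 2x2 table is (class vs background) x
    (annotated vs not); fold is the ratio of annotated proportions.
    """
    target = classes.index[classes == target_class]
    background = classes.index[classes == background_class]
    rows = []
    for name, members in annotations.items():
        if len(target) == 0 or len(background) == 0:
            continue
        k_t = sum(e in members for e in target)
        k_b = sum(e in members for e in background)
        table = [[k_t, len(target) - k_t], [k_b, len(background) - k_b]]
        _, p = stats.fisher_exact(table, alternative=alternative)
        prop_t = k_t / len(target)
        prop_b = k_b / len(background)
        fold = prop_t / prop_b if prop_b > 0 else np.inf
        rows.append({
            "annotation": name, "class": target_class,
            "prop_class": prop_t, "prop_background": prop_b,
            "fold": fold, "p": float(p),
        })
    return pd.DataFrame(rows)
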