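"""Variant effects on transcription-factor binding motifs.

Sequences are scored against position weight matrices with log-odds
relative to a background base composition, min-max normalized to [0, 1].
A match passes at significance ``match_p`` when its raw score reaches
the background-distribution threshold, computed by discrete convolution
of the per-position score distributions.  A variant's motif effect is
the normalized-score difference between its alternative and reference
alleles over the match offsets covering the variant base; differences
of at least ``strong_diff`` are classed strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats

__all__ = [
    "Pwm",
    "read_jaspar",
    "score_threshold",
    "pwm_match",
    "variant_motif_effect",
    "tf_context_test",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class Pwm:
    """A position weight matrix: positions x 4 base probabilities (ACGT)."""

    name: str
    probs: tuple[tuple[float, ...], ...]
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        P = np.asarray(self.probs, dtype=float)
        if P.ndim != 2 or P.shape[1] != 4:
            raise ValueError("probs must be positions x 4")
        if P.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each position must sum to 1")

    @property
    def length(self) -> int:
        return len(self.probs)

    def log_odds(self) -> np.ndarray:
        """Log2 odds vs background, with a pseudocount against -inf."""
        P = np.asarray(self.probs, dtype=float) + self.pseudocount
        P = P / P.sum(axis=1, keepdims=True)
        bg = np.asarray(self.background, dtype=float)
        return np.log2(P / bg)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmin(self.log_odds(), axis=1))

    @classmethod
    def from_probabilities(cls, name: str, probs: np.ndarray, **kw) -> "Pwm":
        return cls(name, tuple(map(tuple, np.asarray(probs, dtype=float))), **kw)


def read_jaspar(path: str, background=None) -> list[Pwm]:
    """Read JASPAR-format PWMs (count matrices normalized per position)."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
        out = []
        for m in records:
            counts = np.array([[m.counts[b][i] for b in BASES]
                               for i in range(m.length)], dtype=float)
            probs = counts / counts.sum(axis=1, keepdims=True)
            kw = {"background": tuple(background)} if background else {}
            out.append(Pwm.from_probabilities(m.name or m.matrix_id, probs, **kw))
    return out


# ---------------------------------------------------------------------------
# background score distribution and match threshold
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _threshold_cached(pwm: Pwm, match_p: float, n_bins: int) -> float:
    lo = pwm.log_odds()
    bg = np.asarray(pwm.background, dtype=float)
    smin = lo.min(axis=1).sum()
    smax = lo.max(axis=1).sum()
    if smax <= smin:
        return smin
    w = (smax - smin) / n_bins
    # per-position integer bins (floor): rounded sum underestimates the
    # true score by at most L*w, compensated below
    pos_bins = np.floor((lo - lo.min(axis=1, keepdims=True)) / w).astype(int)
    dist = np.array([1.0])
    offset = 0.0
    for j in range(pwm.length):
        step = np.zeros(pos_bins[j].max() + 1)
        for b in range(4):
            step[pos_bins[j, b]] += bg[b]
        dist = np.convolve(dist, step)
        offset += lo[j].min()
    tail = np.cumsum(dist[::-1])[::-1]
    idx = np.searchsorted(-tail, -match_p, side="left")
    # idx == len(dist): even the maximal score is too probable under the
    # background; return a threshold no achievable score reaches
    t_r = offset + idx * w
    return float(t_r + pwm.length * w)


def score_threshold(pwm: Pwm, match_p: float = 1e-4, n_bins: int = 1000) -> float:
    """Raw log-odds threshold t with P(score >= t) <= match_p under the
    background, by exact discrete convolution of per-position score
    distributions (bin width = score range / ``n_bins``).

    Per-position scores are floored onto the bin grid and the resulting
    threshold shifted up by one bin per position, so the guarantee
    P(score >= t) <= match_p holds exactly; t exceeds the unrounded
    minimal threshold by at most ``length / n_bins`` of the score range.
    """
    return _threshold_cached(pwm, match_p, n_bins)


# ---------------------------------------------------------------------------
# sequence scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, -1) for c in seq.upper()], dtype=int)


def _scan(codes: np.ndarray, lo: np.ndarray, offsets) -> list[tuple[float, int, str]]:
    """Raw scores at the given offsets on both strands; skips N windows."""
    L = lo.shape[0]
    lo_rc = lo[::-1, ::-1]
    out = []
    for o in offsets:
        window = codes[o:o + L]
        if len(window) < L or (window < 0).any():
            continue
        out.append((float(lo[np.arange(L), window].sum()), o, "+"))
        out.append((float(lo_rc[np.arange(L), window].sum()), o, "-"))
    return out


def pwm_match(
    sequence: str, pwm: Pwm, match_p: float = 1e-4, n_bins: int = 1000
) -> dict:
    """Best match of ``pwm`` anywhere in ``sequence`` (both strands).

    Returns the best min-max-normalized score in [0, 1], its offset and
    strand, and whether the raw score passes the ``match_p`` threshold.
    """
    if len(sequence) < pwm.length:
        raise ValueError("motif longer than sequence window")
    lo = pwm.log_odds()
    smin = lo.min(axis=1).sum()
    smax = lo.max(axis=1).sum()
    codes = _encode(sequence)
    hits = _scan(codes, lo, range(len(sequence) - pwm.length + 1))
    if not hits:
        return {"score": np.nan, "offset": -1, "strand": ".", "passed": False}
    raw, offset, strand = max(hits)
    norm = (raw - smin) / (smax - smin) if smax > smin else 0.0
    return {
        "score": float(np.clip(norm, 0.0, 1.0)),
        "raw": raw,
        "offset": offset,
        "strand": strand,
        "passed": raw >= score_threshold(pwm, match_p, n_bins),
    }


def variant_motif_effect(
    ref_window: str,
    alt_window: str,
    pwms: list[Pwm],
    match_p: float = 1e-4,
    strong_diff: float = 0.4,
    n_bins: int = 1000,
    variant_id: str = "",
) -> pd.DataFrame:
    """Score a SNV's two alleles against each PWM (MotifHit records).

    The windows must be identical strings except at the center base
    (the variant); matches are restricted to offsets overlapping the
    center.  effect = 'none' if neither allele passes ``match_p``,
    'strong' if |alt - ref| normalized difference >= ``strong_diff``,
    else 'weak'.
    """
    if len(ref_window) != len(alt_window):
        raise ValueError("only SNVs supported (windows of equal length)")
    if len(ref_window) % 2 != 1:
        raise ValueError("windows must have odd length centered on the variant")
    center = len(ref_window) // 2
    diffs = [i for i, (a, b) in enumerate(zip(ref_window, alt_window)) if a != b]
    if diffs not in ([center], []):
        raise ValueError("windows must differ only at the center base")

    rows = []
    for pwm in pwms:
        L = pwm.length
        if len(ref_window) < 2 * L - 1:
            raise ValueError(
                f"window too short for {pwm.name}: needs motif length - 1 each side"
            )
        lo = pwm.log_odds()
        smin = lo.min(axis=1).sum()
        smax = lo.max(axis=1).sum()
        thr = score_threshold(pwm, match_p, n_bins)
        offsets = [o for o in range(len(ref_window) - L + 1) if o <= center < o + L]

        def best(seq):
            hits = _scan(_encode(seq), lo, offsets)
            if not hits:
                return np.nan, False
            raw = max(hits)[0]
            norm = (raw - smin) / (smax - smin) if smax > smin else 0.0
            return float(np.clip(norm, 0.0, 1.0)), raw >= thr

        ref_score, ref_pass = best(ref_window)
        alt_score, alt_pass = best(alt_window)
        if not (ref_pass or alt_pass):
            effect = "none"
        else:
            diff = alt_score - ref_score
            effect = "strong" if abs(diff) >= strong_diff else "weak"
        rows.append({
            "variant": variant_id,
            "tf": pwm.name,
            "ref_score": ref_score,
            "alt_score": alt_score,
            "allele_diff": alt_score - ref_score,
            "effect": effect,
            "passed_ref": ref_pass,
            "passed_alt": alt_pass,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cell-type-context TF expression test
# ---------------------------------------------------------------------------

def tf_context_test(
    strong_hits: pd.DataFrame,
    tf_expression: pd.DataFrame,
    cell_type_a: str,
    cell_type_b: str,
    cpm_min: float = 50.0,
) -> tuple[pd.DataFrame, float]:
    """Are motif-perturbing TFs more expressed where the QTL acts?

    ``strong_hits`` lists TFs with strong motif perturbations at QTLs
    specific to cell type A (column ``tf``); ``tf_expression`` is
    TF x cell-type CPM.  TFs with CPM >= ``cpm_min`` in A or B enter a
    one-sided Wilcoxon rank-sum test of expression in A vs B
    (alternative: A > B).  With fewer than 3 eligible TFs the p-value is
    reported missing.
    """
    tfs = sorted(set(strong_hits["tf"]) & set(tf_expression.index))
    expr = tf_expression.loc[tfs]
    eligible = expr[(expr[cell_type_a] >= cpm_min) | (expr[cell_type_b] >= cpm_min)]
    table = pd.DataFrame({
        "tf": eligible.index,
        "expr_a": eligible[cell_type_a].to_numpy(),
        "expr_b": eligible[cell_type_b].to_numpy(),
    }).reset_index(drop=True)
    if len(table) < 3:
        return table, np.nan
    res = stats.mannwhitneyu(
        table["expr_a"], table["expr_b"], alternative="greater",
        use_continuity=False, method="asymptotic",
    )
    return table, float(res.pvalue)
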