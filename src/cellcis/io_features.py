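"""Readers/writers, pseudobulk quantification, normalization and the
tested-variant universe.

On-disk conventions: minimal GT-only VCF (1-based positions), BED4
peaks (0-based half-open), tab-separated matrices with the feature id in
the first column and one column per sample.  All readers and writers
round-trip exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from cyvcf2 import VCF
from scipy import stats

from .types import FeatureMatrix, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "merge_peak_sets",
    "pseudobulk_quantify",
    "normalize_transform",
    "TestUniverse",
    "build_test_universe",
    "annotate_promoters",
    "classify_promoter_peaks",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read a GT-only VCF into a GenotypeMatrix.

    Missing genotypes (./.) become NaN dosages; phased separators are
    accepted and the phase is retained in the haplotype tables (NaN for
    unphased heterozygotes).  Multiallelic or symbolic ALT records are
    rejected with the record location.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    dos_rows, hapa_rows, hapb_rows = [], [], []
    for rec in vcf:
        loc = f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record at {loc}")
        if not set(rec.ALT[0]) <= set("ACGT"):
            raise ValueError(f"symbolic/non-SNV ALT at {loc}")
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{loc}_{rec.REF}_{rec.ALT[0]}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        dos, ha, hb = [], [], []
        for a1, a2, phased in rec.genotypes:
            if a1 < 0 or a2 < 0:
                dos.append(np.nan)
                ha.append(np.nan)
                hb.append(np.nan)
            else:
                dos.append(float(a1 + a2))
                if phased or a1 == a2:
                    ha.append(float(a1))
                    hb.append(float(a2))
                else:
                    ha.append(np.nan)
                    hb.append(np.nan)
        dos_rows.append(dos)
        hapa_rows.append(ha)
        hapb_rows.append(hb)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="variant"),
    )
    dosages = pd.DataFrame(np.array(dos_rows, dtype=float).T if dos_rows else
                           np.empty((len(samples), 0)),
                           index=samples, columns=ids)
    hap_a = pd.DataFrame(np.array(hapa_rows, dtype=float).T if hapa_rows else
                         np.empty((len(samples), 0)), index=samples, columns=ids)
    hap_b = pd.DataFrame(np.array(hapb_rows, dtype=float).T if hapb_rows else
                         np.empty((len(samples), 0)), index=samples, columns=ids)
    return GenotypeMatrix(variants, dosages, (hap_a, hap_b))


def write_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF (phased where haplotypes are known)."""
    v = genotypes.variants
    hap = genotypes.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        for vid, rec in v.iterrows():
            gts = []
            for s in genotypes.samples:
                d = genotypes.dosages.loc[s, vid]
                if np.isnan(d):
                    gts.append("./.")
                    continue
                if hap is not None:
                    a, b = hap[0].loc[s, vid], hap[1].loc[s, vid]
                    if not (np.isnan(a) or np.isnan(b)):
                        gts.append(f"{int(a)}|{int(b)}")
                        continue
                d = int(d)
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t{vid}\t{rec['ref']}\t{rec['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def read_bed(path: str) -> pd.DataFrame:
    """Read BED4 (chrom, start, end, name) into a name-indexed frame."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    return df.set_index("name")


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """Write a name-indexed interval frame as BED4."""
    out = intervals.reset_index()[["chrom", "start", "end"]].copy()
    out["name"] = intervals.index
    out.to_csv(path, sep="\t", header=False, index=False)


def read_matrix_tsv(path: str) -> pd.DataFrame:
    """Feature x sample TSV: first column feature id, header = samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(values: pd.DataFrame, path: str) -> None:
    values.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# peak standardization
# ---------------------------------------------------------------------------

def merge_peak_sets(peak_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-cell-type peak intervals into a standardized peak set.

    Overlapping input intervals are merged single-linkage (strand
    ignored); each merged peak carries the set of cell types whose input
    peaks overlap it, as a ``cell_types`` frozenset column.  The result
    is indexed by a coordinate-derived peak id, with ``anchor`` at the
    interval midpoint.
    """
    frames = []
    for ct, df in peak_sets.items():
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"malformed interval in {ct!r} peak set")
        frames.append(pd.DataFrame({
            "Chromosome": df["chrom"], "Start": df["start"],
            "End": df["end"], "cell_type": ct,
        }))
    allp = pd.concat(frames, ignore_index=True)
    merged = pr.PyRanges(allp[["Chromosome", "Start", "End"]]).merge().df
    joined = pr.PyRanges(merged).join(pr.PyRanges(allp)).df
    key = ["Chromosome", "Start", "End"]
    flags = joined.groupby(key, observed=True)["cell_type"].agg(
        lambda s: frozenset(s)
    )
    merged = merged.merge(flags.rename("cell_types"), on=key)
    out = pd.DataFrame({
        "chrom": merged["Chromosome"].astype(str),
        "start": merged["Start"].astype(int),
        "end": merged["End"].astype(int),
        "cell_types": merged["cell_types"],
    })
    out = out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out.index = pd.Index(
        [f"{c}:{s}-{e}" for c, s, e in zip(out["chrom"], out["start"], out["end"])],
        name="peak",
    )
    out["anchor"] = (out["start"] + out["end"]) // 2
    return out


# ---------------------------------------------------------------------------
# pseudobulk quantification
# ---------------------------------------------------------------------------

def pseudobulk_quantify(
    cell_counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
    mode: str = "mean_cpm",
    features: pd.DataFrame | None = None,
    feature_lengths: pd.Series | None = None,
    cpm_min: float = 5.0,
    fpkm_min: float = 2.0,
) -> dict[str, tuple[FeatureMatrix | pd.DataFrame, pd.Series]]:
    """Aggregate cell-level counts to per-sample, per-cell-type values.

    ``cell_counts`` is features x cells; ``cell_meta`` maps each cell
    (index) to a ``sample`` and ``cell_type``.  ``mean_cpm`` scales each
    cell to counts per million and averages cells of a (sample, cell
    type) group; ``fpkm`` additionally divides by feature length in kb
    (``feature_lengths`` required).  Returns per cell type the value
    table (a FeatureMatrix when ``features`` is given, else a plain
    frame) and the keep-mask: mean CPM across samples >= 5 for genes,
    mean FPKM >= 2 for peaks.
    """
    if mode not in ("mean_cpm", "fpkm"):
        raise ValueError("mode must be mean_cpm or fpkm")
    if not set(cell_counts.columns) <= set(cell_meta.index):
        raise ValueError("every cell must have sample and cell-type labels")
    if mode == "fpkm" and feature_lengths is None:
        raise ValueError("fpkm mode requires feature_lengths")

    lib = cell_counts.sum(axis=0)
    per_cell = cell_counts / lib.replace(0, np.nan) * 1e6
    if mode == "fpkm":
        per_cell = per_cell.div(feature_lengths.reindex(cell_counts.index) / 1e3,
                                axis=0) / 1e3  # CPM / (kb) / 1e3 == FPKM
    unit = "CPM" if mode == "mean_cpm" else "FPKM"

    out: dict[str, tuple[FeatureMatrix | pd.DataFrame, pd.Series]] = {}
    samples = sorted(cell_meta["sample"].unique())
    for ct, meta_ct in cell_meta.groupby("cell_type"):
        cols = {}
        for s in samples:
            cells = meta_ct.index[meta_ct["sample"] == s]
            if len(cells) == 0:
                log.warning("no %s cells for sample %s; value missing", ct, s)
                cols[s] = pd.Series(np.nan, index=cell_counts.index)
            else:
                cols[s] = per_cell[cells].mean(axis=1)
        table = pd.DataFrame(cols)
        mask = table.mean(axis=1) >= (cpm_min if mode == "mean_cpm" else fpkm_min)
        if features is not None:
            out[ct] = (FeatureMatrix(features, table, unit, ct), mask)
        else:
            out[ct] = (table, mask)
    return out


def cell_cpm(counts: pd.Series) -> pd.Series:
    """CPM of a single cell's counts (each cell scaled to one million)."""
    return counts / counts.sum() * 1e6


# ---------------------------------------------------------------------------
# normalization / transformation
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample quantile normalization.

    After the transform every sample column has identical sorted values:
    the cross-sample mean of order statistics.  Ties within a column
    receive the mean of the corresponding reference values.
    """
    ranked = values.rank(method="average")
    ref = np.sort(values.to_numpy(), axis=0).mean(axis=1)
    n = len(ref)
    out = {}
    for col in values.columns:
        r = ranked[col].to_numpy()
        lo = np.floor(r).astype(int) - 1
        hi = np.ceil(r).astype(int) - 1
        out[col] = (ref[lo] + ref[hi]) / 2.0
    return pd.DataFrame(out, index=values.index)


def inverse_normal_transform(values: pd.DataFrame, offset: float = 3.0 / 8.0) -> pd.DataFrame:
    """Rank-based inverse normal transform per feature across samples.

    value_i = Phi^{-1}((rank_i - c)/(n + 1 - 2c)) with the Blom offset
    c = 3/8 by default and average ranks for ties.
    """
    n = values.shape[1]
    if n < 2:
        raise ValueError("at least 2 samples required")
    ranks = values.rank(axis=1, method="average")
    return pd.DataFrame(
        stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1)),
        index=values.index, columns=values.columns,
    )


def normalize_transform(fm: FeatureMatrix, mode: str, offset: float = 3.0 / 8.0) -> FeatureMatrix:
    """Quantile-normalize across samples or inverse-normal per feature."""
    if mode == "quantile":
        return fm.with_values(quantile_normalize(fm.values), "quantile")
    if mode == "int":
        return fm.with_values(inverse_normal_transform(fm.values, offset), "INT")
    raise ValueError("mode must be 'quantile' or 'int'")


# ---------------------------------------------------------------------------
# tested-variant universe
# ---------------------------------------------------------------------------

@dataclass
class TestUniverse:
    """Candidate variants per feature after the standard cis filters."""

    candidates: dict[str, list[str]]
    window_kb: float = 250.0
    filters: dict = field(default_factory=dict)

    def __getitem__(self, feature: str) -> list[str]:
        return self.candidates.get(feature, [])

    def items(self):
        return self.candidates.items()

    def all_variants(self) -> list[str]:
        seen: dict[str, None] = {}
        for vs in self.candidates.values():
            for v in vs:
                seen.setdefault(v)
        return list(seen)


def build_test_universe(
    genotypes: GenotypeMatrix,
    features: pd.DataFrame,
    ocrs: pd.DataFrame | None,
    cell_type: str | None = None,
    window_kb: float = 250.0,
    maf_min: float = 0.1,
    min_carriers: int = 4,
    max_missing: float = 0.2,
    mode: str = "window",
) -> TestUniverse:
    """Candidate variants per feature for cis association testing.

    A candidate must lie within ``window_kb`` of the feature anchor
    (``mode='window'``; TSS for genes) or inside the feature interval
    itself (``mode='within'``; caQTL residence), fall inside an OCR
    accessible in ``cell_type`` (skipped when ``ocrs`` is None), have
    minor allele frequency >= ``maf_min``, at least ``min_carriers``
    samples carrying the minor allele, and missingness <= 20%.
    """
    v = genotypes.variants
    maf = genotypes.maf()
    carriers = genotypes.minor_allele_carriers()
    missing = genotypes.missingness()
    keep = (maf >= maf_min) & (carriers >= min_carriers) & (missing <= max_missing)

    in_ocr = pd.Series(True, index=v.index)
    if ocrs is not None:
        sel = ocrs
        if cell_type is not None:
            sel = ocrs[[cell_type in cts for cts in ocrs["cell_types"]]]
        in_ocr = pd.Series(False, index=v.index)
        pos0 = v["pos"] - 1
        for chrom, grp in sel.groupby("chrom", observed=True):
            on_chrom = v.index[v["chrom"] == chrom]
            if len(on_chrom) == 0:
                continue
            p = pos0[on_chrom].to_numpy()
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            hit = ((p[:, None] >= starts[None, :]) & (p[:, None] < ends[None, :])).any(axis=1)
            in_ocr[on_chrom] = hit
    keep &= in_ocr

    window = window_kb * 1000.0
    cands: dict[str, list[str]] = {}
    pos0 = v["pos"] - 1
    for fid, frow in features.iterrows():
        on_chrom = v["chrom"] == frow["chrom"]
        if mode == "within":
            near = (pos0 >= frow["start"]) & (pos0 < frow["end"])
        else:
            near = (pos0 - frow["anchor"]).abs() <= window
        cands[fid] = list(v.index[on_chrom & near & keep])
    return TestUniverse(
        cands, window_kb,
        {"maf_min": maf_min, "min_carriers": min_carriers,
         "max_missing": max_missing, "cell_type": cell_type, "mode": mode},
    )


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def annotate_promoters(genes: pd.DataFrame, flank_bp: int = 1000) -> pd.DataFrame:
    """Promoter intervals: TSS +/- flank, 0-based half-open.

    The TSS is the gene's ``anchor`` (interval start on + strand, end-1
    on -); the promoter of a gene is [tss - flank, tss + flank + 1).
    """
    tss = genes["anchor"]
    out = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": (tss - flank_bp).clip(lower=0),
        "end": tss + flank_bp + 1,
        "gene": genes.index,
    })
    out.index = pd.Index([f"prom_{g}" for g in genes.index], name="promoter")
    return out


def classify_promoter_peaks(
    peaks: pd.DataFrame, promoters: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag peaks overlapping any promoter by >= 1 bp.

    Returns the boolean promoter-class series and the (peak, gene)
    overlap pairs so promoter peaks can be tied to their genes.
    """
    pk = pr.PyRanges(pd.DataFrame({
        "Chromosome": peaks["chrom"], "Start": peaks["start"],
        "End": peaks["end"], "peak": peaks.index,
    }))
    pm = pr.PyRanges(pd.DataFrame({
        "Chromosome": promoters["chrom"], "Start": promoters["start"],
        "End": promoters["end"], "gene": promoters["gene"],
    }))
    joined = pk.join(pm).df
    if joined.empty:
        pairs = pd.DataFrame(columns=["peak", "gene"])
    else:
        pairs = joined[["peak", "gene"]].drop_duplicates().reset_index(drop=True)
    flag = pd.Series(False, index=peaks.index, name="promoter")
    flag[pairs["peak"].unique()] = True
    return flag, pairs
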