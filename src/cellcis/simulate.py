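"""Synthetic-data generation with planted ground truth.

Every input the pipeline consumes can be generated here: diploid
genotypes with block LD structure, per-cell-type pseudobulk phenotypes
with planted cis effects, heterozygote allelic sequencing counts,
master/dependent peak architectures, barcoded MPRA counts and GWAS
summary statistics with an annotation-enriched causal variant.

LD is produced by a block-mosaic copy-with-mutation scheme: within a
block every variant shares one allele frequency and each haplotype
copies the previous variant's allele with probability ``ld_decay``,
refreshing it from the population frequency otherwise.  This yields
pairwise haplotype correlation ``ld_decay**d`` at distance ``d`` variants
while keeping marginal frequencies exact; blocks are independent.  Only
the pairwise r² structure matters downstream, so no coalescent machinery
is used.

All randomness flows from a single seed through named substreams
(:func:`cellcis._rng.substream`), so identical config + seed yields
byte-identical outputs and effects planted in one cell type leave the
draws of every other cell type untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .types import FeatureMatrix, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "simulate_genotypes",
    "add_duplicate_variant",
    "simulate_pseudobulk",
    "simulate_dependency_architecture",
    "simulate_allelic_counts",
    "simulate_mpra",
    "simulate_gwas_block",
]

CIS_WINDOW_BP = 250_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the scale of a 20-donor single-cell multiomics
    cohort: 20 samples, minor allele frequencies at or above 0.1, and
    per-site sequencing depths around 50 reads.
    """

    n_samples: int = 20
    seed: int = 0
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 10
    ld_decay: float = 0.8
    wgs_depth: float = 50.0
    atac_depth: float = 50.0
    mpra_depth: float = 100.0
    noise_sd: float = 1.0
    dispersion: float = 0.0  # optional NB overdispersion; 0 = pure Poisson

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("insufficient samples")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if min(self.wgs_depth, self.atac_depth, self.mpra_depth) <= 0:
            raise ValueError("depths must be positive")
        if not 0 <= self.ld_decay <= 1:
            raise ValueError("ld_decay must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    def rng(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)


@dataclass(frozen=True)
class PlantedEffect:
    """A cis effect to plant: per-allele slope of a variant on a feature."""

    feature: str
    variant: str
    cell_type: str
    slope: float


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: SimulationConfig,
    n_variants: int = 100,
    chrom: str = "chr1",
    spacing_bp: int = 1000,
    start_pos: int = 10_001,
) -> GenotypeMatrix:
    """Simulate phased diploid genotypes with block-mosaic LD.

    Variants are laid out every ``spacing_bp`` bases on ``chrom``
    (1-based positions starting at ``start_pos``) and partitioned into
    consecutive blocks of ``config.ld_block_size`` variants.
    """
    rng = config.rng("genotypes")
    n = config.n_samples
    lo, hi = config.maf_range
    n_hap = 2 * n

    haps = np.empty((n_hap, n_variants), dtype=np.int8)
    for block_start in range(0, n_variants, config.ld_block_size):
        block_end = min(block_start + config.ld_block_size, n_variants)
        p = rng.uniform(lo, hi)
        haps[:, block_start] = rng.random(n_hap) < p
        for j in range(block_start + 1, block_end):
            fresh = rng.random(n_hap) < p
            copy = rng.random(n_hap) < config.ld_decay
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)

    ids = [f"var{i:05d}" for i in range(n_variants)]
    samples = [f"S{i:02d}" for i in range(n)]
    pos = start_pos + spacing_bp * np.arange(n_variants)
    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(bases, size=n_variants)
    alt = np.array(
        [rng.choice([b for b in bases if b != r]) for r in ref]
    )
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt},
        index=pd.Index(ids, name="variant"),
    )
    hap_a = pd.DataFrame(haps[0::2], index=samples, columns=ids)
    hap_b = pd.DataFrame(haps[1::2], index=samples, columns=ids)
    dosages = (hap_a + hap_b).astype(float)
    return GenotypeMatrix(variants, dosages, (hap_a, hap_b))


def add_duplicate_variant(
    genotypes: GenotypeMatrix, variant: str, new_id: str, pos: int | None = None
) -> GenotypeMatrix:
    """Append a copy of ``variant``'s genotype column (r² = 1 pair)."""
    rec = genotypes.variants.loc[variant].copy()
    if pos is not None:
        rec["pos"] = pos
    variants = pd.concat([genotypes.variants, rec.to_frame(new_id).T])
    variants["pos"] = variants["pos"].astype(int)
    dosages = genotypes.dosages.copy()
    dosages[new_id] = dosages[variant]
    haps = None
    if genotypes.haplotypes is not None:
        a, b = (h.copy() for h in genotypes.haplotypes)
        a[new_id] = a[variant]
        b[new_id] = b[variant]
        haps = (a, b)
    return GenotypeMatrix(variants, dosages, haps)


# ---------------------------------------------------------------------------
# pseudobulk phenotypes with planted cis effects
# ---------------------------------------------------------------------------

def _feature_table(
    genotypes: GenotypeMatrix,
    n_features: int,
    kind: str,
    prefix: str,
    width: int,
) -> pd.DataFrame:
    """Lay features evenly across the simulated variant span (0-based)."""
    pos0 = genotypes.variants["pos"].to_numpy() - 1
    chrom = genotypes.variants["chrom"].iloc[0]
    anchors = np.linspace(pos0.min(), pos0.max(), n_features).round().astype(int)
    start = np.maximum(anchors - width // 2, 0)
    ids = [f"{prefix}{i:04d}" for i in range(n_features)]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + width,
            "strand": "+",
            "anchor": anchors,
        },
        index=pd.Index(ids, name="feature"),
    )


def simulate_pseudobulk(
    genotypes: GenotypeMatrix,
    effects: list[PlantedEffect],
    config: SimulationConfig,
    cell_types: tuple[str, ...] = ("Rod", "Cone"),
    n_features: int = 50,
    kind: str = "gene",
    baseline: float = 10.0,
    features: pd.DataFrame | None = None,
) -> tuple[dict[str, FeatureMatrix], pd.DataFrame]:
    """Per-cell-type pseudobulk phenotypes with planted cis effects.

    phenotype = baseline + slope * dosage + N(0, noise_sd), on an
    already-normalized scale (unit tag ``normalized``).  Returns one
    FeatureMatrix per cell type and a truth table with one row per
    (feature, cell type): planted rows carry their slope and
    ``is_causal``; null rows carry effect 0.
    """
    if features is None:
        width = 1000 if kind == "gene" else 500
        features = _feature_table(
            genotypes, n_features, kind, "g" if kind == "gene" else "pk", width
        )
    for eff in effects:
        if eff.feature not in features.index:
            raise KeyError(f"unknown feature {eff.feature!r}")
        if eff.variant not in genotypes.variants.index:
            raise KeyError(f"unknown variant {eff.variant!r}")
        if eff.cell_type not in cell_types:
            raise ValueError(f"unknown cell type {eff.cell_type!r}")
        pos0 = genotypes.variants.loc[eff.variant, "pos"] - 1
        if abs(pos0 - features.loc[eff.feature, "anchor"]) > CIS_WINDOW_BP:
            raise ValueError("not cis")

    samples = genotypes.samples
    out: dict[str, FeatureMatrix] = {}
    truth_rows = []
    by_ct: dict[str, list[PlantedEffect]] = {ct: [] for ct in cell_types}
    for eff in effects:
        by_ct[eff.cell_type].append(eff)

    for ct in cell_types:
        rng = config.rng(f"pseudobulk:{kind}:{ct}")
        vals = baseline + config.noise_sd * rng.standard_normal(
            (len(features), len(samples))
        )
        values = pd.DataFrame(vals, index=features.index, columns=samples)
        planted = {}
        for eff in by_ct[ct]:
            g = genotypes.dosages[eff.variant].fillna(
                genotypes.dosages[eff.variant].mean()
            )
            values.loc[eff.feature] = values.loc[eff.feature] + eff.slope * g.values
            planted[eff.feature] = eff
        out[ct] = FeatureMatrix(features, values, "normalized", ct)
        for fid in features.index:
            eff = planted.get(fid)
            truth_rows.append(
                {
                    "entity": fid,
                    "cell_type": ct,
                    "variant": eff.variant if eff else "",
                    "effect_size": eff.slope if eff else 0.0,
                    "is_causal": eff is not None,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return out, truth


# ---------------------------------------------------------------------------
# master/dependent peak architecture
# ---------------------------------------------------------------------------

def simulate_dependency_architecture(
    genotypes: GenotypeMatrix,
    variant: str,
    coupling_signs: tuple[int, ...] = (1, 1, 1),
    config: SimulationConfig | None = None,
    cell_type: str = "Rod",
    beta: float = 2.0,
    dependent_offsets_bp: tuple[int, ...] | None = None,
    n_null_peaks: int = 20,
    baseline: float = 10.0,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Accessibility matrix with one master peak and coupled dependents.

    The variant's dosage drives the master peak's accessibility; each
    dependent peak equals ``sign x master signal`` plus noise.  Null
    background peaks within the window are included for calibration.
    Dependents farther than 250 kb from the variant are rejected.
    """
    config = config or SimulationConfig()
    if dependent_offsets_bp is None:
        dependent_offsets_bp = tuple(
            10_000 * (i + 1) for i in range(len(coupling_signs))
        )
    if len(dependent_offsets_bp) != len(coupling_signs):
        raise ValueError("one offset per coupling sign required")
    if any(abs(o) > CIS_WINDOW_BP for o in dependent_offsets_bp):
        raise ValueError("dependent peak outside the 250 kb window")

    rng = config.rng(f"dependency:{cell_type}:{variant}")
    vpos0 = int(genotypes.variants.loc[variant, "pos"]) - 1
    chrom = genotypes.variants.loc[variant, "chrom"]
    g = genotypes.dosages[variant].fillna(genotypes.dosages[variant].mean())
    n = len(g)

    rows, values, truth_rows = [], [], []
    master_signal = beta * g.to_numpy() + config.noise_sd * rng.standard_normal(n)

    def peak_row(pid, center):
        rows.append(
            {"id": pid, "chrom": chrom, "start": center - 250, "end": center + 250,
             "strand": ".", "anchor": center}
        )

    peak_row("master", vpos0)
    values.append(baseline + master_signal)
    truth_rows.append(
        {"entity": "master", "role": "master", "coupling": 1,
         "variant": variant, "effect_size": beta, "is_causal": True}
    )
    for k, (sign, off) in enumerate(zip(coupling_signs, dependent_offsets_bp)):
        pid = f"dep{k}"
        peak_row(pid, vpos0 + off)
        noise = config.noise_sd * rng.standard_normal(n)
        values.append(baseline + sign * master_signal + noise)
        truth_rows.append(
            {"entity": pid, "role": "dependent", "coupling": sign,
             "variant": variant, "effect_size": sign * beta,
             "is_causal": sign != 0}
        )
    for k in range(n_null_peaks):
        pid = f"null{k}"
        # spread nulls on the opposite side of the window; fall back to
        # interleaved positions when the variant sits near the chromosome start
        center = vpos0 - 5_000 * (k + 1)
        if center < 250:
            center = vpos0 + 5_000 * (k + 1) + 2_500
        peak_row(pid, center)
        values.append(baseline + config.noise_sd * rng.standard_normal(n))
        truth_rows.append(
            {"entity": pid, "role": "null", "coupling": 0, "variant": variant,
             "effect_size": 0.0, "is_causal": False}
        )

    features = pd.DataFrame(rows).set_index("id")
    features["start"] = features["start"].clip(lower=0)
    fm = FeatureMatrix(
        features,
        pd.DataFrame(np.asarray(values), index=features.index, columns=genotypes.samples),
        "normalized",
        cell_type,
    )
    return fm, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# allelic counts
# ---------------------------------------------------------------------------

def simulate_allelic_counts(
    genotypes: GenotypeMatrix,
    imbalance: dict[str, float],
    config: SimulationConfig,
    cell_type: str = "Rod",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allelic count records for WGS and ATAC sources.

    For heterozygotes the WGS alternative count is Binomial(depth, 0.5)
    and the ATAC alternative count Binomial(depth, planted fraction);
    homozygotes emit reads of the carried allele only.  Depths are fixed
    at the configured per-assay means so that the planted binomial
    fraction is the only source of imbalance.
    """
    for v, frac in imbalance.items():
        if not 0 < frac < 1:
            raise ValueError(f"alt-fraction for {v} must be in (0, 1)")
        if v not in genotypes.variants.index:
            raise KeyError(f"unknown variant {v!r}")
    rng = config.rng(f"allelic:{cell_type}")
    dw = int(round(config.wgs_depth))
    da = int(round(config.atac_depth))

    vids = list(imbalance)
    fracs = np.array([imbalance[v] for v in vids])
    dos = genotypes.dosages[vids].to_numpy()  # samples x variants
    n_s, n_v = dos.shape
    obs = ~np.isnan(dos)
    het = dos == 1
    wgs_alt = np.where(het, rng.binomial(dw, 0.5, size=dos.shape), 0)
    atac_alt = np.where(
        het,
        rng.binomial(da, np.broadcast_to(fracs, dos.shape)),
        0,
    )
    hom_alt = dos == 2
    wgs_alt = np.where(hom_alt, dw, wgs_alt)
    atac_alt = np.where(hom_alt, da, atac_alt)

    si, vi = np.nonzero(obs)
    sample_arr = np.asarray(genotypes.samples, dtype=object)[si]
    var_arr = np.asarray(vids, dtype=object)[vi]
    wgs = pd.DataFrame({
        "variant": var_arr, "sample": sample_arr, "cell_type": cell_type,
        "source": "WGS", "ref_count": dw - wgs_alt[si, vi],
        "alt_count": wgs_alt[si, vi],
    })
    atac = pd.DataFrame({
        "variant": var_arr, "sample": sample_arr, "cell_type": cell_type,
        "source": "ATAC", "ref_count": da - atac_alt[si, vi],
        "alt_count": atac_alt[si, vi],
    })
    counts = pd.concat([wgs, atac], ignore_index=True)
    truth = pd.DataFrame(
        {
            "entity": list(imbalance),
            "cell_type": cell_type,
            "effect_size": [f - 0.5 for f in imbalance.values()],
            "is_causal": [f != 0.5 for f in imbalance.values()],
        }
    )
    return counts, truth


# ---------------------------------------------------------------------------
# MPRA counts
# ---------------------------------------------------------------------------

def simulate_mpra(
    activities: dict[str, float],
    config: SimulationConfig,
    barcodes_per_element: int = 3,
    basal_barcodes: int = 25,
    replicates: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Barcoded RNA/DNA counts for reporter elements.

    ``activities`` maps element id to log2 activity relative to the
    basal promoter; DNA counts are Poisson(depth) and RNA counts
    Poisson(depth x 2**activity), so the expected RNA/DNA ratio of an
    element is 2**activity times the basal ratio.  The basal promoter is
    emitted with ``basal_barcodes`` barcodes per replicate (element id
    ``basal``, class label ``basal``).
    """
    if replicates < 2:
        raise ValueError("at least 2 replicates required")
    if barcodes_per_element < 1:
        raise ValueError("barcodes_per_element must be >= 1")
    rng = config.rng("mpra")
    depth = config.mpra_depth

    def draw(mean, size):
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mean / shape, size=size)
            return rng.poisson(lam)
        return rng.poisson(mean, size=size)

    records = []
    for rep in range(replicates):
        for bc in range(basal_barcodes):
            dna = draw(depth, None)
            rna = draw(depth, None)
            records.append(("basal", f"basal_bc{bc}", f"rep{rep}", dna, rna, "basal"))
        for elem, act in activities.items():
            for bc in range(barcodes_per_element):
                dna = draw(depth, None)
                rna = draw(depth * 2.0 ** act, None)
                records.append((elem, f"{elem}_bc{bc}", f"rep{rep}", dna, rna, "test"))
    counts = pd.DataFrame(
        records,
        columns=["element", "barcode", "replicate", "dna_count", "rna_count", "class"],
    )
    truth = pd.DataFrame(
        {
            "entity": list(activities),
            "effect_size": list(activities.values()),
            "is_causal": [a != 0 for a in activities.values()],
        }
    )
    return counts, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas_block(
    genotypes: GenotypeMatrix,
    causal: str,
    config: SimulationConfig,
    z_causal: float = 8.0,
    n_gwas: int = 50_000,
    annotations: dict[str, int] | None = None,
    paired_qtl: str = "none",
    z_qtl: float | None = None,
    block_id: str = "block0",
    stream: str = "gwas",
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """GWAS (and optionally molecular-QTL) summary statistics for a block.

    Per-variant z-scores follow z_j = r_{j,causal} * z_causal + N(0,1),
    the standard single-causal approximation under LD; betas and
    standard errors are consistent with z and allele frequency via
    se_j = 1/sqrt(2 f_j (1-f_j) n_gwas).  ``paired_qtl`` is one of
    ``none``, ``shared`` (QTL trait driven by the same causal variant)
    or ``distinct`` (QTL causal chosen with r² < 0.1 to the GWAS causal;
    an error if no such variant exists).
    """
    if causal not in genotypes.variants.index:
        raise KeyError(f"unknown variant {causal!r}")
    if n_gwas < 100:
        raise ValueError("n_gwas must be >= 100")
    if paired_qtl not in ("none", "shared", "distinct"):
        raise ValueError("paired_qtl must be none, shared or distinct")
    rng = config.rng(f"{stream}:{block_id}")

    d = genotypes.dosages.fillna(genotypes.dosages.mean())
    corr = d.corrwith(d[causal]).fillna(0.0)

    def summary(causal_id: str, z0: float) -> pd.DataFrame:
        r = d.corrwith(d[causal_id]).fillna(0.0).to_numpy()
        z = r * z0 + rng.standard_normal(len(r))
        # frequencies re-estimated in the large GWAS cohort cannot be
        # monomorphic; keep them off the boundary
        f = np.clip(genotypes.alt_frequency().to_numpy(), 0.01, 0.99)
        se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_gwas)
        beta = z * se
        p = 2.0 * stats.norm.sf(np.abs(z))
        v = genotypes.variants
        return pd.DataFrame(
            {
                "variant_id": v.index,
                "chrom": v["chrom"].to_numpy(),
                "pos": v["pos"].to_numpy(),
                "beta": beta,
                "se": se,
                "p": np.clip(p, np.nextafter(0, 1), 1.0),
                "maf": np.minimum(f, 1 - f),
                "block": block_id,
            }
        ).reset_index(drop=True)

    gwas = summary(causal, z_causal)
    qtl = None
    qtl_causal = ""
    if paired_qtl != "none":
        zq = z_qtl if z_qtl is not None else z_causal
        if paired_qtl == "shared":
            qtl_causal = causal
        else:
            low_ld = corr[corr**2 < 0.1].index.tolist()
            low_ld = [v for v in low_ld if v != causal]
            if not low_ld:
                raise ValueError("no variant with r² < 0.1 to the causal available")
            qtl_causal = low_ld[len(low_ld) // 2]
        qtl = summary(qtl_causal, zq)

    ann = annotations or {}
    truth = pd.DataFrame(
        {
            "entity": genotypes.variants.index,
            "is_causal": genotypes.variants.index == causal,
            "category": [ann.get(v, 0) for v in genotypes.variants.index],
            "qtl_causal": qtl_causal,
            "block": block_id,
        }
    ).reset_index(drop=True)
    return gwas, qtl, truth
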