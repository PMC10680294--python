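"""Core in-memory containers shared across the pipeline.

Coordinate conventions: genomic intervals (peaks, genes, promoters) are
0-based half-open throughout, as on disk in BED; variant positions are
stored 1-based as in VCF and converted where intervals are intersected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FeatureMatrix",
    "VALID_UNITS",
]

#: value-table unit tags a FeatureMatrix may carry
VALID_UNITS = ("counts", "CPM", "FPKM", "quantile", "INT", "normalized")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage table with variant metadata.

    Parameters
    ----------
    variants
        One row per variant, indexed by unique variant id, with columns
        ``chrom``, ``pos`` (1-based int), ``ref``, ``alt``.
    dosages
        Samples (rows) x variant ids (columns); entries in {0, 1, 2} or
        NaN for missing genotypes.
    haplotypes
        Optional pair (hap_a, hap_b) of 0/1 tables aligned with
        ``dosages``; NaN where phase is unknown.
    """

    variants: pd.DataFrame
    dosages: pd.DataFrame
    haplotypes: tuple[pd.DataFrame, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        if not self.variants.index.is_unique:
            raise ValueError("variant ids must be unique")
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValueError("dosage columns must match variant ids")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def samples(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def n_samples(self) -> int:
        return len(self.dosages.index)

    def alt_frequency(self) -> pd.Series:
        """Alternative-allele frequency per variant on non-missing calls."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        """Minor-allele frequency per variant on non-missing calls."""
        af = self.alt_frequency()
        return np.minimum(af, 1.0 - af)

    def missingness(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0)

    def minor_allele_carriers(self) -> pd.Series:
        """Number of samples carrying at least one copy of the minor allele."""
        d = self.dosages
        af = self.alt_frequency()
        alt_carriers = (d >= 1).sum(axis=0)
        ref_carriers = (d <= 1).sum(axis=0)
        return pd.Series(
            np.where(af <= 0.5, alt_carriers, ref_carriers),
            index=d.columns,
        )

    def subset_variants(self, ids) -> "GenotypeMatrix":
        ids = list(ids)
        haps = None
        if self.haplotypes is not None:
            haps = (self.haplotypes[0][ids], self.haplotypes[1][ids])
        return GenotypeMatrix(self.variants.loc[ids], self.dosages[ids], haps)


@dataclass
class FeatureMatrix:
    """Features (genes or peaks) x samples value table.

    ``features`` holds one row per feature id with columns ``chrom``,
    ``start``, ``end`` (0-based half-open), ``strand`` and ``anchor`` —
    the TSS for genes, the summit for peaks (0-based point inside the
    interval).
    """

    features: pd.DataFrame
    values: pd.DataFrame
    unit: str = "counts"
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if not self.features.index.is_unique:
            raise ValueError("feature ids must be unique")
        if list(self.values.index) != list(self.features.index):
            raise ValueError("value rows must match feature ids")
        f = self.features
        if (f["start"] >= f["end"]).any():
            raise ValueError("feature intervals must satisfy start < end")
        bad = (f["anchor"] < f["start"]) | (f["anchor"] >= f["end"])
        if bad.any():
            raise ValueError("anchor (TSS/summit) must lie within the interval")
        if self.unit in ("counts", "CPM", "FPKM"):
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"{self.unit} values must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, unit: str | None = None) -> "FeatureMatrix":
        return FeatureMatrix(
            self.features, values, unit or self.unit, self.cell_type
        )
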