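"""Shared in-memory containers for the genome/methylome divergence pipeline.

Coordinate discipline: every internal interval is 0-based half-open; every
coordinate read from or written to VCF/GFF3/cytosine reports is 1-based.
Genotypes are stored as alt-allele dosage (0/1/2) with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: consequence -> high-impact class used for clade-specific variant calling
HIGH_IMPACT_CLASSES = {
    "frameshift_variant": "frameshift",
    "stop_gained": "stop_gain",
    "stop_lost": "stop_loss",
    "start_lost": "start_loss",
    "splice_acceptor_variant": "splicing",
    "splice_donor_variant": "splicing",
}


class ValidationError(ValueError):
    """Raised when an input file violates the documented contract."""


@dataclass
class SampleSheet:
    """Accession -> species/lineage mapping with hybrid flags.

    Clade labels used throughout the pipeline are either species names or
    lineage names from this sheet; hybrids are excluded from all
    species/lineage comparisons.
    """

    table: pd.DataFrame  # columns: sample_id, species, lineage, is_hybrid

    def __post_init__(self) -> None:
        required = ["sample_id", "species", "lineage", "is_hybrid"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        t = self.table
        dup = t["sample_id"][t["sample_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate sample_id(s): {sorted(set(dup))}")
        for col in ("species", "lineage"):
            bad = t.loc[t[col].isna() | (t[col].astype(str).str.strip() == ""), "sample_id"]
            if len(bad):
                raise ValidationError(f"empty {col} for sample(s): {bad.tolist()}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def species_labels(self) -> list[str]:
        return sorted(self.table.loc[~self.table["is_hybrid"], "species"].unique())

    @property
    def lineage_labels(self) -> list[str]:
        return sorted(self.table.loc[~self.table["is_hybrid"], "lineage"].unique())

    def is_clade(self, label: str) -> bool:
        return label in self.species_labels or label in self.lineage_labels

    def clade_indices(self, label: str, include_hybrids: bool = False) -> np.ndarray:
        """Column indices of the samples belonging to a species or lineage."""
        t = self.table
        mask = (t["species"] == label) | (t["lineage"] == label)
        if not include_hybrids:
            mask &= ~t["is_hybrid"]
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise ValidationError(f"clade label {label!r} matches no (non-hybrid) sample")
        return idx

    def index_of(self, sample_id: str) -> int:
        pos = self.table.index[self.table["sample_id"] == sample_id]
        if len(pos) != 1:
            raise KeyError(sample_id)
        return int(pos[0])


@dataclass
class GeneModel:
    """A gene with the CDS of its first mRNA, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    dnds_eligible: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.cds_segments = sorted(self.cds_segments)
        total = sum(e - s + 1 for s, e in self.cds_segments)
        if total % 3 != 0:
            self.dnds_eligible = False

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (1-based)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass
class GenotypeMatrix:
    """Variant sites x samples alt-allele dosage with site annotations.

    ``sites`` columns: chrom, pos (1-based), ref, alt, consequence, impact,
    gene_id, is_snp. Row order is genomic. ``dosage`` holds 0/1/2 with -1
    for missing calls.
    """

    sites: pd.DataFrame
    dosage: np.ndarray  # (n_sites, n_samples) int8
    samples: list[str]

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValidationError("dosage shape does not match sites/samples")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sites.loc[mask].copy(), self.dosage[mask], self.samples)

    def snps_only(self) -> "GenotypeMatrix":
        """Biallelic SNP records (after splitting) for pi/FST/PCA/NJ."""
        return self.subset_sites(self.sites["is_snp"].to_numpy())


@dataclass
class MethylationMatrix:
    """CG sites x samples read counts; beta = meth/total where covered.

    A sample is covered at a site when total >= min_depth; uncovered entries
    are treated as missing, never as beta 0.
    """

    sites: pd.DataFrame  # columns: chrom, pos (1-based position of the + strand C)
    meth: np.ndarray  # (n_sites, n_samples) int32
    total: np.ndarray
    samples: list[str]
    min_depth: int = 3

    def __post_init__(self) -> None:
        if self.meth.shape != self.total.shape or self.meth.shape != (
            len(self.sites),
            len(self.samples),
        ):
            raise ValidationError("count matrices do not match sites/samples")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValidationError("negative read counts")
        if (self.meth > self.total).any():
            raise ValidationError("meth_count exceeds total_count")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def covered(self) -> np.ndarray:
        return self.total >= self.min_depth

    @property
    def beta(self) -> np.ndarray:
        """Per-site per-sample methylation level; NaN where uncovered."""
        with np.errstate(divide="ignore", invalid="ignore"):
            b = self.meth / np.where(self.total == 0, 1, self.total)
        b = b.astype(float)
        b[~self.covered] = np.nan
        return b

    def qc_mask(self, min_fraction: float = 0.8) -> np.ndarray:
        """Sites covered in at least ``min_fraction`` of samples (PCA QC)."""
        return self.covered.mean(axis=1) >= min_fraction
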