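"""Synthetic multi-clade genome + methylome generator with a truth manifest.

Emulates a three-lineage, ten-species, 36-accession panel: clade-structured
SNPs/INDELs dropped on the lineage/species/sample tree, planted clade-fixed
high-impact variants, bimodal CG methylation with negative-binomial depth
and beta-binomial read counts, planted inter-group DMR windows, CG-loss
variants that ablate methylation in carriers, and cis-driver variants whose
dosage (rather than clade label) drives a subset of planted DMRs.

All randomness flows through one seeded generator; output bytes are a pure
function of the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import GeneModel, MethylationMatrix, SampleSheet

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_CODON_AA = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, b1 in enumerate(_BASES):
    for _j, b2 in enumerate(_BASES):
        for _k, b3 in enumerate(_BASES):
            _CODON_AA[b1 + b2 + b3] = _AA[16 * _i + 4 * _j + _k]
_COMP = str.maketrans("ACGT", "TGCA")

HIGH_CONSEQUENCES = {
    "frameshift": "frameshift_variant",
    "stop_gain": "stop_gained",
    "stop_loss": "stop_lost",
    "start_loss": "start_lost",
    "splicing": "splice_donor_variant",
}


def _default_lineages() -> dict:
    return {
        "Asian": {"A_japonica": 7, "A_oxysepala": 7, "A_yabeana": 2, "A_viridiflora": 2},
        "European": {"A_vulgaris": 2, "A_alpina": 2, "A_fragrans": 2},
        "American": {"A_coerulea": 3, "A_canadensis": 3, "A_chrysantha": 2},
    }


def _default_ccvs() -> list:
    return [
        ["A_japonica", "A_oxysepala", 6],
        ["A_oxysepala", "A_japonica", 6],
        ["Asian", "American", 4],
        ["European", "American", 4],
        ["European", "Asian", 4],
    ]


def _default_dmrs() -> list:
    return [
        ["A_japonica", "A_oxysepala", 60],
        ["Asian", "American", 30],
        ["Asian", "European", 30],
        ["American", "European", 30],
    ]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic panel (defaults = the bundled
    three-lineage / ten-species / 36-accession design on 2 x 1 Mb chromosomes)."""

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    lineage_spec: dict = field(default_factory=_default_lineages)
    hybrids: list = field(default_factory=lambda: [["A_japonica", "A_oxysepala", 4]])
    gc_content: float = 0.36
    background_cpg_retention: float = 0.35  # CpG -> TpG deamination depletion
    n_genes: int = 100
    gene_codons: tuple = (150, 300)
    utr_length: int = 150
    two_exon_fraction: float = 0.3
    n_islands: int = 20
    island_length: tuple = (250, 1500)
    variant_rate: float = 0.01  # background variants per bp (whole panel)
    indel_fraction: float = 0.1
    branch_probs: tuple = (0.15, 0.45, 0.40)  # lineage / species / sample
    planted_ccvs: list = field(default_factory=_default_ccvs)
    ccv_genic_fraction: float = 0.4
    cg_loss_fraction: float = 0.38
    cg_loss_indel_fraction: float = 0.1
    planted_dmrs: list = field(default_factory=_default_dmrs)
    dmr_delta_beta: float = 0.4
    dmr_min_sites: int = 3
    dmr_genic_fraction: float = 0.4  # planted windows placed inside gene bodies
    cis_driver_fraction: float = 0.5
    driver_beta_range: float = 0.8  # beta span across dosage 0..2 at driver DMRs
    # planted tail classes must fit inside the 5% tails of the defined-gene
    # universe (genes with cross-clade CDS divergence), which is smaller than
    # n_genes; 3+3 leaves margin at the default 100 genes
    selection_comparison: tuple = ("A_japonica", "A_oxysepala")
    n_positive_genes: int = 3
    n_purifying_genes: int = 3
    positive_nonsyn: int = 15
    depth_mean: float = 12.0
    depth_dispersion: float = 5.0
    vcf_depth_mean: float = 30.0
    vcf_depth_dispersion: float = 8.0
    beta_mixture: tuple = ((8.0, 2.0, 0.6), (2.0, 8.0, 0.4))
    species_effect_sd: float = 0.05
    sample_effect_sd: float = 0.03
    bb_concentration: float = 30.0
    null_mode: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.dmr_delta_beta <= 1):
            raise ValueError("dmr_delta_beta must lie in (0, 1]")
        for lin, species in self.lineage_spec.items():
            for sp, n in species.items():
                if n < 2:
                    raise ValueError(f"species {sp} needs >= 2 samples, got {n}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("gene_codons", "island_length", "branch_probs", "beta_mixture",
                    "selection_comparison"):
            d[key] = _to_plain(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _to_plain(x):
    if isinstance(x, (tuple, list)):
        return [_to_plain(i) for i in x]
    return x


def build_sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for lineage, species in config.lineage_spec.items():
        for sp, n in species.items():
            for i in range(n):
                rows.append((f"{sp}_{i + 1:02d}", sp, lineage, False))
    for pa, pb, n in config.hybrids:
        lineage = next(
            lin for lin, sps in config.lineage_spec.items() if pa in sps
        )
        for i in range(n):
            rows.append((f"hyb_{pa}_{pb}_{i + 1:02d}", f"{pa}x{pb}", lineage, True))
    return pd.DataFrame(rows, columns=["sample_id", "species", "lineage", "is_hybrid"])


# ------------------------------------------------------------------ reference


def simulate_reference(config: SimConfig, rng: np.random.Generator):
    """Random genome with planted CpG-rich islands and non-overlapping genes.

    Returns (chrom -> mutable S1 array, genes, islands DataFrame). Genes carry
    a UTR pad on both sides of the CDS; ~30% have two CDS exons.
    """
    base_p = [(1 - config.gc_content) / 2, config.gc_content / 2,
              config.gc_content / 2, (1 - config.gc_content) / 2]
    genome: dict[str, np.ndarray] = {}
    chrom_names = [f"Chr{i + 1}" for i in range(config.n_chromosomes)]
    for chrom in chrom_names:
        arr = rng.choice(
            np.frombuffer(b"ACGT", dtype="S1"), size=config.chrom_length, p=base_p
        ).copy()
        # deaminate most background CpGs (C -> T) so CpG density outside the
        # planted islands and gene bodies is depleted, as in real genomes
        cpg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
        lost = cpg[rng.random(len(cpg)) > config.background_cpg_retention]
        arr[lost] = b"T"
        genome[chrom] = arr

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def place(chrom: str, length: int, margin: int = 200) -> int | None:
        for _ in range(200):
            start = int(rng.integers(margin, config.chrom_length - length - margin))
            if all(start + length + margin <= s or start >= e + margin
                   for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                return start
        return None

    # CpG islands: GC-rich iid sequence (obs/exp CpG ~ 1 by construction)
    island_rows = []
    for i in range(config.n_islands):
        chrom = chrom_names[i % len(chrom_names)]
        length = int(rng.integers(config.island_length[0], config.island_length[1] + 1))
        start = place(chrom, length)
        if start is None:
            raise ValueError(
                f"genome of {config.chrom_length} bp too small for the requested islands/genes"
            )
        isl = rng.choice(
            np.frombuffer(b"ACGT", dtype="S1"), size=length, p=[0.17, 0.33, 0.33, 0.17]
        )
        genome[chrom][start : start + length] = isl
        island_rows.append((chrom, start, start + length))
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])

    # genes: random stop-free CDS written into the genome; codon usage is
    # biased to the genomic base composition so coding regions do not read
    # as GC-rich islands
    codon_pool = [c for c in _CODON_AA if c not in _STOPS and c != "ATG"]
    pbase = {"A": (1 - config.gc_content) / 2, "T": (1 - config.gc_content) / 2,
             "C": config.gc_content / 2, "G": config.gc_content / 2}
    weights = np.array([pbase[c[0]] * pbase[c[1]] * pbase[c[2]] for c in codon_pool])
    weights = weights / weights.sum()
    genes: list[GeneModel] = []
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % len(chrom_names)]
        n_codons = int(rng.integers(config.gene_codons[0], config.gene_codons[1] + 1))
        cds = "ATG" + "".join(rng.choice(codon_pool, size=n_codons - 1, p=weights))
        two_exon = rng.random() < config.two_exon_fraction
        intron = int(rng.integers(100, 301)) if two_exon else 0
        span = len(cds) + intron + 2 * config.utr_length
        start0 = place(chrom, span, margin=300)
        if start0 is None:
            raise ValueError(
                f"genome of {config.chrom_length} bp too small for {config.n_genes} genes"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        cds_genomic = cds if strand == "+" else cds.translate(_COMP)[::-1]
        cds_start0 = start0 + config.utr_length
        if two_exon:
            cut = (len(cds) // 2) // 3 * 3  # split at a codon boundary
            if strand == "-":
                cut = len(cds) - cut
            seg1 = cds_genomic[:cut]
            seg2 = cds_genomic[cut:]
            s1 = (cds_start0, cds_start0 + len(seg1))
            s2 = (s1[1] + intron, s1[1] + intron + len(seg2))
            genome[chrom][s1[0] : s1[1]] = np.frombuffer(seg1.encode(), dtype="S1")
            genome[chrom][s2[0] : s2[1]] = np.frombuffer(seg2.encode(), dtype="S1")
            segments = [(s1[0] + 1, s1[1]), (s2[0] + 1, s2[1])]  # to 1-based incl.
            gene_end0 = s2[1] + config.utr_length
        else:
            genome[chrom][cds_start0 : cds_start0 + len(cds)] = np.frombuffer(
                cds_genomic.encode(), dtype="S1"
            )
            segments = [(cds_start0 + 1, cds_start0 + len(cds))]
            gene_end0 = cds_start0 + len(cds) + config.utr_length
        genes.append(
            GeneModel(
                gene_id=f"GENE{gi + 1:04d}",
                chromosome=chrom,
                start=start0 + 1,
                end=gene_end0,
                strand=strand,
                cds_segments=segments,
            )
        )
    return genome, genes, islands


def cpg_positions(genome: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """1-based positions of the C of each plus-strand CpG, per chromosome."""
    out = {}
    for chrom, arr in genome.items():
        hit = (arr[:-1] == b"C") & (arr[1:] == b"G")
        out[chrom] = np.flatnonzero(hit) + 1
    return out


# ------------------------------------------------------------------ variants


class _Panel:
    """Sample/clade bookkeeping shared by the variant and methylome steps."""

    def __init__(self, config: SimConfig):
        self.sheet_df = build_sample_sheet(config)
        self.samples = self.sheet_df["sample_id"].tolist()
        self.n = len(self.samples)
        self.species_idx: dict[str, np.ndarray] = {}
        self.lineage_idx: dict[str, np.ndarray] = {}
        nh = ~self.sheet_df["is_hybrid"].to_numpy()
        for sp in self.sheet_df.loc[nh, "species"].unique():
            self.species_idx[sp] = np.flatnonzero(
                nh & (self.sheet_df["species"] == sp).to_numpy()
            )
        for lin in self.sheet_df["lineage"].unique():
            self.lineage_idx[lin] = np.flatnonzero(
                nh & (self.sheet_df["lineage"] == lin).to_numpy()
            )
        self.hybrid_parents: dict[int, tuple[str, str]] = {}
        for pa, pb, _n in config.hybrids:
            mask = self.sheet_df["species"] == f"{pa}x{pb}"
            for i in np.flatnonzero(mask.to_numpy()):
                self.hybrid_parents[int(i)] = (pa, pb)
        self.branches = (
            [("lineage", lin) for lin in self.lineage_idx]
            + [("species", sp) for sp in self.species_idx]
            + [("sample", i) for i in np.flatnonzero(nh)]
        )

    def clade_idx(self, label: str) -> np.ndarray:
        if label in self.species_idx:
            return self.species_idx[label]
        return self.lineage_idx[label]

    def branch_dosage(self, kind: str, which, rng: np.random.Generator) -> np.ndarray:
        """Dosage vector for a variant dropped on one tree branch."""
        d = np.zeros(self.n, dtype=np.int8)
        if kind == "lineage":
            d[self.lineage_idx[which]] = 2
            carriers = {self.sheet_df["lineage"].iloc[i] for i in self.lineage_idx[which]}
            for h, (pa, pb) in self.hybrid_parents.items():
                dose = sum(
                    1
                    for p in (pa, pb)
                    if self.sheet_df.loc[self.sheet_df["species"] == p, "lineage"].iloc[0]
                    in carriers
                )
                d[h] = dose
        elif kind == "species":
            d[self.species_idx[which]] = 2
            for h, (pa, pb) in self.hybrid_parents.items():
                d[h] = (pa == which) + (pb == which)
        else:  # single sample
            d[which] = 1 if rng.random() < 0.5 else 2
        return d


def _cpg_free(seq: np.ndarray, start0: int, end0: int) -> bool:
    """True when [start0, end0) touches no CpG dinucleotide."""
    lo = max(start0 - 1, 0)
    hi = min(end0 + 1, len(seq))
    window = seq[lo:hi]
    return not ((window[:-1] == b"C") & (window[1:] == b"G")).any()


class _CdsMap:
    """Genome <-> CDS coordinate mapping for stop-aware variant planting."""

    def __init__(self, gene: GeneModel, genome: dict[str, np.ndarray]):
        self.gene = gene
        pos = []
        for s, e in gene.cds_segments:
            pos.extend(range(s, e + 1))  # 1-based genome positions, genomic order
        if gene.strand == "-":
            pos = pos[::-1]
        self.positions = np.array(pos)  # index = CDS offset
        seq = "".join(
            genome[gene.chromosome][p - 1].decode() for p in pos
        )
        self.cds = seq if gene.strand == "+" else None
        if gene.strand == "-":
            self.cds = "".join(
                genome[gene.chromosome][p - 1].decode().translate(_COMP) for p in pos
            )
        self.used_codons: set[int] = set()

    def plant(self, rng: np.random.Generator, synonymous: bool):
        """Pick (genome pos, ref base, alt base) realising a syn/nonsyn change."""
        n_codons = len(self.cds) // 3
        order = rng.permutation(n_codons)
        for ci in order:
            if ci in self.used_codons or ci == 0:
                continue
            codon = self.cds[3 * ci : 3 * ci + 3]
            choices = []
            for off in range(3):
                for b in "ACGT":
                    if b == codon[off]:
                        continue
                    alt_codon = codon[:off] + b + codon[off + 1 :]
                    if alt_codon in _STOPS:
                        continue
                    same = _CODON_AA[alt_codon] == _CODON_AA[codon]
                    if same == synonymous:
                        choices.append((off, b))
            if not choices:
                continue
            off, alt_cds = choices[int(rng.integers(len(choices)))]
            cds_off = 3 * ci + off
            gpos = int(self.positions[cds_off])
            ref_cds = self.cds[cds_off]
            if self.gene.strand == "+":
                ref_g, alt_g = ref_cds, alt_cds
            else:
                ref_g, alt_g = ref_cds.translate(_COMP), alt_cds.translate(_COMP)
            self.used_codons.add(ci)
            return gpos, ref_g, alt_g, cds_off
        return None

    def classify_snp(self, gpos: int, alt_g: str) -> str | None:
        """missense/synonymous/None(stop created) for a genome-coordinate SNP."""
        hits = np.flatnonzero(self.positions == gpos)
        if len(hits) == 0:
            return "intron"
        off = int(hits[0])
        alt_cds = alt_g if self.gene.strand == "+" else alt_g.translate(_COMP)
        ci = off // 3
        codon = self.cds[3 * ci : 3 * ci + 3]
        within = off % 3
        new = codon[:within] + alt_cds + codon[within + 1 :]
        if new in _STOPS or ci in self.used_codons:
            return None
        self.used_codons.add(ci)
        return "synonymous_variant" if _CODON_AA[new] == _CODON_AA[codon] else "missense_variant"


def simulate_variants(
    config: SimConfig,
    genome: dict[str, np.ndarray],
    genes: list[GeneModel],
    panel: _Panel,
    rng: np.random.Generator,
    driver_variants: list[dict],
    cpg_grid: dict[str, np.ndarray],
    planted_dmrs: list[dict] | None = None,
):
    """Background + planted variants; returns (variant frame, dosage, manifest parts)."""
    records: list[dict] = []
    used: dict[str, set[int]] = {c: set() for c in genome}
    cds_maps = {g.gene_id: _CdsMap(g, genome) for g in genes}
    gene_lookup: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_lookup.setdefault(g.chromosome, []).append(g)

    def gene_at(chrom: str, pos: int) -> GeneModel | None:
        for g in gene_lookup.get(chrom, ()):
            if g.start <= pos <= g.end:
                return g
        return None

    def add(chrom, pos, ref, alt, consequence, impact, gene_id, dosage, mq=60.0,
            dp_floor=0, truth=None):
        used[chrom].update(range(pos, pos + len(ref)))
        records.append(
            dict(chrom=chrom, pos=pos, ref=ref, alt=alt, consequence=consequence,
                 impact=impact, gene_id=gene_id, dosage=dosage, mq=mq,
                 dp_floor=dp_floor, truth=truth)
        )

    manifest: dict = {"ccvs": [], "cg_loss": [], "selection": [], "drivers": []}

    # --- cis-driver variants first (their positions are already finalised) --
    for dv in driver_variants:
        cons, impact, gid = "intergenic_region", "MODIFIER", ""
        g_here = gene_at(dv["chrom"], dv["pos"])
        if g_here is not None:
            gid = g_here.gene_id
            cls = None
            for cand_alt in [dv["alt"]] + [
                b for b in "ACGT" if b not in (dv["alt"], dv["ref"])
            ]:
                cls = cds_maps[gid].classify_snp(dv["pos"], cand_alt)
                if cls is not None:
                    dv["alt"] = cand_alt
                    break
            if cls is None:  # cannot happen before other CDS planting
                raise ValueError("no stop-free alt allele for a driver variant")
            if cls == "intron":
                cons, impact = "intron_variant", "MODIFIER"
            else:
                cons = cls
                impact = "LOW" if cls == "synonymous_variant" else "MODERATE"
        add(dv["chrom"], dv["pos"], dv["ref"], dv["alt"], cons,
            impact, gid, dv["dosage"], dp_floor=10, truth="driver")
        manifest["drivers"].append(
            dict(chrom=dv["chrom"], pos=dv["pos"], ref=dv["ref"], alt=dv["alt"],
                 dmr=[dv["dmr_chrom"], dv["dmr_start"], dv["dmr_end"]])
        )

    # --- planted CCVs -------------------------------------------------------
    nh_idx = np.flatnonzero(~panel.sheet_df["is_hybrid"].to_numpy())
    for carrier, reference, count in config.planted_ccvs:
        idx_c = panel.clade_idx(carrier)
        idx_r = panel.clade_idx(reference)
        outside = [i for i in nh_idx if i not in set(idx_c) | set(idx_r)]
        for _ in range(count):
            impact_class = ["frameshift", "stop_gain", "stop_loss", "start_loss",
                            "splicing"][int(rng.integers(5))]
            genic = rng.random() < config.ccv_genic_fraction
            chrom = pos = ref = alt = None
            gene_id = ""
            for _try in range(300):
                if genic:
                    g = genes[int(rng.integers(len(genes)))]
                    cand = int(rng.integers(g.start, g.end + 1))
                    in_cds = any(s <= cand <= e for s, e in g.cds_segments)
                    # SNP-class CCVs stay out of the CDS (a real planted stop
                    # would corrupt the consensus translation); frameshift
                    # INDELs may sit anywhere in the gene body.
                    if impact_class != "frameshift" and in_cds:
                        continue
                    gene_hit = g.gene_id
                else:
                    c = list(genome)[int(rng.integers(len(genome)))]
                    cand = int(rng.integers(500, config.chrom_length - 500))
                    if gene_at(c, cand) is not None:
                        continue
                    g = None
                    gene_hit = ""
                c = g.chromosome if g is not None else c
                seq = genome[c]
                span = 4 if impact_class == "frameshift" else 1
                if any(p in used[c] for p in range(cand, cand + span + 1)):
                    continue
                if not _cpg_free(seq, cand - 1, cand - 1 + span):
                    continue
                refbase = seq[cand - 1].decode()
                if impact_class == "frameshift":
                    if rng.random() < 0.5:  # insertion
                        ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                        ref, alt = refbase, refbase + ins
                    else:  # deletion
                        dlen = int(rng.integers(1, 4))
                        ref = "".join(
                            seq[cand - 1 : cand + dlen].astype("U1")
                        )
                        alt = refbase
                        if not _cpg_free(seq, cand - 1, cand - 1 + dlen + 1):
                            continue
                else:
                    alts = [b for b in "ACGT" if b != refbase]
                    ref, alt = refbase, alts[int(rng.integers(3))]
                chrom, pos, gene_id = c, cand, gene_hit
                break
            if chrom is None:
                raise ValueError("could not place a planted CCV; genome too crowded")
            d = np.zeros(panel.n, dtype=np.int8)
            d[idx_c] = 2
            d[idx_r] = 0
            if outside:
                d[outside[0]] = 1  # pins the variant to this clade pair alone
            for h, (pa, pb) in panel.hybrid_parents.items():
                in_carrier = {pa, pb} & {
                    panel.sheet_df["species"].iloc[i] for i in idx_c
                }
                d[h] = len(in_carrier)
            consequence = HIGH_CONSEQUENCES[impact_class]
            add(chrom, pos, ref, alt, consequence, "HIGH", gene_id, d, dp_floor=10,
                truth="ccv")
            manifest["ccvs"].append(
                dict(chrom=chrom, pos=pos, ref=ref, alt=alt, impact_class=impact_class,
                     carrier=carrier, reference=reference, gene_id=gene_id)
            )

    # --- planted selection-class genes -------------------------------------
    carrier_sp = config.selection_comparison[0]
    eligible = [g for g in genes if g.dnds_eligible]
    order = rng.permutation(len(eligible))
    chosen = [eligible[i] for i in order[: config.n_positive_genes + config.n_purifying_genes]]
    selection_gene_ids = {g.gene_id for g in chosen}
    for rank, g in enumerate(chosen):
        positive = rank < config.n_positive_genes
        cm = cds_maps[g.gene_id]
        n_nonsyn = config.positive_nonsyn if positive else 0
        n_syn = 1 if positive else 4
        placed = 0
        for synonymous, n_want in ((False, n_nonsyn), (True, n_syn)):
            for _ in range(n_want):
                got = cm.plant(rng, synonymous=synonymous)
                if got is None:
                    continue
                gpos, refb, altb, _off = got
                if gpos in used[g.chromosome] or not _cpg_free(
                    genome[g.chromosome], gpos - 1, gpos
                ):
                    continue
                d = panel.branch_dosage("species", carrier_sp, rng)
                cons = "synonymous_variant" if synonymous else "missense_variant"
                impact = "LOW" if synonymous else "MODERATE"
                add(g.chromosome, gpos, refb, altb, cons, impact, g.gene_id, d,
                    dp_floor=10, truth="selection")
                placed += 1
        manifest["selection"].append(
            dict(gene_id=g.gene_id, planted_class="positive" if positive else "purifying",
                 comparison=list(config.selection_comparison), n_substitutions=placed)
        )

    # --- CG-loss variants ---------------------------------------------------
    # keep planted DMR windows free of CG-loss so the two truth signals stay
    # attributable
    excluded_sites: set[tuple[str, int]] = set()
    for rec in planted_dmrs or ():
        excluded_sites.update((rec["chrom"], p) for p in rec.get("sites", ()))
    for chrom, grid in cpg_grid.items():
        candidates = [
            int(p)
            for p in grid
            if (chrom, int(p)) not in excluded_sites
            and p not in used[chrom]
            and (p + 1) not in used[chrom]
        ]
        n_loss = int(round(config.cg_loss_fraction * len(grid)))
        picks = rng.choice(len(candidates), size=min(n_loss, len(candidates)),
                           replace=False)
        for ci in np.sort(picks):
            p = candidates[int(ci)]
            seq = genome[chrom]
            consequence_override = None
            if rng.random() < config.cg_loss_indel_fraction:
                ref = seq[p - 1].decode() + seq[p].decode()
                alt = seq[p - 1].decode()  # deletes the G
                vpos = p
            else:
                if rng.random() < 0.5:
                    vpos, refb = p, "C"
                    alt_pool = ["T", "A", "G"]
                else:
                    vpos, refb = p + 1, "G"
                    alt_pool = ["A", "T", "C"]
                ref = refb
                alt = alt_pool[int(rng.integers(3))]
                gene_here = gene_at(chrom, vpos)
                if gene_here is not None and gene_here.gene_id in selection_gene_ids:
                    continue
                if gene_here is not None:
                    # a CpG inside a CDS: pick an alt that does not create a
                    # premature stop; skip the site if none exists
                    cm = cds_maps[gene_here.gene_id]
                    cls = None
                    for cand_alt in [alt] + [b for b in alt_pool if b != alt]:
                        cls = cm.classify_snp(vpos, cand_alt)
                        if cls is not None:
                            alt = cand_alt
                            break
                    if cls is None:
                        continue
                    if cls != "intron":
                        consequence_override = cls
            kind = ("lineage", "species", "sample")[
                int(rng.choice(3, p=[0.2, 0.6, 0.2]))
            ]
            if kind == "lineage":
                which = list(panel.lineage_idx)[int(rng.integers(len(panel.lineage_idx)))]
            elif kind == "species":
                which = list(panel.species_idx)[int(rng.integers(len(panel.species_idx)))]
            else:
                which = int(nh_idx[int(rng.integers(len(nh_idx)))])
            d = panel.branch_dosage(kind, which, rng)
            gene = gene_at(chrom, vpos)
            if consequence_override is not None:
                cons = consequence_override
                impact = "LOW" if cons == "synonymous_variant" else "MODERATE"
            elif gene is None:
                cons, impact = "intergenic_region", "MODIFIER"
            else:
                cons, impact = "intron_variant", "MODIFIER"
            add(chrom, vpos, ref, alt, cons, impact, gene.gene_id if gene else "", d,
                dp_floor=10, truth="cg_loss")
            manifest["cg_loss"].append(
                dict(chrom=chrom, cpg_pos=p, variant_pos=vpos, ref=ref, alt=alt)
            )

    # --- background variants ------------------------------------------------
    n_background = int(config.variant_rate * config.chrom_length * config.n_chromosomes)
    probs = np.asarray(config.branch_probs, dtype=float)
    probs = probs / probs.sum()
    n_low_mq = 20
    for bi in range(n_background):
        chrom = list(genome)[int(rng.integers(len(genome)))]
        seq = genome[chrom]
        for _try in range(50):
            pos = int(rng.integers(200, config.chrom_length - 200))
            is_indel = rng.random() < config.indel_fraction
            span = int(rng.integers(1, 4)) + 1 if is_indel else 1
            if any(p in used[chrom] for p in range(pos, pos + span + 1)):
                continue
            if not _cpg_free(seq, pos - 1, pos - 1 + span):
                continue
            refbase = seq[pos - 1].decode()
            gene = gene_at(chrom, pos)
            gene_id = gene.gene_id if gene else ""
            if gene is not None and gene.gene_id in selection_gene_ids:
                continue  # planted selection classes stay uncontaminated
            if is_indel:
                if rng.random() < 0.5:
                    ins = "".join(rng.choice(list("ACGT"), size=span - 1))
                    ref, alt = refbase, refbase + ins
                else:
                    ref = "".join(seq[pos - 1 : pos - 1 + span].astype("U1"))
                    alt = refbase
                consequence = "intergenic_region" if gene is None else "intron_variant"
                impact = "MODIFIER"
            else:
                alts = [b for b in "ACGT" if b != refbase]
                alt = alts[int(rng.integers(3))]
                ref = refbase
                consequence, impact = "intergenic_region", "MODIFIER"
                if gene is not None:
                    cls = cds_maps[gene.gene_id].classify_snp(pos, alt)
                    if cls is None:  # would create a premature stop
                        continue
                    if cls == "intron":
                        consequence, impact = "intron_variant", "MODIFIER"
                    else:
                        consequence = cls
                        impact = "LOW" if cls == "synonymous_variant" else "MODERATE"
            kind_i = int(rng.choice(3, p=probs))
            kind = ("lineage", "species", "sample")[kind_i]
            if kind == "lineage":
                which = list(panel.lineage_idx)[int(rng.integers(len(panel.lineage_idx)))]
            elif kind == "species":
                which = list(panel.species_idx)[int(rng.integers(len(panel.species_idx)))]
            else:
                which = int(nh_idx[int(rng.integers(len(nh_idx)))])
            d = panel.branch_dosage(kind, which, rng)
            mq = 15.0 if bi < n_low_mq else 60.0
            add(chrom, pos, ref, alt, consequence, impact, gene_id, d, mq=mq)
            break

    frame = pd.DataFrame(records).sort_values(["chrom", "pos"]).reset_index(drop=True)
    dosage = np.vstack(frame.pop("dosage").to_numpy())
    return frame, dosage, manifest


# ------------------------------------------------------------------ methylome


def plan_dmrs(
    config: SimConfig,
    cpg_grid: dict[str, np.ndarray],
    panel: _Panel,
    genes: list[GeneModel],
    rng: np.random.Generator,
    window: int = 100,
):
    """Choose planted DMR windows (>= dmr_min_sites CpGs) and driver variants.

    Per comparison, ~``dmr_genic_fraction`` of the windows are placed inside
    gene bodies in runs long enough to exceed the 20% DMG rule; the rest are
    intergenic. ``cis_driver_fraction`` of the first comparison's windows get
    a clade-correlated driver variant and dosage-keyed methylation.
    """
    window_sites: dict[tuple[str, int], np.ndarray] = {}
    for chrom, grid in cpg_grid.items():
        wid = (grid - 1) // window
        for w in np.unique(wid):
            sites = grid[wid == w]
            if len(sites) >= config.dmr_min_sites:
                window_sites[(chrom, int(w) * window)] = sites

    gene_windows: dict[str, list[tuple[str, int]]] = {}
    genic_keys: set[tuple[str, int]] = set()
    for g in genes:
        inside = []
        w0 = ((g.start - 1) // window + (1 if (g.start - 1) % window else 0)) * window
        for ws in range(w0, g.end - window + 1, window):
            key = (g.chromosome, ws)
            if key in window_sites:
                inside.append(key)
        gene_windows[g.gene_id] = inside
        genic_keys.update(
            (g.chromosome, ws)
            for ws in range(((g.start - 1) // window) * window, g.end, window)
        )

    used: set[tuple[str, int]] = set()
    planted = []
    driver_variants = []
    free_keys = sorted(k for k in window_sites if k not in genic_keys)
    free_order = list(rng.permutation(len(free_keys)))
    gene_order = [genes[i].gene_id for i in rng.permutation(len(genes))]
    gene_cursor = 0

    def make_rec(key, ga, gb, gene_id=""):
        chrom, wstart = key
        used.add(key)
        return dict(comparison=[ga, gb], chrom=chrom, start=wstart,
                    end=wstart + window, delta_beta=config.dmr_delta_beta,
                    sites=[int(s) for s in window_sites[key]], gene_id=gene_id,
                    driver=None)

    for entry_i, (ga, gb, count) in enumerate(config.planted_dmrs):
        n_driver = (
            int(round(count * config.cis_driver_fraction)) if entry_i == 0 else 0
        )
        n_genic = int(round(count * config.dmr_genic_fraction))
        placed_genic = 0
        while placed_genic < n_genic and gene_cursor < len(gene_order):
            gid = gene_order[gene_cursor]
            gene_cursor += 1
            g = next(x for x in genes if x.gene_id == gid)
            need = int((g.end - g.start + 1) * 0.2 // window) + 1
            avail = [k for k in gene_windows[gid] if k not in used]
            if len(avail) < need:
                continue
            for key in avail[:need]:
                planted.append(make_rec(key, ga, gb, gene_id=gid))
                placed_genic += 1
        n_random = count - placed_genic
        placed_driver = 0
        for _ in range(n_random):
            while free_order:
                key = free_keys[free_order.pop(0)]
                if key not in used:
                    break
            else:
                raise ValueError("not enough CpG-bearing windows for the DMR plan")
            rec = make_rec(key, ga, gb)
            if placed_driver < n_driver:
                chrom, wstart = key
                offset = int(rng.integers(-400, 401))
                vpos = max(2, wstart + 50 + offset)
                # the driver allele is clade-correlated (freq 0.9 vs 0.1 in
                # the compared clades, 0.5 elsewhere) so the window is both
                # group-differential and dosage-keyed beyond the group labels
                freq = np.full(panel.n, 0.5)
                freq[panel.clade_idx(ga)] = 0.9
                freq[panel.clade_idx(gb)] = 0.1
                dosage = rng.binomial(2, freq).astype(np.int8)
                rec["driver"] = dict(pos=vpos)
                driver_variants.append(
                    dict(chrom=chrom, pos=vpos, ref="?", alt="?", dosage=dosage,
                         dmr_chrom=chrom, dmr_start=wstart, dmr_end=wstart + window,
                         window_sites=[int(s) for s in window_sites[key]])
                )
                placed_driver += 1
            planted.append(rec)
    return planted, driver_variants


def _finalize_driver_alleles(driver_variants, genome, used_positions):
    """Assign real ref/alt once the genome exists; nudge off CpGs/collisions."""
    for dv in driver_variants:
        seq = genome[dv["chrom"]]
        pos = dv["pos"]
        for cand in range(pos, pos + 50):
            if cand in used_positions[dv["chrom"]]:
                continue
            if not _cpg_free(seq, cand - 1, cand):
                continue
            refbase = seq[cand - 1].decode()
            alts = [b for b in "ACGT" if b != refbase]
            dv["pos"] = cand
            dv["ref"] = refbase
            dv["alt"] = alts[0]
            used_positions[dv["chrom"]].add(cand)
            break
        else:
            raise ValueError("could not finalise a driver variant position")


def simulate_methylomes(
    config: SimConfig,
    cpg_grid: dict[str, np.ndarray],
    panel: _Panel,
    planted_dmrs: list[dict],
    variant_frame: pd.DataFrame,
    dosage: np.ndarray,
    manifest: dict,
    rng: np.random.Generator,
) -> MethylationMatrix:
    """Latent beta -> depths -> beta-binomial counts for every CpG x sample."""
    chroms = []
    positions = []
    for chrom in cpg_grid:
        chroms.extend([chrom] * len(cpg_grid[chrom]))
        positions.extend(int(p) for p in cpg_grid[chrom])
    sites = pd.DataFrame({"chrom": chroms, "pos": positions})
    n_sites, n = len(sites), panel.n

    # baseline: bimodal mixture, shared by all samples at a site
    (a1, b1, w1), (a2, b2, _w2) = config.beta_mixture
    comp = rng.random(n_sites) < w1
    beta0 = np.where(comp, rng.beta(a1, b1, n_sites), rng.beta(a2, b2, n_sites))
    beta0 = np.clip(beta0, 0.02, 0.98)

    species_list = list(panel.species_idx)
    if config.null_mode:
        latent = np.repeat(beta0[:, None], n, axis=1)
    else:
        sp_effect = {
            sp: np.clip(
                beta0 + rng.normal(0, config.species_effect_sd, n_sites), 0.02, 0.98
            )
            for sp in species_list
        }
        latent = np.empty((n_sites, n))
        for j in range(n):
            if j in panel.hybrid_parents:
                pa, pb = panel.hybrid_parents[j]
                latent[:, j] = (sp_effect[pa] + sp_effect[pb]) / 2
            else:
                latent[:, j] = sp_effect[panel.sheet_df["species"].iloc[j]]

    site_index = pd.MultiIndex.from_frame(sites)

    def rows_of(chrom: str, poslist) -> np.ndarray:
        return site_index.get_indexer(
            pd.MultiIndex.from_arrays([[chrom] * len(poslist), list(poslist)])
        )

    if not config.null_mode:
        dmr_key = {}
        for dv in manifest.get("drivers", []):
            dmr_key[(dv["dmr"][0], dv["dmr"][1])] = (dv["chrom"], dv["pos"])
        vkey = pd.MultiIndex.from_frame(variant_frame[["chrom", "pos"]])
        delta = config.dmr_delta_beta
        for rec in planted_dmrs:
            rows = rows_of(rec["chrom"], rec["sites"])
            rows = rows[rows >= 0]
            if rec["driver"] is not None:
                vchrom, vpos = dmr_key[(rec["chrom"], rec["start"])]
                vrow = vkey.get_indexer([(vchrom, vpos)])[0]
                dose = dosage[vrow].astype(float)
                dose[dose < 0] = 1.0
                r = config.driver_beta_range
                latent[np.ix_(rows, np.arange(n))] = np.clip(
                    0.5 - r / 2 + r * (dose / 2)[None, :], 0.02, 0.98
                )
            else:
                ga, gb = rec["comparison"]
                latent[np.ix_(rows, panel.clade_idx(ga))] = 0.5 + delta / 2
                latent[np.ix_(rows, panel.clade_idx(gb))] = 0.5 - delta / 2

        # CG-loss ablation keyed to carrier dosage
        loss = manifest.get("cg_loss", [])
        if loss:
            lchrom = [r["chrom"] for r in loss]
            lpos = [r["cpg_pos"] for r in loss]
            lrows = site_index.get_indexer(pd.MultiIndex.from_arrays([lchrom, lpos]))
            vrows = vkey.get_indexer(
                pd.MultiIndex.from_arrays(
                    [[r["chrom"] for r in loss], [r["variant_pos"] for r in loss]]
                )
            )
            for sr, vr in zip(lrows, vrows):
                if sr < 0 or vr < 0:
                    continue
                d = dosage[vr]
                hom = d == 2
                het = d == 1
                if hom.any():
                    latent[sr, hom] = rng.beta(1, 60, int(hom.sum()))
                latent[sr, het] = latent[sr, het] / 2

    if not config.null_mode and config.sample_effect_sd > 0:
        latent = np.clip(
            latent + rng.normal(0, config.sample_effect_sd, latent.shape), 0.005, 0.995
        )

    p_nb = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    depth = rng.negative_binomial(config.depth_dispersion, p_nb, size=(n_sites, n))
    if config.null_mode or config.bb_concentration <= 0:
        p_read = latent
    else:
        nu = config.bb_concentration
        p_read = rng.beta(np.maximum(latent * nu, 1e-6),
                          np.maximum((1 - latent) * nu, 1e-6))
    meth = rng.binomial(depth, p_read)
    return MethylationMatrix(
        sites, meth.astype(np.int32), depth.astype(np.int32), panel.samples, min_depth=3
    )


# --------------------------------------------------------------- file writers


def _write_fasta(genome: dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in genome.items():
            fh.write(f">{chrom}\n")
            s = arr.tobytes().decode()
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def _write_gff3(genes: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chromosome}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mid = f"{g.gene_id}.1"
            fh.write(
                f"{g.chromosome}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_segments):
                fh.write(
                    f"{g.chromosome}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mid}.cds{i};Parent={mid}\n"
                )


def _write_vcf(
    frame: pd.DataFrame,
    dosage: np.ndarray,
    samples: list[str],
    config: SimConfig,
    rng: np.random.Generator,
    path: Path,
) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    p_nb = config.vcf_depth_dispersion / (config.vcf_depth_dispersion + config.vcf_depth_mean)
    dp = rng.negative_binomial(config.vcf_depth_dispersion, p_nb,
                               size=(len(frame), len(samples)))
    floor = frame["dp_floor"].to_numpy()
    dp = np.maximum(dp, floor[:, None])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in frame["chrom"].unique():
            fh.write(f"##contig=<ID={chrom},length={config.chrom_length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
            "Allele|Annotation|Impact|Gene\">\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        cols = frame[["chrom", "pos", "ref", "alt", "consequence", "impact",
                      "gene_id", "mq"]].to_numpy()
        for i, (chrom, pos, ref, alt, cons, impact, gene, mq) in enumerate(cols):
            ann = f"{alt}|{cons}|{impact}|{gene}"
            fields = [
                str(chrom), str(pos), ".", str(ref), str(alt), "100", "PASS",
                f"MQ={float(mq):g};ANN={ann}", "GT:DP",
            ]
            fields += [f"{gt_map[int(g)]}:{int(d)}" for g, d in zip(dosage[i], dp[i])]
            fh.write("\t".join(fields) + "\n")


def _write_reports(mat: MethylationMatrix, out_dir: Path, rng: np.random.Generator) -> dict:
    """Per-sample cytosine reports; counts split read-by-read across strands."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    chrom = mat.sites["chrom"].to_numpy()
    pos = mat.sites["pos"].to_numpy()
    for j, sample in enumerate(mat.samples):
        meth = mat.meth[:, j]
        unmeth = mat.total[:, j] - meth
        meth_plus = rng.binomial(meth, 0.5)
        unmeth_plus = rng.binomial(unmeth, 0.5)
        n = len(pos)
        rows = pd.DataFrame(
            {
                "chrom": np.repeat(chrom, 2),
                "pos": np.dstack([pos, pos + 1]).reshape(-1),
                "strand": np.tile(["+", "-"], n),
                "meth": np.dstack([meth_plus, meth - meth_plus]).reshape(-1),
                "unmeth": np.dstack([unmeth_plus, unmeth - unmeth_plus]).reshape(-1),
                "context": "CG",
            }
        )
        p = out_dir / f"{sample}.CX_report.txt"
        rows.to_csv(p, sep="\t", header=False, index=False)
        paths[sample] = p
    return paths


# --------------------------------------------------------------- entry points


def generate_dataset(config: SimConfig, out_dir: str | Path) -> dict:
    """Emit the full synthetic bundle + truth manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    panel = _Panel(config)

    genome, genes, islands = simulate_reference(config, rng)
    grid = cpg_positions(genome)
    planted_dmrs, driver_variants = plan_dmrs(config, grid, panel, genes, rng)
    used_positions: dict[str, set[int]] = {c: set() for c in genome}
    _finalize_driver_alleles(driver_variants, genome, used_positions)
    frame, dosage, manifest = simulate_variants(
        config, genome, genes, panel, rng, driver_variants, grid, planted_dmrs
    )
    mat = simulate_methylomes(
        config, grid, panel, planted_dmrs, frame, dosage, manifest, rng
    )

    _write_fasta(genome, out / "reference.fa")
    _write_gff3(genes, out / "genes.gff3")
    _write_vcf(frame, dosage, panel.samples, config, rng, out / "variants.vcf")
    build_sample_sheet(config).to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    report_paths = _write_reports(mat, out / "reports", rng)

    manifest_full = {
        "seed": config.seed,
        "samples": panel.samples,
        "islands": islands.to_dict(orient="records"),
        "ccvs": manifest["ccvs"],
        "cg_loss": manifest["cg_loss"],
        "selection": manifest["selection"],
        "drivers": manifest["drivers"],
        "dmrs": [
            {k: v for k, v in rec.items() if k != "sites"} for rec in planted_dmrs
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest_full, fh, indent=1, sort_keys=True)
    config.to_yaml(out / "sim_config.yaml")
    islands.to_csv(out / "islands_truth.tsv", sep="\t", index=False)
    log.info(
        "synthetic bundle: %d variants, %d CpG sites, %d planted DMRs, %d CCVs",
        len(frame), mat.n_sites, len(planted_dmrs), len(manifest["ccvs"]),
    )
    return manifest_full


def simulate_methylation_matrix(
    n_windows: int = 20_000,
    sites_per_window: int = 4,
    n_per_group: tuple[int, int] = (6, 6),
    delta_beta: float = 0.4,
    n_planted: int = 0,
    depth_mean: float = 12.0,
    depth_dispersion: float = 5.0,
    sample_effect_sd: float = 0.03,
    bb_concentration: float = 30.0,
    null_mode: bool = False,
    window: int = 100,
    seed: int = 0,
):
    """In-memory two-group methylation panel over contiguous 100-bp windows.

    Returns (MethylationMatrix, idx_a, idx_b, set of planted (chrom, start)).
    In null mode every sample shares the site's latent beta and counts are
    binomial — the exact sampling null of the stratified test.
    """
    rng = np.random.default_rng(seed)
    na, nb = n_per_group
    n = na + nb
    offsets = np.linspace(5, window - 10, sites_per_window).astype(int)
    pos = (np.arange(n_windows)[:, None] * window + offsets[None, :] + 1).reshape(-1)
    n_sites = len(pos)
    sites = pd.DataFrame({"chrom": "SimChr", "pos": pos})

    comp = rng.random(n_sites) < 0.6
    beta0 = np.where(comp, rng.beta(8, 2, n_sites), rng.beta(2, 8, n_sites))
    beta0 = np.clip(beta0, 0.02, 0.98)
    latent = np.repeat(beta0[:, None], n, axis=1)

    planted = set()
    if n_planted and not null_mode:
        chosen = rng.choice(n_windows, size=n_planted, replace=False)
        for w in np.sort(chosen):
            rows = slice(w * sites_per_window, (w + 1) * sites_per_window)
            latent[rows, :na] = 0.5 + delta_beta / 2
            latent[rows, na:] = 0.5 - delta_beta / 2
            planted.add(("SimChr", int(w) * window))

    if not null_mode and sample_effect_sd > 0:
        latent = np.clip(latent + rng.normal(0, sample_effect_sd, latent.shape),
                         0.005, 0.995)
    p_nb = depth_dispersion / (depth_dispersion + depth_mean)
    depth = rng.negative_binomial(depth_dispersion, p_nb, size=(n_sites, n))
    if null_mode or bb_concentration <= 0:
        p_read = latent
    else:
        p_read = rng.beta(latent * bb_concentration, (1 - latent) * bb_concentration)
    meth = rng.binomial(depth, p_read)
    samples = [f"A{i + 1:02d}" for i in range(na)] + [f"B{i + 1:02d}" for i in range(nb)]
    mat = MethylationMatrix(sites, meth.astype(np.int32), depth.astype(np.int32),
                            samples, min_depth=3)
    return mat, np.arange(na), np.arange(na, n), planted
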