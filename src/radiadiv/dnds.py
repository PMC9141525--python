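"""Pairwise dN/dS via Nei-Gojobori (1986) with Jukes-Cantor correction.

Synonymous/nonsynonymous site counts are averaged over both sequences;
multi-hit codons average the difference counts over all substitution
pathways that avoid stop codons. Substitutions *to* a stop codon count as
nonsynonymous for site counting. dN/dS of 0 is reported whenever pN = 0 and
any synonymous divergence exists (even when the JC correction for pS is
saturated); a saturated class with positive divergence is undefined.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from .datamodel import GeneModel, GenotypeMatrix, SampleSheet

BASES = "TCAG"
CODON_TABLE = {}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(BASES):
    for _j, _b2 in enumerate(BASES):
        for _k, _b3 in enumerate(BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

CODONS = sorted(CODON_TABLE)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
IS_STOP = np.array([CODON_TABLE[c] == "*" for c in CODONS])


def _syn_sites(codon: str) -> float:
    """Fraction-of-synonymous-changes summed over the 3 positions."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE[alt] == aa and CODON_TABLE[alt] != "*":
                s += 1 / 3
    return s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over stop-free pathways."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if CODON_TABLE[nxt] == "*":
                blocked = True
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every pathway crosses a stop; fall back to all pathways
        for order in permutations(diff_pos):
            cur = c1
            sd = nd = 0.0
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if CODON_TABLE[nxt] == CODON_TABLE[cur] and CODON_TABLE[nxt] != "*":
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


_SYN_SITES = np.array([_syn_sites(c) if CODON_TABLE[c] != "*" else np.nan for c in CODONS])
_SD_TABLE = np.zeros((64, 64))
_ND_TABLE = np.zeros((64, 64))
for _a in range(64):
    for _b in range(64):
        if IS_STOP[_a] or IS_STOP[_b]:
            continue
        _SD_TABLE[_a, _b], _ND_TABLE[_a, _b] = _pathway_diffs(CODONS[_a], CODONS[_b])


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    idx = np.array([CODON_INDEX.get(seq[i : i + 3], -1) for i in range(0, len(seq), 3)])
    if (idx < 0).any():
        raise ValueError("non-ACGT codon in CDS")
    if IS_STOP[idx].any():
        raise ValueError("stop codon inside CDS")
    return idx


def _jc(p: float) -> float:
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return np.inf
    return -0.75 * np.log(1 - 4 * p / 3)


def ng86_dnds(cds_a: str, cds_b: str) -> tuple[float, float, float | None]:
    """Return (dN, dS, dN/dS or None) for two in-frame equal-length CDSs."""
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS length mismatch")
    ca, cb = _encode(cds_a), _encode(cds_b)
    S = float(np.sum((_SYN_SITES[ca] + _SYN_SITES[cb]) / 2))
    N = 3 * len(ca) - S
    Sd = float(np.sum(_SD_TABLE[ca, cb]))
    Nd = float(np.sum(_ND_TABLE[ca, cb]))
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc(pS)
    dN = _jc(pN)
    if Sd == 0 and Nd == 0:
        return 0.0, 0.0, None  # identical sequences: ratio undefined
    if dN == 0:
        return dN, dS, 0.0 if (dS > 0 or np.isinf(dS)) else None
    if dS == 0 or np.isinf(dS) or np.isinf(dN):
        return dN, dS, None
    return dN, dS, dN / dS


def consensus_cds(
    gene: GeneModel,
    reference,
    geno: GenotypeMatrix,
    sample_idx: int,
) -> str:
    """Reference CDS with the sample's homozygous-alt SNPs substituted.

    Heterozygous calls and INDELs are left at the reference base (the
    biological consequence of a het is not affirmable at consensus level).
    ``reference`` is a pyfaidx.Fasta-like mapping chrom -> sequence.
    """
    if not gene.dnds_eligible:
        raise ValueError(f"gene {gene.gene_id} not eligible for dN/dS")
    chrom_seq = reference[gene.chromosome]
    pieces = []
    sites = geno.sites
    on_gene = (
        (sites["chrom"] == gene.chromosome)
        & sites["is_snp"].astype(bool)
        & (geno.dosage[:, sample_idx] == 2)
    ).to_numpy()
    snp_pos = sites.loc[on_gene, "pos"].to_numpy()
    snp_ref = sites.loc[on_gene, "ref"].to_numpy()
    snp_alt = sites.loc[on_gene, "alt"].to_numpy()
    for seg_start, seg_end in gene.cds_segments:  # 1-based inclusive
        seq = np.frombuffer(
            str(chrom_seq[seg_start - 1 : seg_end]).upper().encode(), dtype="S1"
        ).copy()
        in_seg = (snp_pos >= seg_start) & (snp_pos <= seg_end)
        for p, r, a in zip(snp_pos[in_seg], snp_ref[in_seg], snp_alt[in_seg]):
            off = p - seg_start
            if seq[off] != r.encode():
                raise ValueError(
                    f"SNP ref allele {r} at {gene.chromosome}:{p} does not match reference"
                )
            seq[off] = a.encode()
        pieces.append(seq.tobytes().decode())
    cds = "".join(pieces)
    if gene.strand == "-":
        cds = _revcomp(cds)
    return cds


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def classify_selection(
    genes: list[GeneModel],
    comparison: tuple[str, str],
    sheet: SampleSheet,
    geno: GenotypeMatrix,
    reference,
    quantile: float = 0.05,
) -> pd.DataFrame:
    """Per-gene mean cross-clade dN/dS with 5% tail selection classes.

    The mean is over all defined pairwise ratios between samples of the two
    clades; the top ``quantile`` of defined means is classed positive, the
    bottom ``quantile`` purifying (closed thresholds, ties included).
    """
    cladeA, cladeB = comparison
    idxA = sheet.clade_indices(cladeA)
    idxB = sheet.clade_indices(cladeB)
    records = []
    for gene in genes:
        if not gene.dnds_eligible:
            records.append((gene.gene_id, np.nan))
            continue
        cache: dict[int, np.ndarray] = {}

        def codons_for(i: int, gene=gene) -> np.ndarray:
            if i not in cache:
                cache[i] = _encode(consensus_cds(gene, reference, geno, i))
            return cache[i]

        ratios = []
        for i in idxA:
            for j in idxB:
                ca, cb = codons_for(int(i)), codons_for(int(j))
                S = float(np.sum((_SYN_SITES[ca] + _SYN_SITES[cb]) / 2))
                N = 3 * len(ca) - S
                Sd = float(np.sum(_SD_TABLE[ca, cb]))
                Nd = float(np.sum(_ND_TABLE[ca, cb]))
                if Sd == 0 and Nd == 0:
                    continue
                dS = _jc(Sd / S if S > 0 else 0.0)
                dN = _jc(Nd / N if N > 0 else 0.0)
                if dN == 0 and (dS > 0 or np.isinf(dS)):
                    ratios.append(0.0)
                elif dS == 0 or np.isinf(dS) or np.isinf(dN):
                    continue
                else:
                    ratios.append(dN / dS)
        records.append((gene.gene_id, float(np.mean(ratios)) if ratios else np.nan))
    df = pd.DataFrame(records, columns=["gene_id", "mean_dnds"])
    df["comparison"] = f"{cladeA}|{cladeB}"
    defined = df["mean_dnds"].notna()
    df["selection_class"] = "undefined"
    if defined.any():
        vals = df.loc[defined, "mean_dnds"]
        hi = vals.quantile(1 - quantile)
        lo = vals.quantile(quantile)
        df.loc[defined & (df["mean_dnds"] >= hi), "selection_class"] = "positive"
        df.loc[defined & (df["mean_dnds"] <= lo), "selection_class"] = "purifying"
        df.loc[defined & (df["selection_class"] == "undefined"), "selection_class"] = "neutral"
    return df[["gene_id", "comparison", "mean_dnds", "selection_class"]]
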