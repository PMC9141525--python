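"""Readers and writers for the external formats the pipeline consumes.

Readers validate into the :mod:`radiadiv.datamodel` containers; writers emit
BED (0-based half-open), TSV result tables and newick trees. Every writer's
output re-parses to an equal in-memory structure.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    GeneModel,
    GenotypeMatrix,
    MethylationMatrix,
    SampleSheet,
    ValidationError,
)

log = logging.getLogger(__name__)

CCV_COLUMNS = [
    "gene_id",
    "carrier_clade",
    "reference_clade",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "impact_class",
    "context",
]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Parse the TSV sample sheet (sample_id, species, lineage, is_hybrid)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species": str, "lineage": str})
    if "is_hybrid" in df.columns:
        df["is_hybrid"] = (
            df["is_hybrid"].astype(str).str.strip().str.lower().map(
                {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
            )
        )
        if df["is_hybrid"].isna().any():
            bad = df.loc[df["is_hybrid"].isna(), "sample_id"].tolist()
            raise ValidationError(f"unparseable is_hybrid flag for sample(s): {bad}")
        df["is_hybrid"] = df["is_hybrid"].astype(bool)
    return SampleSheet(df)


def _parse_ann(info_ann: str | None, alt: str) -> tuple[str, str, str]:
    """First ANN entry matching ``alt``: (consequence, impact, gene_id)."""
    if not info_ann:
        return "unknown", "MODIFIER", ""
    for entry in str(info_ann).split(","):
        fields = entry.split("|")
        if len(fields) < 3:
            raise ValidationError(
                "annotation field is not SnpEff-style ANN (allele|consequence|impact|gene)"
            )
        if fields[0] == alt:
            gene = fields[3] if len(fields) > 3 else ""
            return fields[1], fields[2], gene
    return "unknown", "MODIFIER", ""


def read_vcf_variants(
    path: str | Path,
    sheet: SampleSheet,
    min_depth: int = 3,
    min_mq: float = 20.0,
    max_missing: float = 0.01,
) -> GenotypeMatrix:
    """Read and QC-filter a VCF into a :class:`GenotypeMatrix`.

    Per-sample genotypes with DP <= ``min_depth`` are set missing, then the
    whole record is dropped when the missing-call fraction is >= ``max_missing``
    or site MQ <= ``min_mq``. Multiallelic records are split into biallelic
    rows (other alt alleles count as reference).
    """
    vcf = VCF(str(path))
    order = []
    vcf_samples = list(vcf.samples)
    for s in sheet.sample_ids:
        if s not in vcf_samples:
            raise ValidationError(f"sample {s!r} from sheet not present in VCF")
        order.append(vcf_samples.index(s))
    order = np.asarray(order)

    rows, dosages = [], []
    n_dropped_missing = 0
    n_malformed = 0
    n_missing_ann = 0
    for v in vcf:
        if v.INFO.get("MQ") is not None and float(v.INFO.get("MQ")) <= min_mq:
            continue
        try:
            gts = np.asarray(v.genotypes, dtype=object)
            alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int16)
        except (TypeError, ValueError, IndexError):
            n_malformed += 1
            continue
        alleles = alleles[order]
        dp = v.format("DP")
        low_dp = np.zeros(len(order), dtype=bool)
        if dp is not None:
            dpv = dp.astype(float).reshape(-1)[order]
            low_dp = ~(dpv > min_depth)
        ann = v.INFO.get("ANN")
        if ann is None:
            n_missing_ann += 1
        for k, alt in enumerate(v.ALT, start=1):
            missing = (alleles < 0).any(axis=1) | low_dp
            dosage = (alleles == k).sum(axis=1).astype(np.int8)
            dosage[missing] = -1
            if missing.mean() >= max_missing:
                n_dropped_missing += 1
                continue
            consequence, impact, gene_id = _parse_ann(ann, alt)
            rows.append(
                {
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": alt,
                    "consequence": consequence,
                    "impact": impact,
                    "gene_id": gene_id,
                    "is_snp": len(v.REF) == 1 and len(alt) == 1,
                }
            )
            dosages.append(dosage)
    if n_missing_ann:
        log.warning("%d records had no ANN field; consequence set to 'unknown'", n_missing_ann)
    if n_malformed:
        log.warning("%d records dropped for malformed genotypes", n_malformed)
    log.info("VCF %s: kept %d records, dropped %d for missingness", path, len(rows), n_dropped_missing)
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "consequence", "impact", "gene_id", "is_snp"]
    )
    dmat = (
        np.vstack(dosages).astype(np.int8)
        if dosages
        else np.zeros((0, sheet.n_samples), dtype=np.int8)
    )
    return GenotypeMatrix(sites, dmat, sheet.sample_ids)


_REPORT_COLS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context"]


def read_cytosine_report(
    paths: dict[str, str | Path],
    min_depth: int = 3,
    merge_strands: bool = True,
) -> MethylationMatrix:
    """Read per-sample cytosine reports (Bismark CX dialect) into one matrix.

    Only CG-context rows are used. With ``merge_strands`` the minus-strand
    call of a symmetric CpG (position of the G) is added to the plus-strand C
    at position - 1. Sites with total < ``min_depth`` in a sample are treated
    as missing downstream, not as zero methylation.
    """
    per_sample: dict[str, pd.DataFrame] = {}
    for sample, path in paths.items():
        df = pd.read_csv(path, sep="\t", names=_REPORT_COLS, dtype={"chrom": str})
        if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
            raise ValidationError(f"negative counts in cytosine report {path}")
        df = df[df["context"] == "CG"]
        pos = df["pos"].to_numpy().copy()
        if merge_strands:
            pos[df["strand"].to_numpy() == "-"] -= 1
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].to_numpy(),
                "pos": pos,
                "meth": df["count_meth"].to_numpy(),
                "total": (df["count_meth"] + df["count_unmeth"]).to_numpy(),
            }
        )
        out = out.groupby(["chrom", "pos"], as_index=False, sort=True).sum()
        per_sample[sample] = out

    grid = (
        pd.concat([d[["chrom", "pos"]] for d in per_sample.values()])
        .drop_duplicates()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(grid)
    n_sites, n_samples = len(grid), len(per_sample)
    meth = np.zeros((n_sites, n_samples), dtype=np.int32)
    total = np.zeros((n_sites, n_samples), dtype=np.int32)
    for j, (sample, d) in enumerate(per_sample.items()):
        idx = key.get_indexer(pd.MultiIndex.from_frame(d[["chrom", "pos"]]))
        meth[idx, j] = d["meth"].to_numpy()
        total[idx, j] = d["total"].to_numpy()
    return MethylationMatrix(grid, meth, total, list(per_sample), min_depth=min_depth)


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3; the first mRNA's CDS represents each gene."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(g, featuretype="mRNA", order_by="start"))
        if len(mrnas) > 1:
            log.info("gene %s has %d mRNAs; using the first", g.id, len(mrnas))
        parent = mrnas[0] if mrnas else g
        cds = [(c.start, c.end) for c in db.children(parent, featuretype="CDS", order_by="start")]
        gm = GeneModel(
            gene_id=g.attributes.get("ID", [g.id])[0],
            chromosome=g.seqid,
            start=g.start,
            end=g.end,
            strand=g.strand,
            cds_segments=cds,
        )
        if not gm.dnds_eligible:
            log.info("gene %s CDS length not divisible by 3; excluded from dN/dS", gm.gene_id)
        genes.append(gm)
    return genes


# ---------------------------------------------------------------- writers


def write_windows_bed(windows: pd.DataFrame, path: str | Path, value_col: str) -> None:
    """Windowed statistics as BED: chrom, start, end, name, value."""
    df = windows.copy()
    df["name"] = df["chrom"].astype(str) + ":" + df["start"].astype(str)
    df[["chrom", "start", "end", "name", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_windows_bed(path: str | Path, value_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "name", value_col],
                     dtype={"chrom": str})
    return df.drop(columns=["name"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_newick(tree, path: str | Path) -> None:
    from Bio import Phylo

    Phylo.write(tree, str(path), "newick")


def write_outputs(results: dict, out_dir: str | Path) -> list[Path]:
    """Write a result bundle: DataFrames as TSV, trees as newick.

    Keys ending in ``_bed`` are written as BED from (DataFrame, value_col)
    tuples. Raises before any partial write if ``out_dir`` is unusable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as e:  # pragma: no cover - environment dependent
        raise ValidationError(f"output directory not writable: {out}") from e
    written = []
    for name, obj in results.items():
        if name.endswith("_bed"):
            df, value_col = obj
            p = out / f"{name[:-4]}.bed"
            write_windows_bed(df, p, value_col)
        elif isinstance(obj, pd.DataFrame):
            p = out / f"{name}.tsv"
            write_table(obj, p)
        else:  # assume Bio.Phylo tree
            p = out / f"{name}.nwk"
            write_newick(obj, p)
        written.append(p)
    return written
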