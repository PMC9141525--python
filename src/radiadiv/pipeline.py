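"""End-to-end orchestration of the analysis stages behind one config.

Stage order: simulate (optional) -> io -> popgen / methylome -> ccv / dmr ->
integrate. Re-running with an unchanged config and seed reproduces every
output byte for byte. Every threshold lives in :class:`RunConfig`; stage
code never hard-codes one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import ccv as ccv_mod
from . import dmr as dmr_mod
from . import integrate as integrate_mod
from . import io as io_mod
from . import methylome as meth_mod
from . import popgen
from .dnds import classify_selection
from .simulate import SimConfig, generate_dataset

log = logging.getLogger(__name__)

STAGES = ("simulate", "io", "popgen", "ccv", "methylome", "dmr", "integrate")


def _default_comparisons() -> list:
    return [
        ["A_japonica", "A_oxysepala"],
        ["A_japonica", "American"],
        ["A_japonica", "European"],
        ["A_oxysepala", "American"],
        ["A_oxysepala", "European"],
        ["American", "European"],
    ]


@dataclass
class RunConfig:
    """All inputs, clade comparisons and thresholds of one pipeline run."""

    vcf: str = ""
    sample_sheet: str = ""
    gff: str = ""
    fasta: str = ""
    reports_dir: str = ""
    out_dir: str = "results"
    seed: int = 1
    comparisons: list = field(default_factory=_default_comparisons)
    pi_groups: list = field(default_factory=lambda: [
        "Asian", "European", "American", "A_japonica", "A_oxysepala"])
    mdi_reference_species: str = "A_viridiflora"
    # variant QC
    vcf_min_depth: int = 3
    vcf_min_mq: float = 20.0
    vcf_max_missing: float = 0.01
    # windowed scans
    popgen_window: int = 100_000
    tail_quantile: float = 0.05
    ld_window_snps: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2
    n_pcs_report: int = 10
    # methylome
    meth_min_depth: int = 3
    pca_coverage_fraction: float = 0.8
    mdi_window: int = 100_000
    profile_flank: int = 5000
    cgi_shore: int = 2000
    # DMR / DMG
    dmr_window: int = 100
    dmr_min_sites: int = 3
    dmr_alpha: float = 0.05
    dmr_min_divergence: float = 0.25
    dmg_threshold: float = 0.20
    # selection
    dnds_quantile: float = 0.05
    # integration
    driver_flank: int = 500
    driver_n_pcs: int = 10
    driver_thresholds: list = field(
        default_factory=lambda: [5e-5, 5e-6, 5e-7, 5e-8])
    # simulate stage
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in dependency order; returns result dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    results: dict = {}
    counts: dict = {}

    if "simulate" in stages:
        sim_dir = out / "synthetic"
        sim = SimConfig(**{"seed": config.seed, **config.sim})
        generate_dataset(sim, sim_dir)
        config.vcf = str(sim_dir / "variants.vcf")
        config.sample_sheet = str(sim_dir / "sample_sheet.tsv")
        config.gff = str(sim_dir / "genes.gff3")
        config.fasta = str(sim_dir / "reference.fa")
        config.reports_dir = str(sim_dir / "reports")

    analysis = [s for s in stages if s != "simulate"]
    if not analysis:
        return results

    for p, what in ((config.vcf, "vcf"), (config.sample_sheet, "sample_sheet"),
                    (config.gff, "gff"), (config.fasta, "fasta")):
        if not p or not Path(p).exists():
            raise PipelineError(f"missing input for stage 'io': {what} ({p!r})")

    sheet = io_mod.read_sample_sheet(config.sample_sheet)
    geno = io_mod.read_vcf_variants(
        config.vcf, sheet, min_depth=config.vcf_min_depth,
        min_mq=config.vcf_min_mq, max_missing=config.vcf_max_missing,
    )
    genes = io_mod.read_gff3_genes(config.gff)
    reference = Fasta(config.fasta)
    chrom_lengths = {name: len(reference[name]) for name in reference.keys()}
    counts["n_variants_qc"] = geno.n_sites
    counts["n_snps_qc"] = int(geno.sites["is_snp"].sum())
    counts["n_genes"] = len(genes)
    results.update(sheet=sheet, geno=geno, genes=genes, reference=reference,
                   chrom_lengths=chrom_lengths)

    mat = None
    if {"methylome", "dmr", "integrate"} & set(analysis):
        if not config.reports_dir or not Path(config.reports_dir).exists():
            raise PipelineError("missing input for methylome stages: reports_dir")
        paths = {
            s: Path(config.reports_dir) / f"{s}.CX_report.txt" for s in sheet.sample_ids
        }
        raw = io_mod.read_cytosine_report(paths, min_depth=config.meth_min_depth)
        mat = meth_mod.build_methylation_matrix(raw, min_depth=config.meth_min_depth)
        counts["n_cg_sites"] = mat.n_sites
        results["meth"] = mat

    if "popgen" in analysis:
        results["popgen"] = _run_popgen(config, sheet, geno, genes, reference,
                                        chrom_lengths, out, counts)
    if "ccv" in analysis:
        results["ccv"] = _run_ccv(config, sheet, geno, genes, out, counts)
    if "methylome" in analysis:
        results["methylome"] = _run_methylome(config, sheet, mat, genes, reference,
                                              chrom_lengths, out, counts)
    if "dmr" in analysis:
        results["dmr"] = _run_dmr(config, sheet, mat, genes, out, counts)
    if "integrate" in analysis:
        if "dmr" not in results:
            raise PipelineError("stage 'integrate' requires stage 'dmr' outputs")
        if "popgen" not in results:
            raise PipelineError("stage 'integrate' requires stage 'popgen' outputs")
        results["integrate"] = _run_integrate(config, sheet, geno, mat, genes,
                                              reference, results, out, counts)

    with open(out / "run_log.json", "w") as fh:
        json.dump(counts, fh, indent=1, sort_keys=True)
    results["counts"] = counts
    return results


def _run_popgen(config, sheet, geno, genes, reference, chrom_lengths, out, counts):
    snps = geno.snps_only()
    windows = popgen.make_windows(chrom_lengths, config.popgen_window)
    pi_by_clade = {}
    for clade in config.pi_groups:
        if not sheet.is_clade(clade):
            continue
        idx = sheet.clade_indices(clade)
        pi_by_clade[clade] = popgen.window_pi(snps, idx, windows)
    fst_by_pair = {}
    for a, b in config.comparisons:
        fst_by_pair[(a, b)] = popgen.window_fst(
            snps, sheet.clade_indices(a), sheet.clade_indices(b), windows
        )
    regions = popgen.select_ldgr_hdgr(
        pi_by_clade, fst_by_pair, low_q=config.tail_quantile, high_q=config.tail_quantile
    )
    pruned = popgen.ld_prune(snps, config.ld_window_snps, config.ld_step, config.ld_r2_max)
    counts["n_snps_ld_pruned"] = pruned.n_sites
    coords, ev = popgen.genotype_pca(pruned, n_components=config.n_pcs_report)
    pca_df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    pca_df.insert(0, "sample_id", sheet.sample_ids)

    dist = popgen.allele_sharing_distance(snps)
    trees = {"nj_genome": popgen.nj_tree(dist, sheet.sample_ids)}
    for chrom in chrom_lengths:
        sub = snps.subset_sites((snps.sites["chrom"] == chrom).to_numpy())
        if sub.n_sites >= 3:
            trees[f"nj_{chrom}"] = popgen.nj_tree(
                popgen.allele_sharing_distance(sub), sheet.sample_ids
            )

    selection = {}
    ref_seqs = {name: str(reference[name][:]) for name in chrom_lengths}
    for a, b in config.comparisons:
        selection[(a, b)] = classify_selection(
            genes, (a, b), sheet, geno, ref_seqs, quantile=config.dnds_quantile
        )
    outputs = {}
    for clade, df in pi_by_clade.items():
        outputs[f"pi_{clade}"] = df
        outputs[f"pi_{clade}_bed"] = (df, "pi")
    for (a, b), df in fst_by_pair.items():
        outputs[f"fst_{a}_vs_{b}"] = df
        outputs[f"fst_{a}_vs_{b}_bed"] = (df, "fst")
    outputs["pca_genotype"] = pca_df
    for (a, b), df in selection.items():
        outputs[f"selection_{a}_vs_{b}"] = df
    outputs.update(trees)
    io_mod.write_outputs(outputs, out / "popgen")
    counts["n_windows"] = len(windows)
    return dict(pi=pi_by_clade, fst=fst_by_pair, regions=regions, pca=pca_df,
                trees=trees, selection=selection, pruned=pruned)


def _run_ccv(config, sheet, geno, genes, out, counts):
    tables = []
    for a, b in config.comparisons:
        for carrier, referencec in ((a, b), (b, a)):
            t = ccv_mod.call_ccvs(geno, sheet, carrier, referencec)
            t = ccv_mod.annotate_ccv_context(t, genes)
            tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    io_mod.write_outputs({"ccv_table": table}, out / "ccv")
    counts["n_ccvs"] = len(table)
    counts["ccv_genic_fraction"] = (
        float((table["context"] == "genic").mean()) if len(table) else float("nan")
    )
    return table


def _run_methylome(config, sheet, mat, genes, reference, chrom_lengths, out, counts):
    levels = pd.DataFrame(
        {
            "sample_id": sheet.sample_ids,
            "global_methylation_pct": [
                meth_mod.global_methylation_level(mat, s) for s in sheet.sample_ids
            ],
        }
    )
    coords, ev = meth_mod.methylome_pca(
        mat, n_components=config.n_pcs_report, qc_fraction=config.pca_coverage_fraction
    )
    pca_df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    pca_df.insert(0, "sample_id", sheet.sample_ids)

    ref_sp = config.mdi_reference_species
    ref_sample = None
    if sheet.is_clade(ref_sp):
        ref_sample = sheet.table.loc[
            (sheet.table["species"] == ref_sp) & ~sheet.table["is_hybrid"], "sample_id"
        ].iloc[0]
    mdi_rows = []
    if ref_sample is not None:
        for s in sheet.sample_ids:
            for chrom in chrom_lengths:
                mdi_rows.append(
                    (s, chrom, meth_mod.compute_mdi(mat, s, ref_sample, chrom,
                                                    window=config.mdi_window))
                )
    mdi = pd.DataFrame(mdi_rows, columns=["sample_id", "chrom", "mdi"])

    islands = pd.concat(
        [
            meth_mod.detect_cg_islands(str(reference[chrom][:]), chromosome=chrom)
            for chrom in chrom_lengths
        ],
        ignore_index=True,
    )
    groups = meth_mod.group_indices(sheet, sheet.lineage_labels)
    gene_prof = meth_mod.gene_metaprofile(mat, genes, groups, flank=config.profile_flank)
    cgi_prof = meth_mod.cgi_metaprofile(mat, islands, groups, shore=config.cgi_shore)
    io_mod.write_outputs(
        {
            "global_levels": levels,
            "pca_methylome": pca_df,
            "mdi": mdi,
            "cg_islands": islands,
            "gene_metaprofile": gene_prof,
            "cgi_metaprofile": cgi_prof,
        },
        out / "methylome",
    )
    counts["n_cg_islands"] = len(islands)
    counts["mean_global_methylation_pct"] = float(
        levels["global_methylation_pct"].mean()
    )
    return dict(levels=levels, pca=pca_df, mdi=mdi, islands=islands,
                gene_profile=gene_prof, cgi_profile=cgi_prof)


def _run_dmr(config, sheet, mat, genes, out, counts):
    dmrs = {}
    dmgs = {}
    outputs = {}
    for a, b in config.comparisons:
        d = dmr_mod.scan_dmrs(
            mat, sheet, a, b, window=config.dmr_window, min_sites=config.dmr_min_sites,
            alpha=config.dmr_alpha, min_divergence=config.dmr_min_divergence,
        )
        g = dmr_mod.call_dmgs(d, genes, threshold=config.dmg_threshold)
        dmrs[(a, b)] = d
        dmgs[(a, b)] = g
        outputs[f"dmr_{a}_vs_{b}"] = d
        outputs[f"dmr_{a}_vs_{b}_bed"] = (d[d["is_dmr"]], "divergence")
        outputs[f"dmg_{a}_vs_{b}"] = g
        counts[f"n_dmrs_{a}_vs_{b}"] = int(d["is_dmr"].sum())
        counts[f"n_dmgs_{a}_vs_{b}"] = int(g["is_dmg"].sum())
    io_mod.write_outputs(outputs, out / "dmr")
    return dict(dmrs=dmrs, dmgs=dmgs)


def _run_integrate(config, sheet, geno, mat, genes, reference, results, out, counts):
    loci = integrate_mod.classify_cg_loss_loci(mat, geno, reference)
    counts["cg_loss_pct"] = float(100 * loci["carrying"].mean())
    regression = integrate_mod.cg_loss_regression_table(loci, mat, geno)
    variability = integrate_mod.variability_categories(mat)

    a, b = config.comparisons[0]
    dmrs = results["dmr"]["dmrs"][(a, b)]
    sig = dmrs[dmrs["is_dmr"]].reset_index(drop=True)
    pcs = integrate_mod.compute_structure_pcs(geno, n_pcs=config.driver_n_pcs)
    drivers = integrate_mod.cis_driver_scan(
        sig, geno, mat, flank=config.driver_flank, n_pcs=config.driver_n_pcs,
        thresholds=tuple(config.driver_thresholds), pcs=pcs,
    )
    if len(drivers):
        for thr, frac in drivers.attrs["associated_fraction"].items():
            counts[f"driver_associated_pct_p<{thr:g}"] = 100 * frac

    assoc_rows = []
    for a, b in config.comparisons:
        dmg = results["dmr"]["dmgs"][(a, b)]
        sel = results["popgen"]["selection"][(a, b)]
        try:
            assoc_rows.append(
                integrate_mod.dmg_selection_chisq(dmg, sel, f"{a}|{b}")
            )
        except ValueError as e:
            log.warning("association test skipped for %s vs %s: %s", a, b, e)
    assoc = (
        pd.concat(assoc_rows, ignore_index=True)
        if assoc_rows
        else pd.DataFrame()
    )
    thr_summary = pd.DataFrame(
        [
            {"threshold": thr, "associated_fraction": frac}
            for thr, frac in (drivers.attrs.get("associated_fraction", {}) or {}).items()
        ]
    )
    io_mod.write_outputs(
        {
            "cg_loss_loci": loci,
            "cg_loss_regression": regression,
            "variability_categories": variability,
            "driver_scan": drivers,
            "driver_threshold_summary": thr_summary,
            "dmg_selection_association": assoc,
        },
        out / "integrate",
    )
    return dict(loci=loci, regression=regression, variability=variability,
                drivers=drivers, association=assoc)
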