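"""Shared fixtures: synthetic bundles generated once per session."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pytest
from pyfaidx import Fasta

from radiadiv import io as io_mod
from radiadiv.methylome import build_methylation_matrix
from radiadiv.pipeline import RunConfig, run_pipeline
from radiadiv.simulate import SimConfig, generate_dataset


def small_sim_config(seed: int = 7) -> SimConfig:
    """A reduced panel (2 x 200 kb) that keeps every planted feature class."""
    return SimConfig(
        seed=seed,
        chrom_length=200_000,
        n_genes=30,
        n_islands=6,
        planted_ccvs=[
            ["A_japonica", "A_oxysepala", 3],
            ["A_oxysepala", "A_japonica", 3],
            ["Asian", "American", 2],
            ["European", "American", 2],
            ["European", "Asian", 2],
        ],
        planted_dmrs=[["A_japonica", "A_oxysepala", 12], ["Asian", "American", 6]],
        n_positive_genes=2,
        n_purifying_genes=2,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> dict:
    out = tmp_path_factory.mktemp("small_bundle")
    config = small_sim_config()
    manifest = generate_dataset(config, out)
    return {"dir": Path(out), "manifest": manifest, "config": config}


@pytest.fixture(scope="session")
def small_data(small_bundle) -> dict:
    d = small_bundle["dir"]
    sheet = io_mod.read_sample_sheet(d / "sample_sheet.tsv")
    geno = io_mod.read_vcf_variants(d / "variants.vcf", sheet)
    genes = io_mod.read_gff3_genes(d / "genes.gff3")
    paths = {s: d / "reports" / f"{s}.CX_report.txt" for s in sheet.sample_ids}
    mat = build_methylation_matrix(io_mod.read_cytosine_report(paths))
    reference = Fasta(str(d / "reference.fa"))
    return {
        "sheet": sheet,
        "geno": geno,
        "genes": genes,
        "mat": mat,
        "reference": reference,
        "manifest": small_bundle["manifest"],
        "dir": d,
    }


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory) -> dict:
    """The full bundled study design: 36 accessions, 2 x 1 Mb chromosomes."""
    out = tmp_path_factory.mktemp("default_bundle")
    config = SimConfig(seed=1)
    manifest = generate_dataset(config, out)
    return {"dir": Path(out), "manifest": manifest, "config": config}


@pytest.fixture(scope="session")
def default_data(default_bundle) -> dict:
    d = default_bundle["dir"]
    sheet = io_mod.read_sample_sheet(d / "sample_sheet.tsv")
    geno = io_mod.read_vcf_variants(d / "variants.vcf", sheet)
    genes = io_mod.read_gff3_genes(d / "genes.gff3")
    paths = {s: d / "reports" / f"{s}.CX_report.txt" for s in sheet.sample_ids}
    mat = build_methylation_matrix(io_mod.read_cytosine_report(paths))
    reference = Fasta(str(d / "reference.fa"))
    return {
        "sheet": sheet,
        "geno": geno,
        "genes": genes,
        "mat": mat,
        "reference": reference,
        "manifest": default_bundle["manifest"],
        "dir": d,
    }


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory) -> dict:
    """One full pipeline execution over the default bundle."""
    d = default_bundle["dir"]
    out = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(
        out_dir=str(out),
        seed=1,
        vcf=str(d / "variants.vcf"),
        sample_sheet=str(d / "sample_sheet.tsv"),
        gff=str(d / "genes.gff3"),
        fasta=str(d / "reference.fa"),
        reports_dir=str(d / "reports"),
    )
    results = run_pipeline(cfg, stages=("io", "popgen", "ccv", "methylome", "dmr",
                                        "integrate"))
    return {"results": results, "out": Path(out), "config": cfg,
            "manifest": default_bundle["manifest"], "bundle_dir": d}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def load_manifest(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
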