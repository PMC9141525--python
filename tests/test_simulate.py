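"""Synthetic-data generator: determinism, manifest completeness, planted
signal calibration."""

import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from radiadiv.methylome import detect_cg_islands
from radiadiv.simulate import (
    SimConfig,
    build_sample_sheet,
    generate_dataset,
    simulate_methylation_matrix,
)


def tiny_config(seed=3, **kw):
    base = dict(
        seed=seed,
        chrom_length=80_000,
        n_genes=10,
        n_islands=2,
        planted_ccvs=[["A_japonica", "A_oxysepala", 2]],
        planted_dmrs=[["A_japonica", "A_oxysepala", 4]],
        n_positive_genes=1,
        n_purifying_genes=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_dataset(tiny_config(), a)
        generate_dataset(tiny_config(), b)
        files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        assert files
        for f in files:
            assert filecmp.cmp(a / f, b / f, shallow=False), f

    def test_seed_changes_manifest(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_dataset(tiny_config(seed=3), a)
        generate_dataset(tiny_config(seed=4), b)
        assert (a / "manifest.json").read_text() != (b / "manifest.json").read_text()


class TestSampleDesign:
    def test_default_panel_is_three_lineages_ten_species_36_accessions(self):
        df = build_sample_sheet(SimConfig())
        assert len(df) == 36
        assert df["lineage"].nunique() == 3
        assert df.loc[~df["is_hybrid"], "species"].nunique() == 10
        assert df["is_hybrid"].sum() == 4

    def test_species_sample_minimum_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(lineage_spec={"L": {"sp": 1}})


class TestManifestCompleteness:
    def test_planted_ccvs_relocatable_with_correct_genotypes(self, small_data):
        geno = small_data["geno"]
        sheet = small_data["sheet"]
        key = {(c, p): i for i, (c, p) in enumerate(zip(geno.sites["chrom"],
                                                        geno.sites["pos"]))}
        for rec in small_data["manifest"]["ccvs"]:
            row = key[(rec["chrom"], rec["pos"])]
            idx_c = sheet.clade_indices(rec["carrier"])
            idx_r = sheet.clade_indices(rec["reference"])
            assert (geno.dosage[row, idx_c] == 2).all()
            assert (geno.dosage[row, idx_r] == 0).all()

    def test_planted_cg_loss_variants_in_vcf(self, small_data):
        geno = small_data["geno"]
        vkeys = set(zip(geno.sites["chrom"], geno.sites["pos"]))
        loss = small_data["manifest"]["cg_loss"]
        assert loss
        found = sum((r["chrom"], r["variant_pos"]) in vkeys for r in loss)
        assert found / len(loss) > 0.99

    def test_cg_loss_ablation_in_hom_carriers(self, small_data):
        geno, mat = small_data["geno"], small_data["mat"]
        vkey = {(c, p): i for i, (c, p) in enumerate(zip(geno.sites["chrom"],
                                                         geno.sites["pos"]))}
        skey = {(c, p): i for i, (c, p) in enumerate(zip(mat.sites["chrom"],
                                                         mat.sites["pos"]))}
        beta = mat.beta
        carrier_betas, noncarrier_betas = [], []
        for rec in small_data["manifest"]["cg_loss"][:400]:
            vrow = vkey.get((rec["chrom"], rec["variant_pos"]))
            srow = skey.get((rec["chrom"], rec["cpg_pos"]))
            if vrow is None or srow is None:
                continue
            hom = geno.dosage[vrow] == 2
            ref = geno.dosage[vrow] == 0
            carrier_betas.extend(beta[srow, hom][~np.isnan(beta[srow, hom])])
            noncarrier_betas.extend(beta[srow, ref][~np.isnan(beta[srow, ref])])
        assert np.mean(carrier_betas) < 0.1
        assert np.mean(noncarrier_betas) > 0.3

    def test_zero_cg_loss_fraction_empty_manifest(self, tmp_path):
        man = generate_dataset(tiny_config(cg_loss_fraction=0.0), tmp_path / "o")
        assert man["cg_loss"] == []

    def test_islands_satisfy_criteria_and_are_detected(self, small_data):
        ref = small_data["reference"]
        truth = pd.DataFrame(small_data["manifest"]["islands"])
        assert len(truth) == 6
        for _, isl in truth.iterrows():
            seq = str(ref[isl["chrom"]][isl["start"]:isl["end"]])
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            cpg = sum(1 for i in range(len(seq) - 1) if seq[i: i + 2] == "CG")
            exp = seq.count("C") * seq.count("G") / len(seq)
            assert len(seq) > 200 and gc >= 0.5 and cpg / exp >= 0.6
        for chrom in ("Chr1", "Chr2"):
            det = detect_cg_islands(str(ref[chrom][:]), chrom)
            for _, isl in truth[truth["chrom"] == chrom].iterrows():
                hits = det[(det["start"] < isl["end"]) & (det["end"] > isl["start"])]
                assert len(hits) >= 1

    def test_zero_islands_config_detects_none_across_seeds(self):
        from radiadiv.simulate import simulate_reference

        for seed in range(5):
            cfg = SimConfig(seed=seed, chrom_length=150_000, n_islands=0, n_genes=15)
            genome, _, _ = simulate_reference(cfg, np.random.default_rng(seed))
            n = sum(
                len(detect_cg_islands(arr.tobytes().decode(), c))
                for c, arr in genome.items()
            )
            assert n == 0

    def test_gene_count_and_non_overlap(self, small_data):
        genes = small_data["genes"]
        assert len(genes) == 30
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] < b[0] for a, b in zip(ivs, ivs[1:]))

    def test_report_files_share_site_grid(self, small_data):
        d = small_data["dir"]
        reports = sorted((d / "reports").glob("*.CX_report.txt"))
        assert len(reports) == 36
        first = pd.read_csv(reports[0], sep="\t", header=None, usecols=[0, 1])
        for p in reports[1:3]:
            other = pd.read_csv(p, sep="\t", header=None, usecols=[0, 1])
            pd.testing.assert_frame_equal(first, other)


class TestPlantedSignals:
    def test_hybrids_carry_mosaic_of_parent_species(self, small_data):
        geno, sheet = small_data["geno"], small_data["sheet"]
        jap = sheet.clade_indices("A_japonica")
        oxy = sheet.clade_indices("A_oxysepala")
        hyb = np.flatnonzero(sheet.table["is_hybrid"].to_numpy())
        driver_pos = {(d["chrom"], d["pos"]) for d in small_data["manifest"]["drivers"]}
        keys = list(zip(geno.sites["chrom"], geno.sites["pos"]))
        jap_fixed = (geno.dosage[:, jap] == 2).all(axis=1)
        oxy_absent = (geno.dosage[:, oxy] == 0).all(axis=1)
        rows = [
            i
            for i in np.flatnonzero(jap_fixed & oxy_absent)
            if keys[i] not in driver_pos
        ]
        assert rows
        for i in rows:
            assert (geno.dosage[i, hyb] == 1).all()

    def test_planted_dmr_group_difference_near_delta(self, small_data):
        mat, sheet = small_data["mat"], small_data["sheet"]
        skey = pd.MultiIndex.from_frame(mat.sites[["chrom", "pos"]])
        diffs = []
        for rec in small_data["manifest"]["dmrs"]:
            if rec["driver"] is not None or rec["comparison"] != ["A_japonica", "A_oxysepala"]:
                continue
            sel = (
                (mat.sites["chrom"] == rec["chrom"])
                & (mat.sites["pos"] - 1 >= rec["start"])
                & (mat.sites["pos"] - 1 < rec["end"])
            ).to_numpy()
            ia = sheet.clade_indices("A_japonica")
            ib = sheet.clade_indices("A_oxysepala")

            def pooled(idx):
                cov = mat.covered[np.ix_(sel.nonzero()[0], idx)]
                m = np.where(cov, mat.meth[np.ix_(sel.nonzero()[0], idx)], 0).sum()
                t = np.where(cov, mat.total[np.ix_(sel.nonzero()[0], idx)], 0).sum()
                return m / t

            diffs.append(abs(pooled(ia) - pooled(ib)))
        assert diffs
        assert np.all(np.abs(np.array(diffs) - 0.4) < 0.1)

    def test_null_mode_no_systematic_group_difference(self):
        mat, ia, ib, _ = simulate_methylation_matrix(
            n_windows=500, null_mode=True, seed=9
        )
        beta = mat.beta
        da = np.nanmean(beta[:, ia], axis=1)
        db = np.nanmean(beta[:, ib], axis=1)
        assert abs(np.nanmean(da - db)) < 0.01


class TestBundleParsesEverywhere:
    def test_vcf_gff_fasta_reports_round_trip(self, small_data):
        # the loaded fixtures themselves prove the io_model readers accept the
        # generator's output; spot-check extents here
        assert small_data["geno"].n_sites > 1000
        assert small_data["mat"].n_sites > 1000
        assert len(small_data["reference"]["Chr1"]) == 200_000
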