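"""Methylome summaries: matrix QC, global levels, MDI, islands, metaprofiles."""

import numpy as np
import pandas as pd
import pytest

from radiadiv.datamodel import GeneModel, MethylationMatrix
from radiadiv.methylome import (
    build_methylation_matrix,
    cgi_metaprofile,
    compute_mdi,
    detect_cg_islands,
    gene_metaprofile,
    global_methylation_level,
    methylome_pca,
)


def make_matrix(meth, total, positions=None, chrom="Chr1", min_depth=3):
    meth = np.asarray(meth, dtype=np.int32)
    total = np.asarray(total, dtype=np.int32)
    if positions is None:
        positions = np.arange(1, meth.shape[0] + 1) * 10
    sites = pd.DataFrame({"chrom": chrom, "pos": positions})
    samples = [f"s{i}" for i in range(meth.shape[1])]
    return MethylationMatrix(sites, meth, total, samples, min_depth=min_depth)


class TestMatrix:
    def test_beta_at_threshold_depth(self):
        m = make_matrix([[2]], [[3]])
        assert m.beta[0, 0] == pytest.approx(2 / 3)

    def test_below_threshold_missing(self):
        m = make_matrix([[2]], [[2]])
        assert np.isnan(m.beta[0, 0])

    def test_qc_mask_eighty_percent_rule(self):
        total = np.full((1, 36), 10, dtype=np.int32)
        total[0, :8] = 0  # covered in 28/36 = 77.8% < 80%
        m = make_matrix(np.zeros((1, 36)), total)
        assert not m.qc_mask(0.8)[0]
        total[0, :7] = 10  # now 35/36
        m = make_matrix(np.zeros((1, 36)), total)
        assert m.qc_mask(0.8)[0]

    def test_no_usable_site_rejected(self):
        with pytest.raises(ValueError):
            build_methylation_matrix(make_matrix([[1]], [[1]]), min_depth=3)


class TestGlobalLevel:
    def test_pooled_two_site_example(self):
        m = make_matrix([[3], [7]], [[10], [10]])
        assert global_methylation_level(m, "s0") == pytest.approx(50.0)

    def test_extremes(self):
        m = make_matrix([[10], [10]], [[10], [10]])
        assert global_methylation_level(m, "s0") == 100.0
        m = make_matrix([[0], [0]], [[10], [10]])
        assert global_methylation_level(m, "s0") == 0.0

    def test_uncovered_sites_ignored(self):
        m = make_matrix([[2], [10]], [[2], [10]])  # first site below depth
        assert global_methylation_level(m, "s0") == 100.0


class TestMdi:
    def _ten_window_matrix(self):
        # 10 x 100 kb windows, one site each; window 3 differs by exactly 0.5
        positions = np.arange(10) * 100_000 + 50
        meth = np.tile([[10, 10]], (10, 1))
        meth[3] = [10, 5]
        total = np.full((10, 2), 10)
        return make_matrix(meth, total, positions=positions + 1)

    def test_identity_zero(self):
        m = self._ten_window_matrix()
        assert compute_mdi(m, "s0", "s0", "Chr1") == 0.0

    def test_hand_example_five(self):
        m = self._ten_window_matrix()
        assert compute_mdi(m, "s0", "s1", "Chr1") == pytest.approx(5.0)

    def test_symmetry(self):
        m = self._ten_window_matrix()
        assert compute_mdi(m, "s0", "s1", "Chr1") == compute_mdi(m, "s1", "s0", "Chr1")

    def test_no_shared_window_undefined(self):
        m = make_matrix([[10, 0]], [[10, 0]])  # s1 has no coverage at all
        assert np.isnan(compute_mdi(m, "s0", "s1", "Chr1"))


def brute_force_islands(seq, window=100, min_len=200):
    """Direct per-window criterion evaluation (the independent oracle)."""
    seq = seq.upper()
    L = len(seq)
    covered = np.zeros(L, dtype=bool)
    for i in range(L - window + 1):
        w = seq[i : i + window]
        n_n = sum(c not in "ACGT" for c in w)
        if n_n > window // 2:
            continue
        eff = window - n_n
        c = w.count("C")
        g = w.count("G")
        if eff == 0 or (c + g) / eff <= 0.5:
            continue
        exp = c * g / eff
        if exp == 0:
            continue
        obs = sum(1 for j in range(window - 1) if w[j] == "C" and w[j + 1] == "G")
        if obs / exp > 0.6:
            covered[i : i + window] = True
    runs = []
    i = 0
    while i < L:
        if covered[i]:
            j = i
            while j < L and covered[j]:
                j += 1
            if j - i > min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


class TestCgIslands:
    def test_pure_cg_repeat_single_island(self):
        out = detect_cg_islands("CG" * 300, "c")
        assert len(out) == 1
        assert out.loc[0, "start"] == 0 and out.loc[0, "end"] == 600
        assert out.loc[0, "gc_fraction"] == 1.0
        assert out.loc[0, "obs_exp_cpg"] == pytest.approx(2.0)

    def test_poly_a_no_island(self):
        assert len(detect_cg_islands("A" * 2000)) == 0

    def test_matches_brute_force_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(40):
            L = int(rng.integers(300, 2500))
            p_gc = rng.uniform(0.3, 0.65)
            p = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
            seq = "".join(rng.choice(bases, size=L, p=p))
            got = detect_cg_islands(seq)
            want = brute_force_islands(seq)
            assert list(zip(got["start"], got["end"])) == want

    def test_n_runs_excluded_from_composition(self):
        seq = "CG" * 150 + "N" * 30 + "CG" * 150
        got = detect_cg_islands(seq)
        want = brute_force_islands(seq)
        assert list(zip(got["start"], got["end"])) == want


class TestMetaprofiles:
    def _uniform_matrix(self, gene, beta=0.5, spacing=50, n_samples=4):
        lo = gene.start - 1 - 5000
        hi = gene.end + 5000
        positions = np.arange(max(lo, 0), hi, spacing) + 1
        total = np.full((len(positions), n_samples), 20, dtype=np.int32)
        meth = (total * beta).astype(np.int32)
        return make_matrix(meth, total, positions=positions)

    def test_uniform_beta_flat_profile(self):
        gene = GeneModel("g", "Chr1", 20001, 22000, "+", [(20001, 22000)])
        mat = self._uniform_matrix(gene)
        prof = gene_metaprofile(mat, [gene], {"grp": np.arange(4)})
        vals = prof["beta"].dropna()
        assert len(vals) > 150
        assert np.allclose(vals, 0.5)

    def test_minus_strand_orientation_matches_plus(self):
        gplus = GeneModel("gp", "Chr1", 20001, 22000, "+", [(20001, 22000)])
        gminus = GeneModel("gm", "Chr1", 20001, 22000, "-", [(20001, 22000)])
        positions = np.arange(14000, 28000, 37) + 1
        rng = np.random.default_rng(0)
        total = np.full((len(positions), 2), 20, dtype=np.int32)
        meth = rng.integers(0, 21, size=total.shape).astype(np.int32)
        mat = make_matrix(meth, total, positions=positions)
        pp = gene_metaprofile(mat, [gplus], {"g": np.arange(2)})
        pm = gene_metaprofile(mat, [gminus], {"g": np.arange(2)})
        # the minus-strand profile is the plus-strand profile read right-to-left
        a = pp["beta"].to_numpy()
        b = pm["beta"].to_numpy()[::-1]
        ok = ~(np.isnan(a) | np.isnan(b))
        assert ok.sum() > 100
        np.testing.assert_allclose(a[ok], b[ok], atol=1e-12)

    def test_profile_conserves_pooled_mean(self):
        gene = GeneModel("g", "Chr1", 20001, 22000, "+", [(20001, 22000)])
        rng = np.random.default_rng(1)
        lo, hi = gene.start - 1 - 5000, gene.end + 5000
        positions = np.arange(lo, hi, 61) + 1
        total = rng.integers(3, 30, size=(len(positions), 3)).astype(np.int32)
        meth = rng.binomial(total, 0.3).astype(np.int32)
        mat = make_matrix(meth, total, positions=positions)
        prof = gene_metaprofile(mat, [gene], {"g": np.arange(3)})
        t = prof["total_reads"].to_numpy()
        b = prof["beta"].to_numpy()
        ok = t > 0
        pooled_from_bins = np.sum(b[ok] * t[ok]) / t[ok].sum()
        pooled_direct = mat.meth.sum() / mat.total.sum()
        assert pooled_from_bins == pytest.approx(pooled_direct, abs=1e-12)

    def test_cgi_profile_shift_equivariance(self):
        islands = pd.DataFrame({"chrom": ["Chr1"], "start": [10000], "end": [10800]})
        positions = np.arange(7000, 13800, 41) + 1
        total = np.full((len(positions), 4), 40, dtype=np.int32)
        meth_lo = (total * 0.4).astype(np.int32)
        meth_hi = (total * 0.5).astype(np.int32)  # +0.1 everywhere for group B
        mat = make_matrix(
            np.hstack([meth_lo[:, :2], meth_hi[:, 2:]]), total, positions=positions
        )
        prof = cgi_metaprofile(
            mat, islands, {"A": np.arange(2), "B": np.arange(2, 4)}
        )
        a = prof.loc[prof["group"] == "A", "beta"].to_numpy()
        b = prof.loc[prof["group"] == "B", "beta"].to_numpy()
        ok = ~(np.isnan(a) | np.isnan(b))
        np.testing.assert_allclose(b[ok] - a[ok], 0.1, atol=1e-9)

    def test_no_islands_empty_profile(self):
        mat = make_matrix([[10]], [[20]])
        prof = cgi_metaprofile(mat, pd.DataFrame(columns=["chrom", "start", "end"]),
                               {"g": np.array([0])})
        assert prof["total_reads"].sum() == 0


class TestMethylomePca:
    def test_duplicate_samples_identical_coordinates(self, rng):
        total = np.full((200, 6), 20, dtype=np.int32)
        meth = rng.integers(0, 21, size=(200, 6)).astype(np.int32)
        meth[:, 5] = meth[:, 0]
        mat = make_matrix(meth, total)
        coords, _ = methylome_pca(mat, n_components=3)
        np.testing.assert_allclose(coords[0], coords[5], atol=1e-10)

    def test_species_clusters_separate(self, default_data):
        from sklearn.metrics import silhouette_score

        mat = default_data["mat"]
        sheet = default_data["sheet"]
        coords, _ = methylome_pca(mat, n_components=2)
        labels = sheet.table["species"].to_numpy()
        assert silhouette_score(coords, labels) > 0

    def test_constant_matrix_error(self):
        mat = make_matrix(np.full((50, 4), 10), np.full((50, 4), 20))
        with pytest.raises(ValueError):
            methylome_pca(mat)
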