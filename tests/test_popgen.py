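"""Windowed pi/FST, quantile tails, LD pruning, PCA and NJ reconstruction."""

import numpy as np
import pandas as pd
import pytest

from radiadiv.datamodel import GenotypeMatrix
from radiadiv.popgen import (
    allele_sharing_distance,
    genotype_pca,
    ld_prune,
    make_windows,
    nj_tree,
    pca,
    select_ldgr_hdgr,
    window_fst,
    window_pi,
)


def geno_from_dosage(dosage, positions=None, chrom="Chr1"):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites = dosage.shape[0]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "consequence": "x",
            "impact": "LOW",
            "gene_id": "",
            "is_snp": True,
        }
    )
    samples = [f"s{i}" for i in range(dosage.shape[1])]
    return GenotypeMatrix(sites, dosage, samples)


class TestWindows:
    def test_tiling_with_terminal_partial(self):
        w = make_windows({"c": 250_000}, 100_000)
        assert list(zip(w["start"], w["end"])) == [
            (0, 100_000), (100_000, 200_000), (200_000, 250_000)]
        assert list(w["is_partial"]) == [False, False, True]

    def test_chromosome_shorter_than_window(self):
        w = make_windows({"c": 500}, 1000)
        assert len(w) == 1 and w.loc[0, "end"] == 500

    def test_count_scales(self):
        assert len(make_windows({"c": 1_000_000}, 100)) == 10_000


class TestPi:
    def test_single_snp_hand_value(self):
        g = geno_from_dosage([[1, 1, 1, 1]], positions=[500])
        w = make_windows({"Chr1": 1000}, 1000)
        out = window_pi(g, np.arange(4), w)
        assert out.loc[0, "pi"] == pytest.approx((8 / 7) * 0.5 / 1000, abs=1e-15)

    def test_monomorphic_window_zero(self):
        g = geno_from_dosage([[0, 0, 0, 0], [2, 2, 2, 2]])
        w = make_windows({"Chr1": 100}, 100)
        assert window_pi(g, np.arange(4), w).loc[0, "pi"] == 0.0

    def test_reordering_invariance(self, rng):
        dosage = rng.integers(0, 3, size=(40, 8)).astype(np.int8)
        g = geno_from_dosage(dosage)
        w = make_windows({"Chr1": 500}, 500)
        base = window_pi(g, np.arange(8), w).loc[0, "pi"]
        perm = rng.permutation(8)
        assert window_pi(g, perm, w).loc[0, "pi"] == pytest.approx(base, abs=1e-15)
        site_perm = rng.permutation(40)
        g2 = GenotypeMatrix(
            g.sites.iloc[site_perm].reset_index(drop=True), dosage[site_perm], g.samples
        )
        assert window_pi(g2, np.arange(8), w).loc[0, "pi"] == pytest.approx(base, abs=1e-15)


class TestFst:
    def test_fixed_difference_is_one(self):
        g = geno_from_dosage([[2, 2, 2, 0, 0, 0]])
        w = make_windows({"Chr1": 100}, 100)
        out = window_fst(g, np.arange(3), np.arange(3, 6), w)
        assert out.loc[0, "fst"] == pytest.approx(1.0, abs=1e-12)

    def test_identical_monomorphic_groups_undefined(self):
        g = geno_from_dosage([[0, 0, 0, 0]])
        w = make_windows({"Chr1": 100}, 100)
        assert np.isnan(window_fst(g, np.arange(2), np.arange(2, 4), w).loc[0, "fst"])

    def test_panmictic_pooling_estimator_not_positive(self, rng):
        # splitting one population in two must not suggest differentiation
        vals = []
        for _ in range(30):
            p = rng.uniform(0.2, 0.8)
            dosage = rng.binomial(2, p, size=(50, 12)).astype(np.int8)
            g = geno_from_dosage(dosage)
            w = make_windows({"Chr1": 600}, 600)
            vals.append(window_fst(g, np.arange(6), np.arange(6, 12), w).loc[0, "fst"])
        assert np.nanmean(vals) < 0.02


class TestTails:
    def test_five_percent_of_forty_windows(self):
        w = make_windows({"c": 40 * 100}, 100)
        pi_df = w.copy()
        pi_df["pi"] = np.arange(40) / 1000.0
        fst_df = w.copy()
        fst_df["fst"] = np.arange(40) / 40.0
        res = select_ldgr_hdgr({"cl": pi_df}, {("a", "b"): fst_df})
        assert len(res["ldgr"]["cl"]) == 2
        assert len(res["hdgr"][("a", "b")]) == 2

    def test_ties_all_included(self):
        w = make_windows({"c": 40 * 100}, 100)
        pi_df = w.copy()
        pi_df["pi"] = 0.005  # all equal: everything ties at the threshold
        res = select_ldgr_hdgr({"cl": pi_df}, {})
        assert len(res["ldgr"]["cl"]) == 40

    def test_disjoint_sets_empty_intersection(self):
        w = make_windows({"c": 40 * 100}, 100)
        pi_df = w.copy()
        pi_df["pi"] = np.arange(40) / 1000.0
        fst_df = w.copy()
        fst_df["fst"] = np.arange(40)[::-1] / 40.0  # best FST where pi is lowest? no:
        # lowest pi windows are first rows; highest fst also first rows -> overlap
        res = select_ldgr_hdgr({"cl": pi_df}, {("cl", "x"): fst_df})
        assert set(res["ldgr_hdgr_overlap"][("cl", "x")]) == {("c", 0), ("c", 100)}


class TestLdPrune:
    def test_duplicated_snp_removed(self, rng):
        col = rng.integers(0, 3, size=(1, 20)).astype(np.int8)
        dosage = np.vstack([col, col, rng.integers(0, 3, size=(1, 20)).astype(np.int8)])
        g = geno_from_dosage(dosage)
        pruned = ld_prune(g, window_n_snps=10, step=5, r2_max=0.2)
        assert pruned.n_sites == 2
        assert pruned.sites.loc[0, "pos"] == 10  # the left copy is kept

    def test_independent_snps_kept(self, rng):
        dosage = rng.binomial(2, 0.5, size=(30, 200)).astype(np.int8)
        g = geno_from_dosage(dosage)
        pruned = ld_prune(g, window_n_snps=10, step=5, r2_max=0.9)
        assert pruned.n_sites == 30

    def test_three_snp_chain_hand_trace(self):
        # SNP0 ~ SNP1 (r2=1), SNP1 ~ SNP2 (r2=1): greedy drops 1 then 2
        base = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0], dtype=np.int8)
        dosage = np.vstack([base, base, base])
        g = geno_from_dosage(dosage)
        pruned = ld_prune(g, window_n_snps=3, step=3, r2_max=0.2)
        assert list(pruned.sites["pos"]) == [10]


class TestPca:
    def test_identical_samples_identical_coordinates(self, rng):
        X = rng.normal(size=(50, 5))
        X[:, 4] = X[:, 0]
        coords, _ = pca(X, n_components=3)
        np.testing.assert_allclose(coords[0], coords[4], atol=1e-10)

    def test_rank_one_matrix_pc1_explains_all(self, rng):
        u = rng.normal(size=50)
        v = rng.normal(size=8)
        coords, ev = pca(np.outer(u, v), n_components=3)
        assert ev[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(60, 10))
        coords, ev = pca(X, n_components=4)
        Xc = X - X.mean(axis=1, keepdims=True)
        C = Xc.T @ Xc
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        for j in range(4):
            expected = V[:, order[j]] * np.sqrt(w[order[j]])
            got = coords[:, j]
            agree = min(np.abs(got - expected).max(), np.abs(got + expected).max())
            assert agree < 1e-8
        np.testing.assert_allclose(ev[:4], w[order[:4]] / w.sum(), atol=1e-12)

    def test_zero_variance_error_path(self):
        with pytest.raises(ValueError):
            pca(np.ones((10, 4)), n_components=2)

    def test_genotype_pca_separates_two_populations(self, rng):
        pa = rng.uniform(0.05, 0.3, size=200)
        pb = np.clip(pa + 0.5, 0, 1)
        dosage = np.hstack(
            [rng.binomial(2, pa[:, None], (200, 6)), rng.binomial(2, pb[:, None], (200, 6))]
        ).astype(np.int8)
        coords, _ = genotype_pca(geno_from_dosage(dosage), n_components=2)
        a, b = coords[:6, 0], coords[6:, 0]
        assert (a.max() < b.min()) or (b.max() < a.min())


def random_additive_tree(rng, n_taxa):
    """Random binary tree -> (distance matrix, set of nontrivial splits)."""
    import itertools

    nodes = [frozenset([i]) for i in range(n_taxa)]
    children: dict = {}
    lengths: dict = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        new = a | b
        children[new] = (a, b)
        lengths[a] = rng.uniform(0.05, 1.0)
        lengths[b] = rng.uniform(0.05, 1.0)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    # leaf depths via recursion
    dist = np.zeros((n_taxa, n_taxa))

    def leaf_dists(node):
        if len(node) == 1:
            return {next(iter(node)): 0.0}
        a, b = children[node]
        da = {k: v + lengths[a] for k, v in leaf_dists(a).items()}
        db = {k: v + lengths[b] for k, v in leaf_dists(b).items()}
        return {**da, **db}

    def fill(node):
        if len(node) == 1:
            return
        a, b = children[node]
        da = {k: v + lengths[a] for k, v in leaf_dists(a).items()}
        db = {k: v + lengths[b] for k, v in leaf_dists(b).items()}
        for x, dx in da.items():
            for y, dy in db.items():
                dist[x, y] = dist[y, x] = dx + dy
        fill(a)
        fill(b)

    fill(nodes[0])
    splits = set()
    all_taxa = frozenset(range(n_taxa))
    for node in children:
        if 1 < len(node) < n_taxa - 1:
            splits.add(frozenset([node, all_taxa - node]))
    return dist, splits


def tree_splits(tree, labels):
    all_taxa = frozenset(labels)
    splits = set()
    for clade in tree.get_nonterminals():
        names = frozenset(t.name for t in clade.get_terminals())
        if 1 < len(names) < len(all_taxa) - 1:
            splits.add(frozenset([names, all_taxa - names]))
    return splits


class TestNj:
    def test_three_taxa_exact_branch_lengths(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree = nj_tree(D, ["x", "y", "z"])
        bl = {t.name: t.branch_length for t in tree.get_terminals()}
        assert bl == {"x": 1.0, "y": 1.0, "z": 2.0}

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_additive_matrix_topology_recovered(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 11))
            D, true_splits = random_additive_tree(rng, n)
            labels = [str(i) for i in range(n)]
            tree = nj_tree(D, labels)
            got = tree_splits(tree, labels)
            want = {
                frozenset([frozenset(map(str, a)), frozenset(map(str, b))])
                for s in true_splits
                for a, b in [tuple(s)]
            }
            assert got == want

    def test_newick_round_trip(self, rng):
        from io import StringIO

        from Bio import Phylo

        D, _ = random_additive_tree(rng, 6)
        labels = [f"t{i}" for i in range(6)]
        tree = nj_tree(D, labels)
        buf = StringIO()
        Phylo.write(tree, buf, "newick")
        buf.seek(0)
        back = Phylo.read(buf, "newick")
        assert sorted(t.name for t in back.get_terminals()) == sorted(labels)


class TestAlleleSharing:
    def test_hand_distances_hom_only(self):
        # sites x samples; heterozygous calls are excluded from the distance
        dosage = np.array(
            [[0, 2, 0],   # s0 vs s1 differ, s0 vs s2 share both alleles
             [2, 0, 2],
             [1, 0, 0],   # s0 het here: excluded for pairs involving s0
             [0, 0, 0]],
            dtype=np.int8,
        )
        g = geno_from_dosage(dosage)
        d = allele_sharing_distance(g)
        assert d[0, 1] == pytest.approx(2 / 3)  # 2 of 6 alleles shared over 3 loci
        assert d[0, 2] == pytest.approx(0.0)
        assert d[1, 2] == pytest.approx(0.5)  # 4 loci, shared 4 of 8
        assert np.allclose(np.diag(d), 0)
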