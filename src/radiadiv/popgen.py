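"""Windowed diversity/divergence scans, PCA, LD pruning and NJ phylogeny.

pi uses the unbiased per-site heterozygosity sum over the full window length
(monomorphic positions count toward the denominator, the convention of
windowed scans); FST is the Weir & Cockerham (1984) two-population
variance-component estimator, summed a / (a+b+c) over the window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio.Phylo.BaseTree import Clade, Tree

from .datamodel import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


def make_windows(chrom_lengths: dict[str, int], window_size: int) -> pd.DataFrame:
    """Non-overlapping tiling from coordinate 0; terminal partial window kept."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, window_size)
        for s in starts:
            e = min(s + window_size, length)
            rows.append((chrom, int(s), int(e), e - s < window_size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "is_partial"])


def _window_index(sites: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Map each site to a window row index (-1 when uncovered)."""
    idx = np.full(len(sites), -1, dtype=np.int64)
    for chrom, wsub in windows.groupby("chrom", sort=False):
        mask = (sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos0 = sites.loc[mask, "pos"].to_numpy() - 1  # to 0-based
        starts = wsub["start"].to_numpy()
        ends = wsub["end"].to_numpy()
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        out = np.where(ok, wsub.index.to_numpy()[np.clip(j, 0, len(ends) - 1)], -1)
        idx[mask] = out
    return idx


def window_pi(
    geno: GenotypeMatrix, sample_idx: np.ndarray, windows: pd.DataFrame
) -> pd.DataFrame:
    """Nucleotide diversity per window: (1/L) * sum n/(n-1) * 2p(1-p)."""
    d = geno.dosage[:, sample_idx].astype(float)
    d[d == MISSING] = np.nan
    n = 2 * np.sum(~np.isnan(d), axis=1)  # non-missing allele count per site
    ac = np.nansum(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, ac / np.where(n == 0, 1, n), np.nan)
        per_site = np.where(n >= 2, n / np.maximum(n - 1, 1) * 2 * p * (1 - p), 0.0)
    per_site = np.nan_to_num(per_site)
    widx = _window_index(geno.sites, windows)
    out = windows.copy()
    L = (out["end"] - out["start"]).to_numpy().astype(float)
    sums = np.zeros(len(out))
    counts = np.zeros(len(out), dtype=int)
    ok = widx >= 0
    np.add.at(sums, widx[ok], per_site[ok])
    np.add.at(counts, widx[ok], (n[ok] >= 2).astype(int))
    out["pi"] = sums / L
    out["n_sites"] = counts
    return out


def _wc_components(
    d: np.ndarray, idxA: np.ndarray, idxB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham a, b, c for two populations, plus usable mask."""
    comps = []
    for idx in (idxA, idxB):
        sub = d[:, idx].astype(float)
        sub[sub == MISSING] = np.nan
        n_i = np.sum(~np.isnan(sub), axis=1).astype(float)  # diploid individuals
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.nansum(sub, axis=1) / np.where(n_i == 0, 1, 2 * n_i)
            h_i = np.nansum(sub == 1, axis=1) / np.where(n_i == 0, 1, n_i)
        comps.append((n_i, p_i, h_i))
    (nA, pA, hA), (nB, pB, hB) = comps
    r = 2.0
    usable = (nA >= 1) & (nB >= 1)
    nbar = (nA + nB) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    polymorphic = ~((pbar <= 0) | (pbar >= 1)) | (hbar > 0)
    usable &= polymorphic & (nbar > 1) & (nc > 0)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def window_fst(
    geno: GenotypeMatrix, idxA: np.ndarray, idxB: np.ndarray, windows: pd.DataFrame
) -> pd.DataFrame:
    """Weir-Cockerham theta-hat per window: sum(a) / sum(a+b+c)."""
    a, b, c, usable = _wc_components(geno.dosage, idxA, idxB)
    widx = _window_index(geno.sites, windows)
    out = windows.copy()
    num = np.zeros(len(out))
    den = np.zeros(len(out))
    counts = np.zeros(len(out), dtype=int)
    ok = (widx >= 0) & usable
    np.add.at(num, widx[ok], a[ok])
    np.add.at(den, widx[ok], (a + b + c)[ok])
    np.add.at(counts, widx[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den != 0, num / den, np.nan)
    fst[counts == 0] = np.nan
    out["fst"] = fst
    out["n_sites"] = counts
    return out


def select_ldgr_hdgr(
    pi_by_clade: dict[str, pd.DataFrame],
    fst_by_pair: dict[tuple[str, str], pd.DataFrame],
    low_q: float = 0.05,
    high_q: float = 0.05,
) -> dict:
    """5% tails of windowed pi (LDGR) and FST (HDGR), plus their overlaps.

    Ties at the quantile threshold are all included (closed threshold), so a
    tail may exceed the nominal fraction.
    """
    ldgr = {}
    for clade, df in pi_by_clade.items():
        vals = df["pi"].to_numpy()
        if len(vals) < 1 / low_q:
            log.warning("clade %s: only %d windows for a %.0f%% tail", clade, len(vals), 100 * low_q)
        thr = np.quantile(vals, low_q)
        ldgr[clade] = df[df["pi"] <= thr].reset_index(drop=True)
    hdgr = {}
    for pair, df in fst_by_pair.items():
        vals = df["fst"].dropna().to_numpy()
        thr = np.quantile(vals, 1 - high_q) if len(vals) else np.nan
        hdgr[pair] = df[df["fst"] >= thr].reset_index(drop=True)

    def _keys(df):
        return set(zip(df["chrom"], df["start"]))

    clades = list(ldgr)
    shared_ld = set()
    for i in range(len(clades)):
        for j in range(i + 1, len(clades)):
            shared_ld |= _keys(ldgr[clades[i]]) & _keys(ldgr[clades[j]])
    overlap = {}
    for pair, df in hdgr.items():
        inter = set()
        for clade in pair:
            if clade in ldgr:
                inter |= _keys(ldgr[clade]) & _keys(df)
        overlap[pair] = sorted(inter)
    return {"ldgr": ldgr, "hdgr": hdgr, "shared_ldgr": sorted(shared_ld), "ldgr_hdgr_overlap": overlap}


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Dosage r^2 with pairwise deletion of missing entries. X: snps x samples."""
    M = (X != MISSING).astype(float)
    Xz = np.where(X == MISSING, 0.0, X.astype(float))
    n = M @ M.T
    sx = Xz @ M.T
    sxy = Xz @ Xz.T
    sxx = (Xz**2) @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var = sxx / n - (sx / n) ** 2
        r2 = cov**2 / (var * var.T)
    r2[~np.isfinite(r2)] = 0.0
    return r2


def ld_prune(
    geno: GenotypeMatrix, window_n_snps: int = 50, step: int = 5, r2_max: float = 0.2
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning (drop the right SNP of each r^2 > max pair)."""
    keep = np.ones(geno.n_sites, dtype=bool)
    chrom = geno.sites["chrom"].to_numpy()
    for c in pd.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        for start in range(0, len(cidx), step):
            widx = cidx[start : start + window_n_snps]
            active = widx[keep[widx]]
            if len(active) < 2:
                continue
            r2 = _pairwise_r2(geno.dosage[active])
            local_keep = np.ones(len(active), dtype=bool)
            for i in range(len(active)):
                if not local_keep[i]:
                    continue
                for j in range(i + 1, len(active)):
                    if local_keep[j] and r2[i, j] > r2_max:
                        local_keep[j] = False
            keep[active[~local_keep]] = False
            if start + window_n_snps >= len(cidx):
                break
    return geno.subset_sites(keep)


def pca(
    matrix: np.ndarray, n_components: int = 10, standardize: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a features x samples matrix (NaN = missing, mean-imputed per feature).

    Returns (sample coordinates (n_samples, k), explained variance fractions).
    Zero-variance features are dropped. Component signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    X = np.asarray(matrix, dtype=float).copy()
    mu = np.nanmean(X, axis=1, keepdims=True)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu[:, 0], inds[0])
    X -= X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    nz = sd > 0
    if (~nz).any():
        log.info("PCA: dropped %d zero-variance features", int((~nz).sum()))
    X = X[nz]
    if standardize:
        X /= X.std(axis=1, keepdims=True)
    if X.shape[0] == 0:
        raise ValueError("no informative (non-constant) features for PCA")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    coords = Vt[:k].T * S[:k]
    # deterministic sign convention
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            coords[:, j] *= -1
    ev = S**2 / np.sum(S**2)
    return coords, ev[:k]


def genotype_pca(geno: GenotypeMatrix, n_components: int = 10):
    d = geno.dosage.astype(float)
    d[d == MISSING] = np.nan
    return pca(d, n_components=n_components, standardize=True)


def allele_sharing_distance(geno: GenotypeMatrix, hom_only: bool = True) -> np.ndarray:
    """1 - (shared alleles) / (2 * compared loci), pairwise over samples.

    With ``hom_only`` (the default used for NJ input) heterozygous calls are
    excluded along with missing ones.
    """
    d = geno.dosage
    n = d.shape[1]
    valid = d != MISSING
    if hom_only:
        valid &= d != 1
    dist = np.zeros((n, n))
    df = d.astype(float)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[:, i] & valid[:, j]
            L = both.sum()
            if L == 0:
                dist[i, j] = dist[j, i] = np.nan
                continue
            shared = np.sum(2 - np.abs(df[both, i] - df[both, j]))
            dist[i, j] = dist[j, i] = 1 - shared / (2 * L)
    return dist


def nj_tree(distances: np.ndarray, labels: list[str], return_joins: bool = False):
    """Saitou-Nei neighbor joining; ties by smallest (i, j); branches >= 0.

    Returns an unrooted Bio.Phylo tree (trifurcating root). With
    ``return_joins`` also returns the join sequence as pairs of leaf-name
    frozensets, for step-by-step comparison against an oracle.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n != D.shape[1] or n != len(labels):
        raise ValueError("distance matrix / labels mismatch")
    if n < 3:
        raise ValueError("NJ requires at least 3 samples")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distances must be symmetric with zero diagonal")
    nodes = [Clade(name=lab) for lab in labels]
    leafsets: list[frozenset] = [frozenset([lab]) for lab in labels]
    joins: list[tuple[frozenset, frozenset]] = []
    active = list(range(n))
    D = D.copy()
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - (r[:, None] + r[None, :])
        Q[np.tril_indices(m)] = np.inf  # search i < j only
        # smallest Q; ties resolved by smallest (i, j) position pair
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        i_loc, j_loc = min(map(tuple, ties))
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = dij / 2 + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        new = Clade(clades=[child_i, child_j])
        # distances to the new node (reuse row i as its storage slot)
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (D[i, k] + D[j, k] - dij) / 2
        nodes[i] = new
        joins.append((leafsets[i], leafsets[j]))
        leafsets[i] = leafsets[i] | leafsets[j]
        active.remove(j)
    i, j, k = active
    li = max((D[i, j] + D[i, k] - D[j, k]) / 2, 0.0)
    lj = max((D[i, j] + D[j, k] - D[i, k]) / 2, 0.0)
    lk = max((D[i, k] + D[j, k] - D[i, j]) / 2, 0.0)
    for node, bl in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.branch_length = bl
    root = Clade(clades=[nodes[i], nodes[j], nodes[k]])
    tree = Tree(root=root, rooted=False)
    if return_joins:
        return tree, joins
    return tree
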