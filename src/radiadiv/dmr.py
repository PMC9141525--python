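"""Differential methylation: stratified CMH testing over 100-bp windows.

Each CG site inside a window is one stratum; per stratum the 2x2 table is
(group A, group B) x (methylated, unmethylated) read counts pooled over the
covered samples of each group. Stratifying by site lets windows with very
different read depths contribute on equal footing; the test conditions on
per-stratum margins. A window is a DMR when the BH-adjusted p value is below
``alpha`` and the pooled methylation divergence exceeds ``min_divergence``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneModel, MethylationMatrix, SampleSheet


def _cmh_components(
    a: np.ndarray, row1: np.ndarray, col1: np.ndarray, total: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric mean and variance of the top-left cell given margins."""
    with np.errstate(invalid="ignore", divide="ignore"):
        e = row1 * col1 / total
        v = row1 * (total - row1) * col1 * (total - col1) / (total**2 * (total - 1))
    return e, v


def cmh_test(strata) -> tuple[float, float, int]:
    """Cochran-Mantel-Haenszel chi-square (1 df, no continuity correction).

    ``strata`` is a sequence of 2x2 tables [[a, b], [c, d]] with rows = the
    two groups and columns = (methylated, unmethylated) counts. Strata with
    any zero margin are uninformative and skipped. Returns (statistic,
    p_value, n_informative); (nan, nan, 0) when no stratum is informative.
    """
    t = np.asarray(strata, dtype=float)
    if t.ndim == 2:
        t = t[None]
    a = t[:, 0, 0]
    row1 = t[:, 0, 0] + t[:, 0, 1]
    row2 = t[:, 1, 0] + t[:, 1, 1]
    col1 = t[:, 0, 0] + t[:, 1, 0]
    col2 = t[:, 0, 1] + t[:, 1, 1]
    total = row1 + row2
    informative = (row1 > 0) & (row2 > 0) & (col1 > 0) & (col2 > 0)
    k = int(informative.sum())
    if k == 0:
        return float("nan"), float("nan"), 0
    e, v = _cmh_components(a[informative], row1[informative], col1[informative], total[informative])
    num = float(np.sum(a[informative] - e)) ** 2
    den = float(np.sum(v))
    if den == 0:
        return float("nan"), float("nan"), k
    chi2 = num / den
    return chi2, float(stats.chi2.sf(chi2, df=1)), k


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p value passed to bh_adjust")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def scan_dmrs(
    mat: MethylationMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    window: int = 100,
    min_sites: int = 3,
    alpha: float = 0.05,
    min_divergence: float = 0.25,
) -> pd.DataFrame:
    """Windowed CMH scan between two clades; BH over all tested windows.

    Windows with fewer than ``min_sites`` informative strata are untested and
    excluded from the BH family (untested is not the same as
    non-significant). Divergence is |pooled beta A - pooled beta B| over all
    window sites and covered samples.
    """
    idx_a = sheet.clade_indices(group_a)
    idx_b = sheet.clade_indices(group_b)
    if set(idx_a) & set(idx_b):
        raise ValueError("groups overlap")
    return scan_dmrs_indices(
        mat, idx_a, idx_b, f"{group_a}|{group_b}", window, min_sites, alpha, min_divergence
    )


def scan_dmrs_indices(
    mat: MethylationMatrix,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    comparison: str,
    window: int = 100,
    min_sites: int = 3,
    alpha: float = 0.05,
    min_divergence: float = 0.25,
) -> pd.DataFrame:
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty group")
    cov = mat.covered
    meth = mat.meth
    total = mat.total

    def pooled(idx):
        c = cov[:, idx]
        m = np.where(c, meth[:, idx], 0).sum(axis=1).astype(float)
        t = np.where(c, total[:, idx], 0).sum(axis=1).astype(float)
        return m, t

    mA, tA = pooled(idx_a)
    mB, tB = pooled(idx_b)
    uA, uB = tA - mA, tB - mB
    grand = tA + tB
    informative = (tA > 0) & (tB > 0) & (mA + mB > 0) & (uA + uB > 0)
    e, v = _cmh_components(mA, tA, mA + mB, grand)
    e = np.where(informative, e, 0.0)
    v = np.where(informative, v, 0.0)
    resid = np.where(informative, mA - e, 0.0)

    chroms = mat.sites["chrom"].to_numpy()
    pos0 = mat.sites["pos"].to_numpy() - 1
    wkey = pd.DataFrame({"chrom": chroms, "wstart": (pos0 // window) * window})
    codes, uniq = pd.factorize(pd.MultiIndex.from_frame(wkey), sort=True)
    nw = len(uniq)
    num = np.bincount(codes, weights=resid, minlength=nw) ** 2
    den = np.bincount(codes, weights=v, minlength=nw)
    k = np.bincount(codes, weights=informative.astype(float), minlength=nw).astype(int)
    wmA = np.bincount(codes, weights=mA, minlength=nw)
    wtA = np.bincount(codes, weights=tA, minlength=nw)
    wmB = np.bincount(codes, weights=mB, minlength=nw)
    wtB = np.bincount(codes, weights=tB, minlength=nw)
    with np.errstate(invalid="ignore", divide="ignore"):
        div = np.abs(
            np.where(wtA > 0, wmA / np.where(wtA == 0, 1, wtA), np.nan)
            - np.where(wtB > 0, wmB / np.where(wtB == 0, 1, wtB), np.nan)
        )
        chi2 = np.where(den > 0, num / den, np.nan)
    tested = (k >= min_sites) & (den > 0)
    pvals = np.full(nw, np.nan)
    pvals[tested] = stats.chi2.sf(chi2[tested], df=1)
    padj = np.full(nw, np.nan)
    if tested.any():
        padj[tested] = bh_adjust(pvals[tested])
    out = pd.DataFrame(
        {
            "chrom": [u[0] for u in uniq],
            "start": [int(u[1]) for u in uniq],
            "end": [int(u[1]) + window for u in uniq],
            "comparison": comparison,
            "cmh_statistic": chi2,
            "p_value": pvals,
            "p_adjusted": padj,
            "divergence": div,
            "n_strata": k,
        }
    )
    out = out[tested].reset_index(drop=True)
    out["is_dmr"] = (out["p_adjusted"] < alpha) & (out["divergence"] > min_divergence)
    return out


def call_dmgs(
    dmrs: pd.DataFrame, genes: list[GeneModel], threshold: float = 0.20
) -> pd.DataFrame:
    """Genes with > ``threshold`` of the genic region covered by DMR windows."""
    sig = dmrs[dmrs["is_dmr"]]
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in sig.groupby("chrom"):
        iv = sub[["start", "end"]].to_numpy()
        by_chrom[chrom] = iv[np.argsort(iv[:, 0])]
    rows = []
    comparison = dmrs["comparison"].iloc[0] if len(dmrs) else ""
    for g in genes:
        g0, g1 = g.start - 1, g.end  # to 0-based half-open
        covered = 0
        for s, e in by_chrom.get(g.chromosome, ()):  # windows are disjoint
            lo, hi = max(s, g0), min(e, g1)
            if hi > lo:
                covered += hi - lo
        frac = covered / (g1 - g0)
        rows.append((g.gene_id, comparison, covered, g1 - g0, frac, frac > threshold))
    return pd.DataFrame(
        rows, columns=["gene_id", "comparison", "dmr_bases", "gene_length", "fraction", "is_dmg"]
    )
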