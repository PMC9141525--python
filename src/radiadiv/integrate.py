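"""Dependence of methylation variation on genetic variation.

Covers CG-loss locus classification and per-locus regression, epigenetic
variability categories, the PCA-corrected (Eigenstrat-style) cis-driver scan
for DMRs, and the DMG x selection-class chi-square association.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MISSING, GenotypeMatrix, MethylationMatrix
from .popgen import pca

log = logging.getLogger(__name__)

DRIVER_THRESHOLDS = (5e-5, 5e-6, 5e-7, 5e-8)

# variability category cutoffs as published: ranks 1-10000 / -50000 / -150000
# of 588,659 loci; for smaller panels the same fractions of the locus count.
_CATEGORY_RANKS = (10_000, 50_000, 150_000)
_CATEGORY_UNIVERSE = 588_659


def classify_cg_loss_loci(
    mat: MethylationMatrix, geno: GenotypeMatrix, reference
) -> pd.DataFrame:
    """Flag each CG locus that carries a CG-loss variant; attach its dosage row.

    A CG locus (C at ``pos``, G at ``pos + 1`` on the plus strand) carries a
    CG-loss variant when a SNP hits either base or an INDEL's reference span
    overlaps either base. Returns a frame (chrom, pos, carrying,
    variant_row) where variant_row indexes ``geno`` (-1 when non-carrying).
    """
    sites = geno.sites
    is_snp = sites["is_snp"].to_numpy()
    vpos = sites["pos"].to_numpy()
    vref = sites["ref"].to_numpy()
    vchrom = sites["chrom"].to_numpy()
    rows = {"chrom": [], "pos": [], "carrying": [], "variant_row": []}
    for chrom, csub in mat.sites.groupby("chrom", sort=False):
        cpos = csub["pos"].to_numpy()
        on = vchrom == chrom
        # build position -> variant-row lookup covering each variant's ref span
        span_pos: list[np.ndarray] = []
        span_row: list[np.ndarray] = []
        for row in np.flatnonzero(on):
            start = vpos[row]
            end = start + max(len(vref[row]), 1)  # ref span, half-open
            if not is_snp[row] and len(vref[row]) == 1:
                end = start + 1  # insertion anchored at the base
            span = np.arange(start, end)
            span_pos.append(span)
            span_row.append(np.full(len(span), row))
        if span_pos:
            allpos = np.concatenate(span_pos)
            allrow = np.concatenate(span_row)
            order = np.argsort(allpos, kind="stable")
            allpos, allrow = allpos[order], allrow[order]
        else:
            allpos = np.empty(0, dtype=int)
            allrow = np.empty(0, dtype=int)
        seq = str(reference[chrom][:]).upper() if reference is not None else None
        for p in cpos:
            if seq is not None and seq[p - 1] != "C":
                raise ValueError(f"CG locus {chrom}:{p} is {seq[p - 1]!r}, not C, in reference")
            hit = -1
            for q in (p, p + 1):
                lo = np.searchsorted(allpos, q, side="left")
                if lo < len(allpos) and allpos[lo] == q:
                    hit = int(allrow[lo])
                    break
            rows["chrom"].append(chrom)
            rows["pos"].append(int(p))
            rows["carrying"].append(hit >= 0)
            rows["variant_row"].append(hit)
    return pd.DataFrame(rows)


def cg_loss_regression(dosage: np.ndarray, beta: np.ndarray) -> tuple[float, float]:
    """OLS of per-sample beta on alt-allele dosage: (slope, r_squared)."""
    d = np.asarray(dosage, dtype=float)
    b = np.asarray(beta, dtype=float)
    ok = (d != MISSING) & ~np.isnan(d) & ~np.isnan(b)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    d, b = d[ok], b[ok]
    if np.ptp(d) == 0:
        return float("nan"), float("nan")
    res = stats.linregress(d, b)
    return float(res.slope), float(res.rvalue**2)


def cg_loss_regression_table(
    loci: pd.DataFrame, mat: MethylationMatrix, geno: GenotypeMatrix
) -> pd.DataFrame:
    """Vectorized per-locus OLS of beta on CG-loss dosage for carrying loci."""
    key = pd.MultiIndex.from_frame(mat.sites[["chrom", "pos"]])
    idx = key.get_indexer(pd.MultiIndex.from_frame(loci[["chrom", "pos"]]))
    beta = mat.beta
    out = loci.copy()
    slopes = np.full(len(loci), np.nan)
    r2 = np.full(len(loci), np.nan)
    carrying = loci["carrying"].to_numpy() & (idx >= 0)
    for i in np.flatnonzero(carrying):
        d = geno.dosage[int(loci["variant_row"].iloc[i])].astype(float)
        d[d == MISSING] = np.nan
        slopes[i], r2[i] = cg_loss_regression(d, beta[idx[i]])
    out["slope"] = slopes
    out["r_squared"] = r2
    return out


def variability_categories(mat: MethylationMatrix) -> pd.DataFrame:
    """Ordinal epigenetic-variability labels from the cross-sample beta SD.

    Ranks by descending SD; rank cutoffs are 10,000 / 50,000 / 150,000 when
    at least 150,000 loci are present, otherwise the same fractions of the
    588,659-locus universe those counts correspond to, applied to this panel.
    """
    beta = mat.beta
    with np.errstate(invalid="ignore"):
        sd = np.array([np.nanstd(row, ddof=1) if (~np.isnan(row)).sum() >= 2 else np.nan
                       for row in beta])
    n = len(sd)
    if n >= _CATEGORY_RANKS[-1]:
        cuts = _CATEGORY_RANKS
    else:
        cuts = tuple(max(1, int(round(n * c / _CATEGORY_UNIVERSE))) for c in _CATEGORY_RANKS)
        log.info("variability cutoffs scaled to %s for %d loci", cuts, n)
    order = np.argsort(np.where(np.isnan(sd), -np.inf, sd), kind="stable")[::-1]
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    labels = np.full(n, "low", dtype=object)
    labels[rank <= cuts[2]] = "moderate"
    labels[rank <= cuts[1]] = "high"
    labels[rank <= cuts[0]] = "very high"
    labels[np.isnan(sd)] = "low"
    out = mat.sites[["chrom", "pos"]].copy()
    out["beta_sd"] = sd
    out["rank"] = rank
    out["category"] = labels
    return out


def compute_structure_pcs(geno: GenotypeMatrix, n_pcs: int = 10) -> np.ndarray:
    """Top sample PCs of the standardized genome-wide dosage matrix."""
    d = geno.dosage.astype(float)
    d[d == MISSING] = np.nan
    coords, _ = pca(d, n_components=n_pcs, standardize=True)
    return coords


def eigenstrat_assoc(
    phenotype: np.ndarray, dosages: np.ndarray, pcs: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA-corrected association: chi2 = (n - k - 1) * r^2 on residuals.

    ``dosages`` is (m, n); missing dosage entries are mean-imputed. Returns
    per-variant (chi2, p) with 1 df.
    """
    y = np.asarray(phenotype, dtype=float)
    X = np.asarray(dosages, dtype=float)
    if X.ndim == 1:
        X = X[None]
    X = X.copy()
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=1, keepdims=True)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu[:, 0], inds[0])
    n = len(y)
    k = 0 if pcs is None else pcs.shape[1]
    design = np.ones((n, 1)) if pcs is None else np.column_stack([np.ones(n), pcs])
    proj, *_ = np.linalg.lstsq(design, y, rcond=None)
    ry = y - design @ proj
    projX, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    rX = X.T - design @ projX
    with np.errstate(invalid="ignore", divide="ignore"):
        num = rX.T @ ry
        den = np.sqrt((rX**2).sum(axis=0) * (ry**2).sum())
        r = np.where(den > 0, num / den, 0.0)
    dof = n - k - 1
    chi2 = dof * r**2
    return chi2, stats.chi2.sf(chi2, df=1)


def genomic_control_lambda(chi2_values: np.ndarray) -> float:
    """Median chi-square over the chi2(1) median (0.4549...)."""
    return float(np.median(chi2_values) / stats.chi2.ppf(0.5, df=1))


def cis_driver_scan(
    dmrs: pd.DataFrame,
    geno: GenotypeMatrix,
    mat: MethylationMatrix,
    flank: int = 500,
    n_pcs: int = 10,
    thresholds: tuple[float, ...] = DRIVER_THRESHOLDS,
    pcs: np.ndarray | None = None,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Per-DMR best cis association within +-flank bp, PCA-corrected.

    The DMR phenotype is the per-sample pooled beta over the window's covered
    sites. A DMR is 'associated' at a threshold when any candidate variant's
    p value falls below it (no per-DMR multiplicity correction: the question
    is whether at least one plausible driving mutation exists).
    """
    if pcs is None:
        pcs = compute_structure_pcs(geno, n_pcs=n_pcs)
    vchrom = geno.sites["chrom"].to_numpy()
    vpos = geno.sites["pos"].to_numpy()
    rows = []
    n_skipped = 0
    for _, dmr in dmrs.iterrows():
        on = (mat.sites["chrom"] == dmr["chrom"]).to_numpy()
        pos0 = mat.sites["pos"].to_numpy() - 1
        in_win = on & (pos0 >= dmr["start"]) & (pos0 < dmr["end"])
        cov = mat.covered[in_win]
        m = np.where(cov, mat.meth[in_win], 0).sum(axis=0).astype(float)
        t = np.where(cov, mat.total[in_win], 0).sum(axis=0).astype(float)
        has = t > 0
        if has.sum() < min_samples:
            n_skipped += 1
            continue
        y = m[has] / t[has]
        cand = np.flatnonzero(
            (vchrom == dmr["chrom"])
            & (vpos >= dmr["start"] + 1 - flank)
            & (vpos <= dmr["end"] + flank)
        )
        best_p, best_row = np.nan, -1
        if len(cand):
            chi2, p = eigenstrat_assoc(y, geno.dosage[cand][:, has], pcs[has])
            j = int(np.argmin(p))
            best_p, best_row = float(p[j]), int(cand[j])
        rec = {
            "chrom": dmr["chrom"],
            "start": int(dmr["start"]),
            "end": int(dmr["end"]),
            "n_candidates": len(cand),
            "best_variant_row": best_row,
            "best_p": best_p,
        }
        for thr in thresholds:
            rec[f"associated_p<{thr:g}"] = bool(best_p < thr) if np.isfinite(best_p) else False
        rows.append(rec)
    if n_skipped:
        log.info("cis-driver scan skipped %d DMRs with <%d phenotyped samples", n_skipped, min_samples)
    out = pd.DataFrame(rows)
    out.attrs["thresholds"] = thresholds
    if len(out):
        out.attrs["associated_fraction"] = {
            thr: float(out[f"associated_p<{thr:g}"].mean()) for thr in thresholds
        }
    return out


def dmg_selection_chisq(
    dmgs: pd.DataFrame, selection: pd.DataFrame, comparison: str
) -> pd.DataFrame:
    """Association rows (per selection type) between DMG status and selection.

    The gene universe is the genes present in both tables with a defined
    selection class. Chi-square without continuity correction; p values are
    reported unadjusted.
    """
    sel = selection[selection["selection_class"] != "undefined"]
    merged = dmgs.merge(sel, on="gene_id", suffixes=("_dmg", "_sel"))
    if len(merged) == 0:
        raise ValueError("no gene with both methylation coverage and a defined selection class")
    if not merged["is_dmg"].any():
        raise ValueError("empty DMG set for association test")
    rows = []
    for sel_type in ("positive", "purifying"):
        is_sel = (merged["selection_class"] == sel_type).to_numpy()
        is_dmg = merged["is_dmg"].to_numpy()
        table = np.array(
            [
                [np.sum(is_dmg & is_sel), np.sum(is_dmg & ~is_sel)],
                [np.sum(~is_dmg & is_sel), np.sum(~is_dmg & ~is_sel)],
            ]
        )
        if table[0].sum() == 0 or table[1].sum() == 0 or (table.sum(axis=0) == 0).any():
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {
                "comparison": comparison,
                "selection_type": sel_type,
                "pct_dmg_selected": 100.0 * table[0, 0] / table[0].sum(),
                "pct_non_dmg_selected": 100.0 * table[1, 0] / table[1].sum(),
                "chi2": chi2,
                "p_value": p,
                "n_dmg": int(table[0].sum()),
                "n_non_dmg": int(table[1].sum()),
            }
        )
    return pd.DataFrame(rows)
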