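"""Methylome summaries: global levels, PCA, MDI, CG islands, metaprofiles.

Pooled beta always means sum(meth) / sum(total) over the covered entries in
question — a read-weighted mean, so deep sites weigh more.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import GeneModel, MethylationMatrix, SampleSheet
from .popgen import pca

log = logging.getLogger(__name__)


def build_methylation_matrix(
    raw: MethylationMatrix, min_depth: int = 3
) -> MethylationMatrix:
    """Apply the per-sample depth threshold; error when nothing is usable."""
    mat = MethylationMatrix(
        raw.sites, raw.meth, raw.total, raw.samples, min_depth=min_depth
    )
    if not mat.covered.any():
        raise ValueError("no site passes the depth threshold in any sample")
    return mat


def global_methylation_level(mat: MethylationMatrix, sample: str) -> float:
    """Genome-wide weighted methylation percentage for one sample."""
    j = mat.samples.index(sample)
    cov = mat.covered[:, j]
    total = mat.total[cov, j].sum()
    if total == 0:
        return float("nan")
    return 100.0 * mat.meth[cov, j].sum() / total


def methylome_pca(mat: MethylationMatrix, n_components: int = 10, qc_fraction: float = 0.8):
    """PCA of centered (non-standardized) beta at QC-passing sites."""
    mask = mat.qc_mask(qc_fraction)
    if not mask.any():
        raise ValueError("no site passes the PCA coverage QC")
    return pca(mat.beta[mask], n_components=n_components, standardize=False)


def _window_pooled_beta(
    mat: MethylationMatrix, j: int, chromosome: str, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """(window ids, pooled beta) for one sample on one chromosome."""
    on = (mat.sites["chrom"] == chromosome).to_numpy()
    pos0 = mat.sites.loc[on, "pos"].to_numpy() - 1
    wid = pos0 // window
    cov = mat.covered[on, j]
    meth = np.where(cov, mat.meth[on, j], 0)
    total = np.where(cov, mat.total[on, j], 0)
    nw = int(wid.max()) + 1 if len(wid) else 0
    msum = np.bincount(wid, weights=meth, minlength=nw)
    tsum = np.bincount(wid, weights=total, minlength=nw)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(tsum > 0, msum / tsum, np.nan)
    return np.arange(nw), beta


def compute_mdi(
    mat: MethylationMatrix,
    sample: str,
    reference_sample: str,
    chromosome: str,
    window: int = 100_000,
) -> float:
    """Chromosomal methylation discrepancy index.

    MDI = (100 / |W|) * sum over windows |pooled beta(sample) - pooled
    beta(reference)|, over the windows where both samples have at least one
    covered site. NaN when no window is shared.
    """
    js = mat.samples.index(sample)
    jr = mat.samples.index(reference_sample)
    _, bs = _window_pooled_beta(mat, js, chromosome, window)
    _, br = _window_pooled_beta(mat, jr, chromosome, window)
    n = min(len(bs), len(br))
    both = ~np.isnan(bs[:n]) & ~np.isnan(br[:n])
    if not both.any():
        return float("nan")
    return float(100.0 * np.mean(np.abs(bs[:n][both] - br[:n][both])))


def detect_cg_islands(
    sequence: str,
    chromosome: str = "",
    window: int = 100,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    min_length: int = 200,
) -> pd.DataFrame:
    """Gardiner-Garden/Frommer CpG-island scan (cpgplot-style criteria).

    Every ``window``-bp window (step 1) is flagged when GC > ``min_gc`` and
    observed/expected CpG > ``min_obs_exp``; the union of flagged windows is
    merged into runs and runs longer than ``min_length`` are islands
    (0-based half-open intervals). Ns are excluded from composition; windows
    that are more than half N are skipped.
    """
    seq = sequence.upper()
    L = len(seq)
    if L < window:
        return pd.DataFrame(columns=["chrom", "start", "end", "gc_fraction", "obs_exp_cpg"])
    arr = np.frombuffer(seq.encode(), dtype="S1")
    isC = (arr == b"C").astype(np.int64)
    isG = (arr == b"G").astype(np.int64)
    isN = (~np.isin(arr, [b"A", b"C", b"G", b"T"])).astype(np.int64)
    isCpG = np.zeros(L, dtype=np.int64)
    isCpG[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")

    def wsum(x: np.ndarray, w: int) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(x)])
        return c[w:] - c[:-w]

    nC = wsum(isC, window)
    nG = wsum(isG, window)
    nN = wsum(isN, window)
    # CpG whose two bases both lie inside the window: start positions i..i+w-2
    nCpG = wsum(isCpG, window - 1)[: L - window + 1]
    eff = window - nN
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(eff > 0, (nC + nG) / eff, 0.0)
        exp = np.where(eff > 0, nC * nG / eff, 0.0)
        oe = np.where(exp > 0, nCpG / exp, 0.0)
    flagged = (gc > min_gc) & (oe > min_obs_exp) & (nN <= window // 2)

    covered = np.zeros(L + 1, dtype=np.int64)
    starts = np.flatnonzero(flagged)
    if len(starts) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "gc_fraction", "obs_exp_cpg"])
    np.add.at(covered, starts, 1)
    np.add.at(covered, starts + window, -1)
    mask = np.cumsum(covered[:-1]) > 0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    rows = []
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s > min_length:
            span = arr[s:e]
            c = int((span == b"C").sum())
            g = int((span == b"G").sum())
            n = int(np.isin(span, [b"A", b"C", b"G", b"T"]).sum())
            cpg = int(((span[:-1] == b"C") & (span[1:] == b"G")).sum())
            exp_i = c * g / n if n else 0.0
            rows.append(
                (
                    chromosome,
                    int(s),
                    int(e),
                    (c + g) / n if n else 0.0,
                    cpg / exp_i if exp_i else 0.0,
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc_fraction", "obs_exp_cpg"])


def _accumulate_profile(
    bins: np.ndarray,
    site_rows: np.ndarray,
    mat: MethylationMatrix,
    group_idx: np.ndarray,
    n_bins: int,
    meth_acc: np.ndarray,
    total_acc: np.ndarray,
) -> None:
    cov = mat.covered[np.ix_(site_rows, group_idx)]
    m = np.where(cov, mat.meth[np.ix_(site_rows, group_idx)], 0).sum(axis=1)
    t = np.where(cov, mat.total[np.ix_(site_rows, group_idx)], 0).sum(axis=1)
    np.add.at(meth_acc, bins, m)
    np.add.at(total_acc, bins, t)


def gene_metaprofile(
    mat: MethylationMatrix,
    genes: list[GeneModel],
    groups: dict[str, np.ndarray],
    flank: int = 5000,
    bin_size: int = 100,
    body_bins: int = 100,
) -> pd.DataFrame:
    """Strand-aware pooled-beta profile over flank-body-flank bins per group.

    Flanks are binned at ``bin_size`` (flank/bin_size bins each side); the
    gene body is linearly rescaled to ``body_bins`` bins; TSS is always on
    the left. Returns long-format rows (group, bin, beta, total_reads).
    """
    flank_bins = flank // bin_size
    n_bins = 2 * flank_bins + body_bins
    chrom_arr = mat.sites["chrom"].to_numpy()
    pos0_arr = mat.sites["pos"].to_numpy() - 1
    accs = {g: (np.zeros(n_bins), np.zeros(n_bins)) for g in groups}
    for gene in genes:
        on = np.flatnonzero(
            (chrom_arr == gene.chromosome)
            & (pos0_arr >= gene.start - 1 - flank)
            & (pos0_arr < gene.end + flank)
        )
        if len(on) == 0:
            continue
        pos0 = pos0_arr[on]
        body_len = gene.end - gene.start + 1
        if gene.strand == "+":
            u = pos0 - (gene.start - 1)
        else:
            u = (gene.end - 1) - pos0
        bins = np.empty(len(on), dtype=np.int64)
        up = u < 0
        body = (u >= 0) & (u < body_len)
        down = u >= body_len
        bins[up] = flank_bins + np.floor(u[up] / bin_size).astype(np.int64)
        bins[body] = flank_bins + np.minimum(
            (u[body] * body_bins) // body_len, body_bins - 1
        )
        bins[down] = (
            flank_bins
            + body_bins
            + np.minimum((u[down] - body_len) // bin_size, flank_bins - 1)
        )
        keep = (bins >= 0) & (bins < n_bins)
        if body_len < body_bins:
            log.debug("gene %s shorter than bin resolution; body bins sparse", gene.gene_id)
        for gname, gidx in groups.items():
            _accumulate_profile(
                bins[keep], on[keep], mat, gidx, n_bins, *accs[gname]
            )
    return _profiles_to_frame(accs, flank_bins, body_bins, interpolate_body=True)


def cgi_metaprofile(
    mat: MethylationMatrix,
    islands: pd.DataFrame,
    groups: dict[str, np.ndarray],
    shore: int = 2000,
    bin_size: int = 100,
    body_bins: int = 40,
) -> pd.DataFrame:
    """Pooled-beta profile across CG islands (scaled body) and their shores."""
    shore_bins = shore // bin_size
    n_bins = 2 * shore_bins + body_bins
    chrom_arr = mat.sites["chrom"].to_numpy()
    pos0_arr = mat.sites["pos"].to_numpy() - 1
    accs = {g: (np.zeros(n_bins), np.zeros(n_bins)) for g in groups}
    if len(islands) == 0:
        log.warning("no CG islands supplied; empty metaprofile")
    for _, isl in islands.iterrows():
        on = np.flatnonzero(
            (chrom_arr == isl["chrom"])
            & (pos0_arr >= isl["start"] - shore)
            & (pos0_arr < isl["end"] + shore)
        )
        if len(on) == 0:
            continue
        pos0 = pos0_arr[on]
        body_len = int(isl["end"] - isl["start"])
        u = pos0 - int(isl["start"])
        bins = np.empty(len(on), dtype=np.int64)
        up = u < 0
        body = (u >= 0) & (u < body_len)
        down = u >= body_len
        bins[up] = shore_bins + np.floor(u[up] / bin_size).astype(np.int64)
        bins[body] = shore_bins + np.minimum((u[body] * body_bins) // body_len, body_bins - 1)
        bins[down] = (
            shore_bins + body_bins + np.minimum((u[down] - body_len) // bin_size, shore_bins - 1)
        )
        keep = (bins >= 0) & (bins < n_bins)
        for gname, gidx in groups.items():
            _accumulate_profile(bins[keep], on[keep], mat, gidx, n_bins, *accs[gname])
    return _profiles_to_frame(accs, shore_bins, body_bins, interpolate_body=False)


def _profiles_to_frame(
    accs: dict[str, tuple[np.ndarray, np.ndarray]],
    flank_bins: int,
    body_bins: int,
    interpolate_body: bool,
) -> pd.DataFrame:
    frames = []
    for gname, (m, t) in accs.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(t > 0, m / t, np.nan)
        if interpolate_body:
            body = slice(flank_bins, flank_bins + body_bins)
            b = beta[body]
            if np.isnan(b).any() and (~np.isnan(b)).sum() >= 2:
                x = np.arange(len(b))
                b[np.isnan(b)] = np.interp(x[np.isnan(b)], x[~np.isnan(b)], b[~np.isnan(b)])
                beta[body] = b
        frames.append(
            pd.DataFrame(
                {
                    "group": gname,
                    "bin": np.arange(len(beta)),
                    "beta": beta,
                    "total_reads": t,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group", "bin", "beta", "total_reads"]
    )
    out.attrs["flank_bins"] = flank_bins
    out.attrs["body_bins"] = body_bins
    return out


def group_indices(sheet: SampleSheet, labels: list[str]) -> dict[str, np.ndarray]:
    return {lab: sheet.clade_indices(lab) for lab in labels}
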