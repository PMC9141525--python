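"""Conservative clade-specific variant (CCV) calling.

A CCV is a high-impact variant (frameshift, stop gain/loss, start loss,
splicing alteration) that is homozygous-alternate in every non-hybrid sample
of the carrier clade and homozygous-reference in every non-hybrid sample of
the reference clade. A het or missing call anywhere in either clade
disqualifies the variant — conservation must hold across all samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import HIGH_IMPACT_CLASSES, GeneModel, GenotypeMatrix, SampleSheet
from .io import CCV_COLUMNS

log = logging.getLogger(__name__)


def classify_impact(consequence: str) -> str | None:
    """Map a consequence string to one of the five CCV impact classes."""
    for token in str(consequence).split("&"):
        if token in HIGH_IMPACT_CLASSES:
            return HIGH_IMPACT_CLASSES[token]
    return None


def call_ccvs(
    geno: GenotypeMatrix,
    sheet: SampleSheet,
    carrier: str,
    reference: str,
) -> pd.DataFrame:
    """Table-1-shaped CCV records for one ordered (carrier, reference) pair."""
    if carrier == reference:
        raise ValueError("carrier and reference clade must differ")
    idx_c = sheet.clade_indices(carrier)
    idx_r = sheet.clade_indices(reference)
    if set(idx_c) & set(idx_r):
        raise ValueError("carrier and reference clades overlap")
    impact = geno.sites["consequence"].map(classify_impact)
    candidate = impact.notna().to_numpy()
    d = geno.dosage
    conserved_alt = (d[:, idx_c] == 2).all(axis=1)
    absent_ref = (d[:, idx_r] == 0).all(axis=1)
    hit = candidate & conserved_alt & absent_ref
    sub = geno.sites.loc[hit]
    out = pd.DataFrame(
        {
            "gene_id": sub["gene_id"].to_numpy(),
            "carrier_clade": carrier,
            "reference_clade": reference,
            "chromosome": sub["chrom"].to_numpy(),
            "position": sub["pos"].to_numpy(),
            "ref_allele": sub["ref"].to_numpy(),
            "alt_allele": sub["alt"].to_numpy(),
            "impact_class": impact.loc[hit].to_numpy(),
            "context": "",
        },
        columns=CCV_COLUMNS,
    )
    n_unknown = int((geno.sites["consequence"] == "unknown").sum())
    if n_unknown:
        log.info("%d records with unknown consequence ignored by CCV calling", n_unknown)
    return out.reset_index(drop=True)


def annotate_ccv_context(ccvs: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Flag each CCV genic/intergenic by gene-body overlap; report genic fraction."""
    out = ccvs.copy()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
    context = []
    for chrom, pos in zip(out["chromosome"], out["position"]):
        genic = any(s <= pos <= e for s, e in by_chrom.get(chrom, ()))
        context.append("genic" if genic else "intergenic")
    out["context"] = context
    frac = float(np.mean([c == "genic" for c in context])) if context else np.nan
    out.attrs["genic_fraction"] = frac
    return out
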