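"""Group-specific alternative splicing from per-isoform count tables.

Per-sample relative isoform abundance (isoform counts / gene total) is
computed for genes that are expressed and have more than one annotated
transcript.  Transcripts whose mean ratio in the target cohort differs from
every other cohort (DTK, same machinery as the expression module) are
called alternatively spliced; the AS gene list is the genes of the flagged
transcripts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expression import (
    LOW_EXPRESSION_THRESHOLD,
    call_group_specific,
    dtk_pairwise,
    filter_low_expression,
)

logger = logging.getLogger(__name__)


def isoform_ratios(
    iso_counts: pd.DataFrame,
    transcript_to_gene: pd.Series,
    gene_counts: pd.DataFrame,
    groups: pd.Series,
    threshold: float = LOW_EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Relative isoform abundance for eligible genes.

    Eligible genes are expressed (group-median count > ``threshold`` in at
    least one group, the same gate as the expression filter) and have >= 2
    isoforms.  The ratio is the isoform's count divided by the per-sample
    total over the gene's isoforms; samples where that total is zero get a
    missing ratio.  Returns transcripts x samples with NaN for missing.
    """
    unknown = set(iso_counts.index) - set(transcript_to_gene.index)
    if unknown:
        raise KeyError(f"transcripts with unknown gene: {sorted(unknown)[:5]}")
    t2g = transcript_to_gene.reindex(iso_counts.index)

    expressed = set(filter_low_expression(gene_counts, groups, threshold).index)
    n_iso = t2g.groupby(t2g).size()
    multi = set(n_iso.index[n_iso >= 2])
    eligible_genes = expressed & multi

    keep = t2g.isin(eligible_genes)
    iso = iso_counts.loc[keep].astype(float)
    gene_totals = iso.groupby(t2g.loc[keep]).transform("sum")
    ratios = iso / gene_totals.where(gene_totals > 0)
    return ratios


def call_group_specific_splicing(
    ratios: pd.DataFrame,
    groups: pd.Series,
    target_group: str = "HER2",
    alpha: float = 0.05,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """DTK on isoform ratios; flag transcripts target-specific in ratio.

    Transcripts with fewer than ``min_per_group`` non-missing ratios in any
    group are skipped (logged).  Missing-ratio samples are dropped per
    transcript — unequal group sizes are exactly what DTK supports.
    """
    groups = groups.reindex(ratios.columns)
    group_names = list(pd.unique(groups.dropna()))
    results = {}
    for tx in ratios.index:
        row = ratios.loc[tx]
        vals = {}
        ok = True
        for g in group_names:
            v = row[groups == g].dropna().to_numpy()
            if v.size < min_per_group:
                logger.info("transcript %s skipped: <%d ratios in group %s", tx, min_per_group, g)
                ok = False
                break
            vals[g] = v
        if not ok:
            continue
        results[tx] = dtk_pairwise(vals, alpha=alpha, compute_ci=False)
    if not results:
        return pd.DataFrame(columns=["is_DE", "direction", "p_max"])
    return call_group_specific(results, target_group=target_group, alpha=alpha)


def as_gene_list(calls: pd.DataFrame, transcript_to_gene: pd.Series) -> set[str]:
    """Genes with at least one flagged alternatively spliced transcript."""
    flagged = calls.index[calls["is_DE"]]
    return set(transcript_to_gene.reindex(flagged).dropna())
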