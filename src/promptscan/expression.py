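"""Exonic counting, TPM, gene inclusion/exclusion rules, and a differential
expression stand-in.

Counting follows featureCounts-style semantics: a read on the gene's strand
that overlaps at least one base of any exon is counted once for that gene.
TPM is length-normalised rate scaled so the per-sample sum is 1e6.

The differential caller is a deliberately simple stand-in for a negative
binomial GLM framework: median-of-ratios size factors, a Welch t-test on
log2 normalised counts (or a two-sided binomial test when only one replicate
per condition exists), Benjamini–Hochberg correction, and the published
classification gates (fold >= 2, padj <= 0.05).  It does not shrink
dispersions and should not be used as a general DE method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageError, StrandedCoverage, region_mean
from .genome_intervals import AnalysisParams, GeneModel, GenomicInterval

__all__ = [
    "GeneExpression",
    "count_exonic",
    "compute_tpm",
    "filter_expressed",
    "upstream_readthrough_filter",
    "call_upregulated",
    "size_factors",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneExpression:
    """Per-gene expression summary with classification flags."""

    gene_id: str
    exonic_length: int
    tpm_control: float = float("nan")
    tpm_condition: float = float("nan")
    log2fc: float = float("nan")
    fdr: float = float("nan")
    flags: set[str] = field(default_factory=set)


def count_exonic(reads: Iterable[GenomicInterval], gene: GeneModel) -> int:
    """Reads on the gene's strand overlapping >= 1 bp of any exon, each once."""
    n = 0
    for read in reads:
        if read.strand != gene.strand or read.chrom != gene.chrom:
            continue
        if any(read.start < ex.end and ex.start < read.end for ex in gene.exons):
            n += 1
    return n


def compute_tpm(
    counts: Sequence[float] | np.ndarray, exonic_lengths: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Transcripts per million from raw counts and exonic lengths (bp)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(exonic_lengths, dtype=float)
    if np.any(lengths < 1):
        raise ValueError("exonic lengths must be >= 1 bp")
    rates = counts / (lengths / 1000.0)
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return rates * 1e6 / total


def filter_expressed(
    exprs: Sequence[GeneExpression], params: AnalysisParams | None = None
) -> list[GeneExpression]:
    """Keep genes with control TPM >= tpm_min; flag the rest low_expression.

    The cut is strict as published: TPM < 5 is removed, TPM = 5.0 retained.
    """
    params = params or AnalysisParams()
    kept: list[GeneExpression] = []
    for e in exprs:
        if e.tpm_control < params.tpm_min:
            e.flags.add("low_expression")
        else:
            kept.append(e)
    return kept


def upstream_readthrough_filter(
    genes: Sequence[GeneModel],
    cov_control: StrandedCoverage,
    cov_condition: StrandedCoverage,
    params: AnalysisParams | None = None,
) -> dict[str, bool]:
    """Flag genes whose upstream sense signal rises on depletion.

    For each gene the sense-strand mean over the 1 kb window preceding the
    TSS is compared between conditions; a gene is flagged as contaminated by
    read-through from an upstream unit iff
    ``log2((m_cond + p) / (m_ctrl + p)) >= log2fc_up_threshold``.
    Genes whose window lies entirely off-chromosome are skipped with a warning.
    """
    params = params or AnalysisParams()
    if cov_control.normalisation != cov_condition.normalisation:
        raise CoverageError("tracks must share normalisation")
    w = params.upstream_filter_window
    p = params.pseudocount
    out: dict[str, bool] = {}
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - w, g.tss
        else:
            start, end = g.tss, g.tss + w
        try:
            window = GenomicInterval(g.chrom, max(0, start), end, g.strand)
            m_ctrl = region_mean(cov_control, window, "sense")
            m_cond = region_mean(cov_condition, window, "sense")
        except (ValueError, CoverageError):
            logger.warning("gene %s: upstream window off-chromosome, skipped", g.gene_id)
            continue
        out[g.gene_id] = bool(
            np.log2((m_cond + p) / (m_ctrl + p)) >= params.log2fc_up_threshold
        )
    return out


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples matrix).

    Genes with a zero in any sample are excluded from the reference; when no
    gene survives, total-count factors scaled to mean 1 are used instead.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if positive.sum() >= 1:
        logref = np.mean(np.log(counts[positive]), axis=1)
        sf = np.exp(
            np.median(np.log(counts[positive]) - logref[:, None], axis=0)
        )
    else:
        totals = counts.sum(axis=0)
        sf = totals / totals.mean()
    return sf


def call_upregulated(
    counts_control: np.ndarray,
    counts_condition: np.ndarray,
    params: AnalysisParams | None = None,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Differential upregulation stand-in (genes x replicates per condition).

    Returns a DataFrame with log2fc, pvalue, fdr and the boolean
    ``upregulated`` call (fold >= fold_up_threshold AND fdr <= fdr_threshold).
    """
    params = params or AnalysisParams()
    ctrl = np.atleast_2d(np.asarray(counts_control, dtype=float))
    cond = np.atleast_2d(np.asarray(counts_condition, dtype=float))
    if ctrl.ndim != 2 or cond.ndim != 2 or ctrl.shape[0] != cond.shape[0]:
        raise ValueError("count matrices must be genes x replicates, same genes")
    if ctrl.shape[1] == 0 or cond.shape[1] == 0:
        raise ValueError("each condition needs at least one replicate")
    n_genes = ctrl.shape[0]
    sf = size_factors(np.hstack([ctrl, cond]))
    norm_ctrl = ctrl / sf[: ctrl.shape[1]]
    norm_cond = cond / sf[ctrl.shape[1] :]
    p = params.pseudocount
    mean_ctrl = norm_ctrl.mean(axis=1)
    mean_cond = norm_cond.mean(axis=1)
    log2fc = np.log2((mean_cond + p) / (mean_ctrl + p))

    if ctrl.shape[1] >= 2 and cond.shape[1] >= 2:
        # Welch t on log2 normalised counts (+1 to keep zeros finite)
        t, pvals = stats.ttest_ind(
            np.log2(norm_cond + 1.0),
            np.log2(norm_ctrl + 1.0),
            axis=1,
            equal_var=False,
        )
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
    else:
        # single replicate: exact two-sided binomial split of the pooled count
        s_ctrl = sf[: ctrl.shape[1]].sum()
        s_cond = sf[ctrl.shape[1] :].sum()
        frac = s_cond / (s_ctrl + s_cond)
        pvals = np.ones(n_genes)
        tot = (ctrl.sum(axis=1) + cond.sum(axis=1)).astype(int)
        x = cond.sum(axis=1).astype(int)
        for i in range(n_genes):
            if tot[i] > 0:
                pvals[i] = stats.binomtest(x[i], tot[i], frac).pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]
    upregulated = ((2.0 ** log2fc) >= params.fold_up_threshold) & (
        fdr <= params.fdr_threshold
    )
    index = list(gene_ids) if gene_ids is not None else list(range(n_genes))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "upregulated": upregulated,
        },
        index=pd.Index(index, name="gene_id"),
    )
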