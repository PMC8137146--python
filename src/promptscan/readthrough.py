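"""Transcription read-through quantification at transcription end sites.

For each gene, sense-strand coverage means are taken over the gene body, the
500 bp directly preceding the TES (the PAS-proximal window) and the first
1 kb downstream of the TES, all oriented by strand.  The read-through index
is ``(post_TES_mean + p) / (denominator + p)`` with a small pseudocount; the
condition contrast is the log2 ratio depletion/control of the two indices,
positive when termination fails more often on depletion.

Two denominators appear in common use — the full gene body and the 500 bp
pre-TES window.  Both are computed on every record; the body is the primary
default and ``denominator="pre_tes"`` switches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import StrandedCoverage, region_mean
from .genome_intervals import AnalysisParams, GeneModel, GenomicInterval

__all__ = [
    "ReadthroughRecord",
    "readthrough_record",
    "readthrough_delta",
    "readthrough_table",
]

logger = logging.getLogger(__name__)

Denominator = Literal["body", "pre_tes"]


@dataclass(frozen=True)
class ReadthroughRecord:
    gene_id: str
    condition: str
    body_mean: float
    pre_tes_mean: float
    post_tes_mean: float
    rt_index: float
    denominator: Denominator = "body"
    post_tes_overlaps_gene: bool = False

    def __post_init__(self) -> None:
        if not (self.rt_index > 0 and np.isfinite(self.rt_index)):
            raise ValueError("rt_index must be positive and finite")


def _tes_windows(gene: GeneModel, params: AnalysisParams) -> tuple[
    GenomicInterval, GenomicInterval
]:
    """(pre-TES, post-TES) windows in genomic coordinates, oriented by strand."""
    w_pre, w_post = params.pre_tes_window, params.post_tes_window
    if gene.strand == "+":
        pre = GenomicInterval(gene.chrom, gene.tes - w_pre, gene.tes, "+")
        post = GenomicInterval(gene.chrom, gene.tes, gene.tes + w_post, "+")
    else:
        pre = GenomicInterval(gene.chrom, gene.tes, gene.tes + w_pre, "-")
        post = GenomicInterval(gene.chrom, gene.tes - w_post, gene.tes, "-")
    return pre, post


def readthrough_record(
    cov: StrandedCoverage,
    gene: GeneModel,
    params: AnalysisParams | None = None,
    condition: str = "",
    denominator: Denominator = "body",
    other_genes: Sequence[GeneModel] = (),
) -> ReadthroughRecord | None:
    """Window means and read-through index for one gene on one track.

    Returns None (with a warning) for genes shorter than the pre-TES window.
    The pseudocount keeps the index finite on all-zero tracks (index = 1).
    Genes whose post-TES window overlaps another annotated gene are flagged,
    not dropped.
    """
    params = params or AnalysisParams()
    if gene.span.length < params.pre_tes_window:
        logger.warning(
            "gene %s shorter than pre-TES window (%d bp), skipped",
            gene.gene_id,
            params.pre_tes_window,
        )
        return None
    pre, post = _tes_windows(gene, params)
    if post.end <= 0 or post.start >= cov.chrom_lengths[gene.chrom]:
        logger.warning("gene %s: post-TES window off-chromosome, skipped", gene.gene_id)
        return None
    body_mean = region_mean(cov, gene.span, "sense")
    pre_mean = region_mean(cov, pre, "sense")
    post_mean = region_mean(cov, post, "sense")
    p = params.pseudocount
    den = body_mean if denominator == "body" else pre_mean
    overlap = any(
        o.gene_id != gene.gene_id and o.span.overlaps(post) for o in other_genes
    )
    return ReadthroughRecord(
        gene_id=gene.gene_id,
        condition=condition,
        body_mean=body_mean,
        pre_tes_mean=pre_mean,
        post_tes_mean=post_mean,
        rt_index=(post_mean + p) / (den + p),
        denominator=denominator,
        post_tes_overlaps_gene=overlap,
    )


def readthrough_delta(ctrl: ReadthroughRecord, dep: ReadthroughRecord) -> float:
    """log2(depletion index / control index); positive = more read-through."""
    if ctrl.gene_id != dep.gene_id:
        raise ValueError(
            f"gene_id mismatch: {ctrl.gene_id!r} vs {dep.gene_id!r}"
        )
    return float(np.log2(dep.rt_index / ctrl.rt_index))


def readthrough_table(
    cov_ctrl: StrandedCoverage,
    cov_dep: StrandedCoverage,
    genes: Sequence[GeneModel],
    params: AnalysisParams | None = None,
    tpm: Mapping[str, float] | None = None,
    apply_neighbour_filter: bool = True,
    denominator: Denominator = "body",
) -> pd.DataFrame:
    """Batch read-through contrast over a gene set, sorted by delta descending.

    Gene filters are applied first: the 5 kb-neighbour exclusion (optional)
    and, when a TPM mapping is given, the TPM >= 5 expression filter.
    """
    from .genome_intervals import filter_nonneighbouring

    params = params or AnalysisParams()
    pool = list(genes)
    if apply_neighbour_filter:
        pool = filter_nonneighbouring(pool, params)
    if tpm is not None:
        pool = [g for g in pool if tpm.get(g.gene_id, 0.0) >= params.tpm_min]
    rows = []
    for g in pool:
        rec_c = readthrough_record(
            cov_ctrl, g, params, "control", denominator, other_genes=genes
        )
        rec_d = readthrough_record(
            cov_dep, g, params, "depleted", denominator, other_genes=genes
        )
        if rec_c is None or rec_d is None:
            continue
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "body_mean_ctrl": rec_c.body_mean,
                "body_mean_dep": rec_d.body_mean,
                "post_tes_mean_ctrl": rec_c.post_tes_mean,
                "post_tes_mean_dep": rec_d.post_tes_mean,
                "rt_index_ctrl": rec_c.rt_index,
                "rt_index_dep": rec_d.rt_index,
                "delta_log2": readthrough_delta(rec_c, rec_d),
                "post_tes_overlaps_gene": rec_c.post_tes_overlaps_gene,
            }
        )
    if not rows:
        logger.warning("read-through table is empty after filtering")
        return pd.DataFrame(
            columns=[
                "gene_id",
                "chrom",
                "strand",
                "body_mean_ctrl",
                "body_mean_dep",
                "post_tes_mean_ctrl",
                "post_tes_mean_dep",
                "rt_index_ctrl",
                "rt_index_dep",
                "delta_log2",
                "post_tes_overlaps_gene",
            ]
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["delta_log2", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
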