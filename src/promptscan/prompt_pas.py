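"""PROMPT window quantification, fold-change classes, and polyadenylation-
signal (PAS) density statistics.

PROMPTs are unstable transcripts initiated upstream and antisense of
protein-coding promoters.  Each parent gene defines an upstream antisense
window (3 kb by default); windows overlapping any other gene body are
dropped.  Per-window fold change between conditions classifies PROMPTs as
upregulated (log2FC >= 1, inclusive) or not, and the window sequence in
transcript orientation is scanned for the consensus PAS hexamer AWTAAA
(AATAAA or ATTAAA), counting overlapping matches, to give a per-kb density.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .coverage import StrandedCoverage, region_mean
from .genome_intervals import AnalysisParams, GeneModel, GenomicInterval

__all__ = [
    "PromptRegion",
    "PasDensity",
    "define_prompt_windows",
    "prompt_fc",
    "scan_pas",
    "pas_density",
    "split_density_by_class",
    "estimate_prompt_extent",
    "read_fasta",
    "write_fasta",
]

logger = logging.getLogger(__name__)

PAS_PATTERN = re.compile(r"(?=(A[AT]TAAA))")


@dataclass
class PromptRegion:
    prompt_id: str
    parent_gene: str
    window: GenomicInterval  # strand opposite the parent gene
    signal: dict[str, float] = field(default_factory=dict)
    log2fc: float = float("nan")
    upregulated: bool = False


@dataclass(frozen=True)
class PasDensity:
    prompt_id: str
    length_bp: int
    positions: tuple[int, ...]
    n_sites: int
    density: float  # sites per kb

    def __post_init__(self) -> None:
        if any(
            b <= a for a, b in zip(self.positions, self.positions[1:])
        ):
            raise ValueError("positions must be strictly increasing")


def define_prompt_windows(
    genes: Sequence[GeneModel],
    window_bp: int = 3000,
    chrom_lengths: Mapping[str, int] | None = None,
    all_genes: Sequence[GeneModel] | None = None,
) -> list[PromptRegion]:
    """Upstream antisense windows for a pre-filtered gene set.

    For a + gene with TSS t the window is ``[t - window_bp, t)`` on ``-``;
    mirrored for - genes.  Windows are clipped at chromosome edges; windows
    overlapping any other gene span (checked against ``all_genes`` when
    given, else ``genes``) are dropped with a warning.
    """
    pool = all_genes if all_genes is not None else genes
    out: list[PromptRegion] = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - window_bp, g.tss
        else:
            start, end = g.tss, g.tss + window_bp
        start = max(0, start)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[g.chrom])
        if start >= end:
            logger.warning("gene %s: PROMPT window fully clipped, dropped", g.gene_id)
            continue
        window = GenomicInterval(g.chrom, start, end, g.span.opposite_strand())
        hit = next(
            (o for o in pool if o.gene_id != g.gene_id and o.span.overlaps(window)),
            None,
        )
        if hit is not None:
            logger.warning(
                "gene %s: PROMPT window overlaps gene %s, dropped",
                g.gene_id,
                hit.gene_id,
            )
            continue
        out.append(
            PromptRegion(
                prompt_id=f"PROMPT_{g.gene_id}", parent_gene=g.gene_id, window=window
            )
        )
    return out


def prompt_fc(
    prompts: Sequence[PromptRegion],
    cov_ctrl: StrandedCoverage,
    cov_cond: StrandedCoverage,
    params: AnalysisParams | None = None,
) -> list[PromptRegion]:
    """Per-PROMPT condition means, log2FC and upregulation class (in place).

    The class boundary is inclusive: log2FC = 1.0 counts as upregulated.
    """
    params = params or AnalysisParams()
    if cov_ctrl.normalisation != cov_cond.normalisation:
        raise ValueError("tracks must share normalisation")
    p = params.pseudocount
    for pr in prompts:
        m_ctrl = region_mean(cov_ctrl, pr.window, "sense")
        m_cond = region_mean(cov_cond, pr.window, "sense")
        pr.signal = {"control": m_ctrl, "condition": m_cond}
        pr.log2fc = float(np.log2((m_cond + p) / (m_ctrl + p)))
        pr.upregulated = pr.log2fc >= params.log2fc_up_threshold
    return list(prompts)


def scan_pas(sequence: str) -> list[int]:
    """All start offsets of AWTAAA (AATAAA | ATTAAA), overlapping included.

    Case-insensitive; N never matches; sequences shorter than 6 give [].
    The scan is single-strand: callers supply the transcript-sense sequence
    (reverse-complemented for minus-strand windows).
    """
    return [m.start() for m in PAS_PATTERN.finditer(sequence.upper())]


def pas_density(
    prompts: Sequence[PromptRegion], genome: Mapping[str, str]
) -> list[PasDensity]:
    """PAS hexamer density (sites per kb) over each PROMPT window.

    Window sequences are extracted in transcript orientation; truncated
    windows keep their realised length in the denominator.
    """
    out: list[PasDensity] = []
    for pr in prompts:
        chrom = pr.window.chrom
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} missing from genome")
        seq = genome[chrom][pr.window.start : pr.window.end]
        if pr.window.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        positions = scan_pas(seq)
        length = pr.window.length
        out.append(
            PasDensity(
                prompt_id=pr.prompt_id,
                length_bp=length,
                positions=tuple(positions),
                n_sites=len(positions),
                density=len(positions) / (length / 1000.0),
            )
        )
    return out


def split_density_by_class(
    densities: Sequence[PasDensity], prompts: Sequence[PromptRegion]
) -> dict[str, dict]:
    """Partition PAS densities by the upregulation class of their PROMPT.

    Returns, per group, n, mean and median density (None when empty).
    """
    up_ids = {p.prompt_id for p in prompts if p.upregulated}
    groups: dict[str, list[float]] = {"upregulated": [], "not_upregulated": []}
    for d in densities:
        key = "upregulated" if d.prompt_id in up_ids else "not_upregulated"
        groups[key].append(d.density)
    out: dict[str, dict] = {}
    for key, vals in groups.items():
        if vals:
            out[key] = {
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
            }
        else:
            out[key] = {"n": 0, "mean": None, "median": None}
    return out


def estimate_prompt_extent(
    cov: StrandedCoverage,
    gene: GeneModel,
    max_extent: int = 12000,
    bin_size: int = 100,
    threshold_fraction: float = 0.5,
    plateau_bins: int = 5,
) -> int:
    """Estimate how far antisense PROMPT signal extends upstream of the TSS.

    Signal is averaged in fixed bins walking upstream (antisense strand); the
    plateau level is the mean of the first ``plateau_bins`` bins and the
    extent is the far edge of the furthest bin above
    ``threshold_fraction * plateau``.  Returns 0 when there is no signal.
    """
    antisense = "-" if gene.strand == "+" else "+"
    chrom_len = cov.chrom_lengths[gene.chrom]
    n_bins = max_extent // bin_size
    means = np.full(n_bins, np.nan)
    for i in range(n_bins):
        if gene.strand == "+":
            start, end = gene.tss - (i + 1) * bin_size, gene.tss - i * bin_size
        else:
            start, end = gene.tss + i * bin_size, gene.tss + (i + 1) * bin_size
        start, end = max(0, start), min(chrom_len, end)
        if start >= end:
            break
        arr = cov.strand_array(gene.chrom, antisense)
        lo = start // cov.bin_size
        hi = (end - 1) // cov.bin_size + 1
        means[i] = arr[lo:hi].mean()
    plateau = np.nanmean(means[:plateau_bins])
    if not np.isfinite(plateau) or plateau <= 0:
        return 0
    above = np.flatnonzero(means > threshold_fraction * plateau)
    if above.size == 0:
        return 0
    return int((above[-1] + 1) * bin_size)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
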