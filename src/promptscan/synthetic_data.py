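"""Synthetic genomes, annotations, stranded coverage and proteomics tables
with machine-readable planted ground truth.

The generator emulates the statistical structure of a two-condition
(control vs. factor-depleted) nuclear RNA-seq experiment in which a
termination/attenuation factor is lost:

* gene bodies at per-gene depth ``lambda_g`` on the sense strand;
* post-TES read-through tails ``lambda_g * r * exp(-x / L_decay)``, with the
  read-through fraction ``r`` raised in the depleted condition for a planted
  subset of genes;
* antisense PROMPT plateaus upstream of each TSS at rate ``q * lambda_g``,
  whose amplitude and extent both increase on depletion for a planted subset
  (stabilisation *and* extension);
* a small sense-strand "read-in" baseline upstream of every TSS, amplified in
  the depleted condition for a few genes (upstream read-through
  contamination);
* clustered bidirectional eRNA plateaus over super-enhancer intervals on a
  dedicated chromosome, amplified by a fixed fold on depletion;
* Poisson sampling noise per base (switchable off for closed-form checks);
* a TMT-style proteomics table with a planted minority of ratio-depleted
  proteins, some of which deliberately fail the peptide-support gate.

Everything is deterministic under the master seed: per-stream child
generators are derived with fixed labelled spawn keys, so outputs are
byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import StrandedCoverage, write_bedgraph, write_chrom_sizes
from .genome_intervals import (
    AnalysisParams,
    GeneModel,
    GenomicInterval,
    write_gtf,
)
from .prompt_pas import PromptRegion, define_prompt_windows, scan_pas, write_fasta

__all__ = [
    "SyntheticSpec",
    "make_annotation",
    "make_genome",
    "se_regions",
    "expected_coverage",
    "simulate_coverage",
    "simulate_counts",
    "simulate_proteomics",
    "simulate_reads",
    "tail_mean_factor",
    "write_outputs",
]

# labelled spawn keys for child random streams
_KEY_ANNOTATION = 1
_KEY_GENOME = 2
_KEY_COVERAGE = 3
_KEY_PROTEOMICS = 4
_KEY_COUNTS = 5
_KEY_READS = 6

CONDITIONS = ("control", "depleted")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generator (defaults are the tested scenario).

    Genes sit in fixed ``gene_pitch`` slots so that PROMPT extension (up to
    ``prompt_extent_depleted`` bp), post-TES decay tails and the 5 kb
    neighbour rule never collide except where pairs are planted on purpose.
    """

    seed: int = 0
    # genome layout
    n_chroms: int = 4
    chrom_length: int = 1_500_000
    gene_pitch: int = 30_000
    n_genes: int = 200
    gene_length_min: int = 2000
    gene_length_max: int = 5000
    # planted neighbourhood violations
    neighbour_pair_fraction: float = 0.10  # fraction of genes in tandem pairs
    divergent_pair_fraction: float = 0.05  # fraction of genes in divergent pairs
    # expression (expected per-base sense depth)
    depth_log_mean: float = math.log(150.0)
    depth_log_sigma: float = 0.4
    depth_floor: float = 50.0
    low_expression_fraction: float = 0.10
    low_expression_depth: float = 0.02
    # post-TES read-through
    readthrough_r_control: float = 0.05
    readthrough_r_depleted: float = 0.40
    readthrough_affected_fraction: float = 0.30
    decay_length: float = 500.0
    # PROMPT (upstream antisense) signal
    prompt_rate_fraction: float = 0.30  # q: antisense rate as fraction of lambda_g
    prompt_extent_control: int = 1500
    prompt_extent_depleted: int = 8000
    prompt_fold: float = 2.5
    prompt_affected_fraction: float = 0.50
    prompt_window: int = 3000
    # upstream read-in contamination
    upstream_rate_fraction: float = 0.05
    upstream_contamination_fold: float = 4.0
    n_upstream_contaminated: int = 5
    # differential expression planting
    n_de_genes: int = 8
    de_fold: float = 6.0
    # super-enhancers (dedicated chromosome)
    n_se: int = 111
    se_width: int = 2000
    se_pitch: int = 10_000
    se_amp_control: float = 5.0
    se_fold: float = 3.0
    # PAS planting (motif counts per PROMPT window)
    pas_count_upregulated: tuple[int, int] = (0, 4)  # low density, half-open
    pas_count_stable: tuple[int, int] = (4, 10)  # higher density
    # proteomics
    proteomics_n: int = 200
    proteomics_n_depleted: int = 4
    proteomics_null_sigma: float = 0.10
    proteomics_depleted_low: float = 0.30
    proteomics_depleted_high: float = 0.60
    proteomics_n_reps: int = 3
    peptide_fail_fraction: float = 0.25
    # read model
    read_length: int = 100
    noise: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chroms < 1:
            raise ValueError("need at least one gene and one chromosome")
        if not (0 <= self.readthrough_r_control <= 1):
            raise ValueError("read-through fraction must be in [0, 1]")
        if not (0 <= self.readthrough_r_depleted <= 1):
            raise ValueError("read-through fraction must be in [0, 1]")
        if self.prompt_extent_depleted > self.gene_pitch - self.gene_length_max:
            raise ValueError("prompt extension does not fit in the gene slot")
        slots = self.n_chroms * (self.chrom_length // self.gene_pitch)
        if self.n_genes > slots:
            raise ValueError(f"{self.n_genes} genes cannot fit in {slots} slots")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        out = {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}
        out["chrSE"] = self.n_se * self.se_pitch + 2 * self.se_pitch
        return out

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))


def tail_mean_factor(window: int, decay_length: float) -> float:
    """Mean of exp(-x/L) over integer offsets x = 0..window-1."""
    q = math.exp(-1.0 / decay_length)
    return (1.0 - q**window) / (window * (1.0 - q))


# ---------------------------------------------------------------------------
# annotation with planted spacing and effect assignments
# ---------------------------------------------------------------------------


def make_annotation(spec: SyntheticSpec) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place genes and assign planted effects; returns (genes, truth table).

    The truth table records, per gene, the geometry, the planted depth and
    effect flags, plus closed-form expected values of the read-through delta
    and PROMPT log2FC that the pipeline should recover.
    """
    rng = spec.rng(_KEY_ANNOTATION)
    slots_per_chrom = spec.chrom_length // spec.gene_pitch
    n_slots = spec.n_chroms * slots_per_chrom
    n_tandem = int(round(spec.neighbour_pair_fraction * spec.n_genes / 2))
    n_div = int(round(spec.divergent_pair_fraction * spec.n_genes / 2))
    n_single = spec.n_genes - 2 * (n_tandem + n_div)
    if n_single < 0:
        raise ValueError("pair fractions exceed the gene budget")
    slot_types = ["tandem"] * n_tandem + ["divergent"] * n_div + ["single"] * n_single
    if len(slot_types) > n_slots:
        raise ValueError("genes cannot fit: too few slots")
    slot_ids = np.sort(rng.choice(n_slots, size=len(slot_types), replace=False))
    rng.shuffle(slot_types)

    genes: list[GeneModel] = []
    rows: list[dict] = []
    gi = 0

    def add_gene(chrom, start, end, strand, pair_kind):
        nonlocal gi
        gi += 1
        gene_id = f"G{gi:04d}"
        span = GenomicInterval(chrom, start, end, strand)
        length = end - start
        e1 = GenomicInterval(chrom, start, start + int(0.4 * length), strand)
        e2 = GenomicInterval(chrom, start + int(0.6 * length), end, strand)
        g = GeneModel(gene_id=gene_id, span=span, exons=(e1, e2))
        genes.append(g)
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "tss": g.tss,
                "tes": g.tes,
                "exonic_length": g.exonic_length,
                "neighbour_violation": pair_kind != "single",
                "divergent": pair_kind == "divergent",
            }
        )

    for slot, kind in zip(slot_ids, slot_types):
        chrom = f"chr{int(slot) // slots_per_chrom + 1}"
        s = (int(slot) % slots_per_chrom) * spec.gene_pitch
        if kind == "single":
            length = int(rng.integers(spec.gene_length_min, spec.gene_length_max + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            add_gene(chrom, s + 12_000, s + 12_000 + length, strand, kind)
        elif kind == "tandem":
            add_gene(chrom, s + 12_000, s + 15_000, "+", kind)
            add_gene(chrom, s + 16_000, s + 19_000, "+", kind)
        else:  # divergent promoters: opposite-strand TSSs 1.5 kb apart
            add_gene(chrom, s + 9_000, s + 12_000, "-", kind)
            add_gene(chrom, s + 13_500, s + 16_500, "+", kind)

    truth = pd.DataFrame(rows)

    # depths
    depth = np.maximum(
        rng.lognormal(spec.depth_log_mean, spec.depth_log_sigma, len(truth)),
        spec.depth_floor,
    )
    singles = truth.index[~truth.neighbour_violation].to_numpy()
    n_low = int(round(spec.low_expression_fraction * spec.n_genes))
    low_idx = rng.choice(singles, size=min(n_low, singles.size), replace=False)
    depth[low_idx] = spec.low_expression_depth
    truth["depth"] = depth
    truth["low_expression"] = False
    truth.loc[low_idx, "low_expression"] = True

    # effect assignments among eligible (single, expressed) genes
    eligible = truth.index[
        ~truth.neighbour_violation & ~truth.low_expression
    ].to_numpy()
    order = rng.permutation(eligible)
    de_idx = order[: spec.n_de_genes]
    up_idx = order[spec.n_de_genes : spec.n_de_genes + spec.n_upstream_contaminated]
    pool = order[spec.n_de_genes + spec.n_upstream_contaminated :]
    n_rt = int(round(spec.readthrough_affected_fraction * eligible.size))
    n_pr = int(round(spec.prompt_affected_fraction * eligible.size))
    rt_idx = rng.choice(pool, size=min(n_rt, pool.size), replace=False)
    pr_idx = rng.choice(pool, size=min(n_pr, pool.size), replace=False)
    for col, idx in (
        ("de_upregulated", de_idx),
        ("upstream_contaminated", up_idx),
        ("readthrough_affected", rt_idx),
        ("prompt_affected", pr_idx),
    ):
        truth[col] = False
        truth.loc[idx, col] = True

    # per-condition planted parameters
    truth["r_control"] = spec.readthrough_r_control
    truth["r_depleted"] = np.where(
        truth.readthrough_affected,
        spec.readthrough_r_depleted,
        spec.readthrough_r_control,
    )
    truth["prompt_extent_control"] = spec.prompt_extent_control
    truth["prompt_extent_depleted"] = np.where(
        truth.prompt_affected, spec.prompt_extent_depleted, spec.prompt_extent_control
    )
    truth["prompt_amp_fold"] = np.where(truth.prompt_affected, spec.prompt_fold, 1.0)

    # which PROMPT windows survive the geometry rules
    params = AnalysisParams(prompt_window=spec.prompt_window)
    from .genome_intervals import filter_nonneighbouring

    analysed = [
        g
        for g, low in zip(genes, truth.low_expression)
        if not low
    ]
    analysed = filter_nonneighbouring(analysed, params)
    windows = define_prompt_windows(
        analysed, spec.prompt_window, spec.chrom_lengths, all_genes=genes
    )
    kept = {w.parent_gene for w in windows}
    truth["prompt_window_kept"] = truth.gene_id.isin(kept)

    # closed-form expectations of what the pipeline measures (pseudocount p)
    p = params.pseudocount
    w = spec.prompt_window
    q = spec.prompt_rate_fraction
    m_ctrl = q * truth.depth * np.minimum(truth.prompt_extent_control, w) / w
    m_dep = (
        q
        * truth.depth
        * truth.prompt_amp_fold
        * np.minimum(truth.prompt_extent_depleted, w)
        / w
    )
    truth["expected_prompt_log2fc"] = np.log2((m_dep + p) / (m_ctrl + p))
    f_post = tail_mean_factor(params.post_tes_window, spec.decay_length)
    rt_c = (truth.r_control * truth.depth * f_post + p) / (truth.depth + p)
    de_scale = np.where(truth.de_upregulated, spec.de_fold, 1.0)
    dep_depth = truth.depth * de_scale
    rt_d = (truth.r_depleted * dep_depth * f_post + p) / (dep_depth + p)
    truth["expected_rt_delta_log2"] = np.log2(rt_d / rt_c)
    return genes, truth


def se_regions(spec: SyntheticSpec) -> list[GenomicInterval]:
    """Super-enhancer intervals (unstranded) on the dedicated chromosome."""
    out = []
    for i in range(spec.n_se):
        start = spec.se_pitch + i * spec.se_pitch + (spec.se_pitch - spec.se_width) // 2
        out.append(GenomicInterval("chrSE", start, start + spec.se_width, "."))
    return out


# ---------------------------------------------------------------------------
# genome sequence with PAS planting
# ---------------------------------------------------------------------------


def _clean_pas(seq: list[str], protected: set[int]) -> None:
    """Destroy every AWTAAA match not starting at a protected offset by
    setting one base outside all protected hexamers to C (C never matches)."""
    protected_bases = set()
    for off in protected:
        protected_bases.update(range(off, off + 6))
    while True:
        hits = [h for h in scan_pas("".join(seq)) if h not in protected]
        if not hits:
            return
        for h in hits:
            for pos in range(h, h + 6):
                if pos not in protected_bases:
                    seq[pos] = "C"
                    break


def make_genome(
    spec: SyntheticSpec,
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with controlled PAS content in PROMPT windows.

    Each retained PROMPT window is scrubbed of spontaneous AWTAAA hexamers
    (in transcript orientation) and then receives a planted number of motifs
    at recorded offsets: few for windows whose PROMPT is planted to be
    upregulated, more for stable ones (the published comparison runs in this
    direction).  The manifest lists every planted site.
    """
    rng = spec.rng(_KEY_GENOME)
    chrom_lengths = spec.chrom_lengths
    arrays = {
        chrom: bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())
        for chrom, length in chrom_lengths.items()
    }
    params = AnalysisParams(prompt_window=spec.prompt_window)
    from .genome_intervals import filter_nonneighbouring

    affected = dict(zip(truth.gene_id, truth.prompt_affected))
    analysed = [
        g for g, low in zip(genes, truth.low_expression) if not low
    ]
    analysed = filter_nonneighbouring(analysed, params)
    windows = define_prompt_windows(
        analysed, spec.prompt_window, chrom_lengths, all_genes=list(genes)
    )
    rows = []
    for w in windows:
        length = w.window.length
        lo, hi = (
            spec.pas_count_upregulated
            if affected[w.parent_gene]
            else spec.pas_count_stable
        )
        n_plant = int(rng.integers(lo, hi))
        grid = np.arange(0, length - 6, 7)
        offsets = np.sort(rng.choice(grid, size=n_plant, replace=False))
        # work on the transcript-sense sequence
        raw = arrays[w.window.chrom][w.window.start : w.window.end].decode("ascii")
        if w.window.strand == "-":
            raw = raw.translate(_COMPLEMENT)[::-1]
        seq = list(raw)
        for off in offsets:
            motif = "AATAAA" if rng.random() < 0.5 else "ATTAAA"
            seq[off : off + 6] = motif
        _clean_pas(seq, set(int(o) for o in offsets))
        final = "".join(seq)
        if w.window.strand == "-":
            final = final.translate(_COMPLEMENT)[::-1]
        arrays[w.window.chrom][w.window.start : w.window.end] = final.encode("ascii")
        rows.append(
            {
                "prompt_id": w.prompt_id,
                "parent_gene": w.parent_gene,
                "chrom": w.window.chrom,
                "start": w.window.start,
                "end": w.window.end,
                "strand": w.window.strand,
                "length_bp": length,
                "n_planted": n_plant,
                "offsets": ",".join(str(int(o)) for o in offsets),
            }
        )
    genome = {c: a.decode("ascii") for c, a in arrays.items()}
    return genome, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------


def _paint(arr: np.ndarray, start: int, end: int, values) -> None:
    """Add values over [start, end) clipped to the array."""
    n = arr.size
    lo, hi = max(0, start), min(n, end)
    if lo >= hi:
        return
    if np.isscalar(values):
        arr[lo:hi] += values
    else:
        arr[lo:hi] += values[lo - start : hi - start]


def expected_coverage(
    spec: SyntheticSpec,
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    condition: str,
) -> StrandedCoverage:
    """Noiseless expected per-base coverage for one condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    depleted = condition == "depleted"
    cov = StrandedCoverage.zeros(spec.chrom_lengths, bin_size=1)
    tinfo = truth.set_index("gene_id")
    tail_len = int(6 * spec.decay_length)
    decay = np.exp(-np.arange(tail_len) / spec.decay_length)
    for g in genes:
        row = tinfo.loc[g.gene_id]
        depth = float(row.depth)
        if depleted and row.de_upregulated:
            depth *= spec.de_fold
        sense = cov.strand_array(g.chrom, g.strand)
        anti = cov.strand_array(g.chrom, "-" if g.strand == "+" else "+")
        _paint(sense, g.span.start, g.span.end, depth)
        r = float(row.r_depleted if depleted else row.r_control)
        tail = depth * r * decay
        if g.strand == "+":
            _paint(sense, g.tes, g.tes + tail_len, tail)
        else:
            _paint(sense, g.tes - tail_len, g.tes, tail[::-1])
        # PROMPT plateau, antisense upstream of the TSS
        extent = int(
            row.prompt_extent_depleted if depleted else row.prompt_extent_control
        )
        amp = spec.prompt_rate_fraction * float(row.depth)
        if depleted and row.prompt_affected:
            amp *= spec.prompt_fold
        if g.strand == "+":
            _paint(anti, g.tss - extent, g.tss, amp)
        else:
            _paint(anti, g.tss, g.tss + extent, amp)
        # sense read-in baseline upstream of the TSS (leak-in from outside the
        # gene, so it does not scale with the gene's own DE fold)
        amp_u = spec.upstream_rate_fraction * float(row.depth)
        if depleted and row.upstream_contaminated:
            amp_u *= spec.upstream_contamination_fold
        w_u = 1000
        if g.strand == "+":
            _paint(sense, g.tss - w_u, g.tss, amp_u)
        else:
            _paint(sense, g.tss, g.tss + w_u, amp_u)
    amp_se = spec.se_amp_control * (spec.se_fold if depleted else 1.0)
    for region in se_regions(spec):
        _paint(cov.strand_array("chrSE", "+"), region.start, region.end, amp_se)
        _paint(cov.strand_array("chrSE", "-"), region.start, region.end, amp_se)
    cov.library_size = max(1, int(round(cov.total_signal() / spec.read_length)))
    return cov


def simulate_coverage(
    spec: SyntheticSpec,
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    condition: str,
    replicate: int = 1,
    noise: bool | None = None,
) -> StrandedCoverage:
    """Observed coverage: Poisson(expected) per base, seeded per
    (condition, replicate); noiseless when ``noise`` is off."""
    cov = expected_coverage(spec, genes, truth, condition)
    noise = spec.noise if noise is None else noise
    if not noise:
        return cov
    rng = spec.rng(_KEY_COVERAGE, CONDITIONS.index(condition), replicate)
    for strand_dict in (cov.plus, cov.minus):
        for chrom in strand_dict:
            strand_dict[chrom] = rng.poisson(strand_dict[chrom]).astype(float)
    cov.library_size = max(1, int(round(cov.total_signal() / spec.read_length)))
    return cov


def simulate_counts(
    spec: SyntheticSpec,
    truth: pd.DataFrame,
    condition: str,
    n_reps: int = 3,
) -> pd.DataFrame:
    """Exonic count matrix (genes x replicates), Poisson around the planted
    expectation ``depth * exonic_length / read_length`` (x fold for planted
    DE genes in the depleted condition)."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = spec.rng(_KEY_COUNTS, CONDITIONS.index(condition))
    lam = truth.depth.to_numpy() * truth.exonic_length.to_numpy() / spec.read_length
    if condition == "depleted":
        lam = lam * np.where(truth.de_upregulated, spec.de_fold, 1.0)
    counts = rng.poisson(lam[:, None], size=(lam.size, n_reps))
    return pd.DataFrame(
        counts,
        index=pd.Index(truth.gene_id, name="gene_id"),
        columns=[f"{condition}_rep{i + 1}" for i in range(n_reps)],
    )


def simulate_proteomics(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TMT quant table plus truth list.

    Null proteins: ratios ~ Normal(1, sigma) truncated at 0, ample peptides.
    Depleted proteins: ratios ~ Uniform(low, high); a configurable fraction
    draw < 5 peptides so the peptide gate is exercised.
    """
    if spec.proteomics_n_depleted > spec.proteomics_n:
        raise ValueError("more depleted proteins than proteins")
    rng = spec.rng(_KEY_PROTEOMICS)
    n, k = spec.proteomics_n, spec.proteomics_n_depleted
    ids = [f"P{i + 1:04d}" for i in range(n)]
    depleted_idx = np.sort(rng.choice(n, size=k, replace=False))
    is_dep = np.zeros(n, dtype=bool)
    is_dep[depleted_idx] = True
    reps = spec.proteomics_n_reps
    ratios = np.maximum(
        rng.normal(1.0, spec.proteomics_null_sigma, size=(n, reps)), 0.0
    )
    ratios[is_dep] = rng.uniform(
        spec.proteomics_depleted_low, spec.proteomics_depleted_high, size=(k, reps)
    )
    peptides = rng.integers(6, 30, size=n)
    n_fail = int(round(spec.peptide_fail_fraction * k))
    fail_idx = depleted_idx[:n_fail]
    peptides[fail_idx] = rng.integers(1, 5, size=n_fail)
    table = pd.DataFrame({"protein_id": ids, "peptide_count": peptides})
    for j in range(reps):
        table[f"ratio_rep{j + 1}"] = ratios[:, j]
    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "depleted": is_dep,
            "passes_peptide_gate": peptides >= 5,
            "expected_candidate": is_dep & (peptides >= 5),
        }
    )
    return table, truth


def simulate_reads(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    spec: SyntheticSpec,
    reads_per_gene: int = 20,
) -> list[GenomicInterval]:
    """Small read-interval emitter (fixed-length reads within exons, on the
    gene's strand) for exercising pileup and exonic counting."""
    rng = spec.rng(_KEY_READS)
    reads: list[GenomicInterval] = []
    for g in genes:
        for _ in range(reads_per_gene):
            ex = g.exons[int(rng.integers(0, len(g.exons)))]
            max_start = max(ex.start, ex.end - spec.read_length)
            start = int(rng.integers(ex.start, max_start + 1))
            end = min(start + spec.read_length, ex.end)
            reads.append(GenomicInterval(g.chrom, start, end, g.strand))
    return reads


# ---------------------------------------------------------------------------
# full emission
# ---------------------------------------------------------------------------


def write_outputs(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit the complete synthetic dataset and truth tables to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    genes, truth = make_annotation(spec)
    genome, manifest = make_genome(spec, genes, truth)

    paths["spec"] = outdir / "spec.json"
    paths["spec"].write_text(json.dumps(asdict(spec), indent=2, sort_keys=True) + "\n")
    paths["genome"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gtf"
    write_gtf(genes, paths["annotation"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    write_chrom_sizes(spec.chrom_lengths, paths["chrom_sizes"])
    paths["se_bed"] = outdir / "super_enhancers.bed"
    from .genome_intervals import write_bed

    write_bed(se_regions(spec), paths["se_bed"])

    for condition in CONDITIONS:
        cov = simulate_coverage(spec, genes, truth, condition)
        plus, minus = write_bedgraph(cov, outdir / f"{condition}.rep1")
        paths[f"{condition}_plus"] = plus
        paths[f"{condition}_minus"] = minus
        counts = simulate_counts(spec, truth, condition)
        p = outdir / f"counts.{condition}.tsv"
        counts.to_csv(p, sep="\t")
        paths[f"counts_{condition}"] = p

    quant, prot_truth = simulate_proteomics(spec)
    paths["proteomics"] = outdir / "proteomics.tsv"
    quant.to_csv(paths["proteomics"], sep="\t", index=False)

    paths["truth_genes"] = truth_dir / "genes.tsv"
    truth.to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["truth_pas"] = truth_dir / "pas_manifest.tsv"
    manifest.to_csv(paths["truth_pas"], sep="\t", index=False)
    paths["truth_proteomics"] = truth_dir / "proteomics.tsv"
    prot_truth.to_csv(paths["truth_proteomics"], sep="\t", index=False)
    return paths
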