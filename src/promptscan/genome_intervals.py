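"""Genomic interval algebra, annotation parsing, and gene-set filtering rules.

All coordinates are 0-based half-open (BED convention) internally; GTF's
1-based closed coordinates are converted at the parsing boundary.  Strand is
``"+"``, ``"-"`` or ``"."`` (unstranded).  Peak-set operations (intersection of
replicate peaks, subtraction of input peaks) ignore strand; gene-level filters
use strand only to locate the TSS and TES.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AnalysisParams",
    "BedParseError",
    "AnnotationError",
    "read_bed",
    "write_bed",
    "read_annotation",
    "write_gtf",
    "write_bed12",
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "filter_nonneighbouring",
]

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for malformed BED records; message names the offending line."""


class AnnotationError(ValueError):
    """Raised for inconsistent gene annotations (e.g. exon outside gene span)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)`` with a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Base-level overlap, strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def opposite_strand(self) -> str:
        if self.strand == ".":
            return "."
        return "-" if self.strand == "+" else "+"


@dataclass(frozen=True)
class GeneModel:
    """One transcript model per gene: stranded span plus ordered exons.

    The TSS is ``span.start`` on ``+`` and ``span.end`` on ``-``; the TES is
    the opposite end (the annotated polyadenylation end).
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: span must be stranded")
        exons = tuple(self.exons) or (self.span,)
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for ex in exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {ex} not on the gene's chrom/strand"
                )
            if ex.start < self.span.start or ex.end > self.span.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{ex.start},{ex.end}) outside "
                    f"span [{self.span.start},{self.span.end})"
                )
            if ex.start < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons unsorted or overlapping"
                )
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def tes(self) -> int:
        return self.span.end if self.strand == "+" else self.span.start

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)


@dataclass(frozen=True)
class AnalysisParams:
    """Every tunable threshold of the pipeline, with the published defaults.

    post_tes_window      bp downstream of the TES scored for read-through (1 kb)
    pre_tes_window       bp directly preceding the TES (PAS-proximal, 500 bp)
    neighbour_distance   half-width of the promoter neighbourhood (5 kb)
    tpm_min              expression cut-off; genes with TPM < 5 are dropped
    upstream_filter_window   bp preceding the TSS checked for read-in signal (1 kb)
    prompt_window        length of the upstream antisense (PROMPT) window
    log2fc_up_threshold  log2 fold-change class boundary (>= 1 is "upregulated")
    fold_up_threshold    linear fold gate for differential expression (>= 2)
    fdr_threshold        BH-adjusted p-value gate (<= 0.05)
    ratio_threshold      TMT abundance-ratio gate, strict (< 0.70)
    min_peptides         peptide-support gate, strict (< 5 discarded)
    pseudocount          added symmetrically to every log2 ratio, coverage units
    """

    post_tes_window: int = 1000
    pre_tes_window: int = 500
    neighbour_distance: int = 5000
    tpm_min: float = 5.0
    upstream_filter_window: int = 1000
    prompt_window: int = 3000
    log2fc_up_threshold: float = 1.0
    fold_up_threshold: float = 2.0
    fdr_threshold: float = 0.05
    ratio_threshold: float = 0.70
    min_peptides: int = 5
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "post_tes_window",
            "pre_tes_window",
            "neighbour_distance",
            "upstream_filter_window",
            "prompt_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "tpm_min",
            "log2fc_up_threshold",
            "fold_up_threshold",
            "fdr_threshold",
            "ratio_threshold",
            "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisParams":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)

    def evolve(self, **kwargs) -> "AnalysisParams":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# BED / GTF input and output
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving file order.

    BED is already 0-based half-open so coordinates are taken verbatim.
    A missing or ``.`` strand column yields an unstranded interval.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = parts[5] if len(parts) >= 6 else "."
            if strand not in STRANDS:
                raise BedParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                out.append(GenomicInterval(parts[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf(path: str | Path) -> list[GeneModel]:
    spans: dict[str, GenomicInterval] = {}
    biotypes: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise AnnotationError(f"{path}:{lineno}: fewer than 9 GTF fields")
            chrom, _, feature, start1, end1, _, strand = parts[:7]
            if feature not in ("gene", "exon"):
                continue
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_gtf_attributes(parts[8])
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
            # GTF is 1-based closed; convert to 0-based half-open.
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            if feature == "gene":
                spans[gene_id] = iv
                biotypes[gene_id] = attrs.get("gene_biotype", "protein_coding")
                order.append(gene_id)
            else:
                exons.setdefault(gene_id, []).append(iv)
    for gid in exons:
        if gid not in spans:
            # exon-only gene: span is the exon hull
            exs = exons[gid]
            spans[gid] = GenomicInterval(
                exs[0].chrom,
                min(e.start for e in exs),
                max(e.end for e in exs),
                exs[0].strand,
            )
            biotypes[gid] = "protein_coding"
            order.append(gid)
    return [
        GeneModel(
            gene_id=gid,
            span=spans[gid],
            exons=tuple(sorted(exons.get(gid, []), key=lambda e: e.start)),
            biotype=biotypes[gid],
        )
        for gid in order
    ]


def _read_bed12(path: str | Path) -> list[GeneModel]:
    out: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise BedParseError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{lineno}: unknown strand {strand!r}")
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise BedParseError(f"{path}:{lineno}: blockCount mismatch")
            span = GenomicInterval(chrom, start, end, strand)
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            )
            out.append(GeneModel(gene_id=name, span=span, exons=exons))
    return out


def read_annotation(
    path: str | Path, dialect: Literal["gtf", "bed12"] = "gtf"
) -> list[GeneModel]:
    """Read a gene annotation (one model per gene_id) from GTF or BED12."""
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene + exon records in GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tpromptscan\tgene\t{g.span.start + 1}\t{g.span.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\tpromptscan\texon\t{ex.start + 1}\t{ex.end}"
                    f"\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(ex.length) for ex in g.exons) + ","
            offs = ",".join(str(ex.start - g.span.start) for ex in g.exons) + ","
            fh.write(
                f"{g.chrom}\t{g.span.start}\t{g.span.end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{g.span.start}\t{g.span.end}\t0\t"
                f"{len(g.exons)}\t{sizes}\t{offs}\n"
            )


# ---------------------------------------------------------------------------
# Interval set algebra (strand-blind, used for peak sets)
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, non-overlapping, strand dropped."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level intersection of the unions of two interval sets.

    This is the replicate-consensus operation for peak sets ("common peaks");
    strand is ignored and the result is merged and sorted.
    """
    ma, mb = merge_intervals(a), merge_intervals(b)
    out: list[GenomicInterval] = []
    chroms = sorted({iv.chrom for iv in ma} & {iv.chrom for iv in mb})
    for chrom in chroms:
        xs = [iv for iv in ma if iv.chrom == chrom]
        ys = [iv for iv in mb if iv.chrom == chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of the union of ``a`` not covered by the union of ``b``.

    The input-subtraction operation for peak sets; merged, sorted, strand-blind.
    """
    ma, mb = merge_intervals(a), merge_intervals(b)
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in mb:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in ma:
        cuts = by_chrom_b.get(iv.chrom, [])
        pos = iv.start
        for cut in cuts:
            if cut.end <= pos or cut.start >= iv.end:
                continue
            if cut.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, cut.start))
            pos = max(pos, cut.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return out


# ---------------------------------------------------------------------------
# Gene-set filtering
# ---------------------------------------------------------------------------


def filter_nonneighbouring(
    genes: Sequence[GeneModel], params: AnalysisParams | None = None
) -> list[GeneModel]:
    """Drop genes with any neighbour near their promoter.

    A gene is retained iff no *other* gene's span overlaps the symmetric
    window ``[TSS - d, TSS + d)`` with ``d = neighbour_distance`` (5 kb
    default).  This also removes divergent-promoter pairs, whose
    opposite-strand TSSs sit within ``d`` of each other.
    """
    params = params or AnalysisParams()
    d = params.neighbour_distance
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept: list[GeneModel] = []
    for g in genes:
        lo, hi = max(0, g.tss - d), g.tss + d
        crowded = any(
            other is not g and other.span.start < hi and lo < other.span.end
            for other in by_chrom[g.chrom]
        )
        if not crowded:
            kept.append(g)
    return kept
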