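"""Stranded base/bin-resolution coverage tracks with normalisation and queries.

A :class:`StrandedCoverage` holds one numeric vector per chromosome and strand
at a fixed bin size (1 bp by default, matching browser-track practice).  A
read overlapping a bin by at least 1 bp increments that bin.  Tracks carry a
normalisation tag (``raw``, ``RPKM`` or ``CPM``) and the library size used to
normalise.  bedGraph (two files, one per strand) is the native interchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .genome_intervals import GenomicInterval

__all__ = [
    "StrandedCoverage",
    "CoverageError",
    "coverage_from_reads",
    "normalise_rpkm",
    "normalise_cpm",
    "region_mean",
    "base_values",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

StrandMode = Literal["sense", "antisense", "both"]


class CoverageError(ValueError):
    pass


@dataclass
class StrandedCoverage:
    chrom_lengths: dict[str, int]
    bin_size: int = 1
    plus: dict[str, np.ndarray] = field(default_factory=dict)
    minus: dict[str, np.ndarray] = field(default_factory=dict)
    normalisation: str = "raw"
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise CoverageError("bin_size must be >= 1")
        for chrom, length in self.chrom_lengths.items():
            n = self.n_bins(chrom)
            for strand_dict in (self.plus, self.minus):
                if chrom not in strand_dict:
                    strand_dict[chrom] = np.zeros(n, dtype=float)
                elif len(strand_dict[chrom]) != n:
                    raise CoverageError(
                        f"{chrom}: vector length {len(strand_dict[chrom])} != "
                        f"ceil({length}/{self.bin_size}) = {n}"
                    )

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.bin_size)

    @classmethod
    def zeros(
        cls, chrom_lengths: Mapping[str, int], bin_size: int = 1
    ) -> "StrandedCoverage":
        return cls(chrom_lengths=dict(chrom_lengths), bin_size=bin_size)

    def strand_array(self, chrom: str, strand: str) -> np.ndarray:
        if chrom not in self.chrom_lengths:
            raise CoverageError(f"unknown chromosome {chrom!r}")
        if strand == "+":
            return self.plus[chrom]
        if strand == "-":
            return self.minus[chrom]
        raise CoverageError(f"bad strand key {strand!r}")

    def total_signal(self) -> float:
        return float(
            sum(a.sum() for a in self.plus.values())
            + sum(a.sum() for a in self.minus.values())
        )

    def copy_like(self, scale: float, normalisation: str) -> "StrandedCoverage":
        return StrandedCoverage(
            chrom_lengths=dict(self.chrom_lengths),
            bin_size=self.bin_size,
            plus={c: a * scale for c, a in self.plus.items()},
            minus={c: a * scale for c, a in self.minus.items()},
            normalisation=normalisation,
            library_size=self.library_size,
        )


def coverage_from_reads(
    reads: Iterable[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 1,
) -> StrandedCoverage:
    """Raw pileup: each read adds 1 to every bin it overlaps, on its strand."""
    cov = StrandedCoverage.zeros(chrom_lengths, bin_size)
    n = 0
    for read in reads:
        if read.chrom not in chrom_lengths:
            raise CoverageError(f"read on unknown chromosome {read.chrom!r}")
        if read.end > chrom_lengths[read.chrom]:
            raise CoverageError(
                f"read {read.chrom}:[{read.start},{read.end}) beyond chromosome end"
            )
        if read.strand not in ("+", "-"):
            raise CoverageError("reads must be stranded")
        arr = cov.strand_array(read.chrom, read.strand)
        lo = read.start // bin_size
        hi = (read.end - 1) // bin_size + 1
        arr[lo:hi] += 1.0
        n += 1
    cov.library_size = n
    return cov


def normalise_rpkm(cov: StrandedCoverage) -> StrandedCoverage:
    """Scale each bin by 1e9 / (library_size * bin_size); tag as RPKM."""
    if cov.normalisation != "raw":
        raise CoverageError(f"track already normalised ({cov.normalisation})")
    if not cov.library_size:
        raise CoverageError("library_size must be > 0 for RPKM")
    return cov.copy_like(1e9 / (cov.library_size * cov.bin_size), "RPKM")


def normalise_cpm(cov: StrandedCoverage) -> StrandedCoverage:
    if cov.normalisation != "raw":
        raise CoverageError(f"track already normalised ({cov.normalisation})")
    if not cov.library_size:
        raise CoverageError("library_size must be > 0 for CPM")
    return cov.copy_like(1e6 / cov.library_size, "CPM")


def _resolve_strands(region_strand: str, mode: StrandMode) -> tuple[str, ...]:
    if mode == "both" or region_strand == ".":
        return ("+", "-")
    if mode == "sense":
        return (region_strand,)
    if mode == "antisense":
        return ("-",) if region_strand == "+" else ("+",)
    raise CoverageError(f"bad strand_mode {mode!r}")


def region_mean(
    cov: StrandedCoverage,
    region: GenomicInterval,
    strand_mode: StrandMode = "sense",
) -> float:
    """Mean bin value over the region clipped to the chromosome.

    ``sense`` reads the region's own strand, ``antisense`` the opposite,
    ``both`` the sum of strands.  Unstranded regions always read both.
    """
    if region.chrom not in cov.chrom_lengths:
        raise CoverageError(f"unknown chromosome {region.chrom!r}")
    start = max(0, region.start)
    end = min(cov.chrom_lengths[region.chrom], region.end)
    if start >= end:
        raise CoverageError(
            f"region {region.chrom}:[{region.start},{region.end}) entirely "
            "off-chromosome"
        )
    lo = start // cov.bin_size
    hi = (end - 1) // cov.bin_size + 1
    strands = _resolve_strands(region.strand, strand_mode)
    total = np.zeros(hi - lo)
    for s in strands:
        total += cov.strand_array(region.chrom, s)[lo:hi]
    return float(total.mean())


def base_values(
    cov: StrandedCoverage,
    chrom: str,
    start: int,
    end: int,
    strands: Sequence[str],
) -> np.ndarray:
    """Per-base values over [start, end); positions off-chromosome are NaN.

    Bin values are expanded to base resolution (each base takes its bin's
    value), which makes downstream window math independent of bin_size for
    piecewise-constant tracks.
    """
    if chrom not in cov.chrom_lengths:
        raise CoverageError(f"unknown chromosome {chrom!r}")
    length = cov.chrom_lengths[chrom]
    out = np.full(end - start, np.nan)
    s_clip, e_clip = max(0, start), min(length, end)
    if s_clip >= e_clip:
        return out
    b = cov.bin_size
    idx = np.arange(s_clip, e_clip) // b
    vals = np.zeros(e_clip - s_clip)
    for s in strands:
        vals += cov.strand_array(chrom, s)[idx]
    out[s_clip - start : e_clip - start] = vals
    return out


# ---------------------------------------------------------------------------
# bedGraph and chrom.sizes interchange
# ---------------------------------------------------------------------------


def _read_one_bedgraph(
    path: str | Path, cov_arr: Mapping[str, np.ndarray], chrom_lengths, bin_size
) -> None:
    covered: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise CoverageError(f"{path}:{lineno}: need 4 bedGraph fields")
            chrom, start, end, value = (
                parts[0],
                int(parts[1]),
                int(parts[2]),
                float(parts[3]),
            )
            if chrom not in chrom_lengths:
                raise CoverageError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > chrom_lengths[chrom]:
                raise CoverageError(
                    f"{path}:{lineno}: record beyond chromosome length"
                )
            if start < covered.get(chrom, 0):
                raise CoverageError(
                    f"{path}:{lineno}: overlapping or unsorted bedGraph records"
                )
            covered[chrom] = end
            if start % bin_size or (end % bin_size and end != chrom_lengths[chrom]):
                raise CoverageError(
                    f"{path}:{lineno}: record not aligned to bin_size {bin_size}"
                )
            lo = start // bin_size
            hi = (end - 1) // bin_size + 1
            cov_arr[chrom][lo:hi] = value


def read_bedgraph(
    path_plus: str | Path,
    path_minus: str | Path,
    chrom_lengths: Mapping[str, int],
    bin_size: int = 1,
    normalisation: str = "raw",
    library_size: int | None = None,
) -> StrandedCoverage:
    """Read a strand pair of bedGraph files; unlisted regions are zero."""
    cov = StrandedCoverage.zeros(chrom_lengths, bin_size)
    _read_one_bedgraph(path_plus, cov.plus, chrom_lengths, bin_size)
    _read_one_bedgraph(path_minus, cov.minus, chrom_lengths, bin_size)
    cov.normalisation = normalisation
    cov.library_size = library_size
    return cov


def _write_one_bedgraph(arr_by_chrom, chrom_lengths, bin_size, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(arr_by_chrom):
            arr = arr_by_chrom[chrom]
            if arr.size == 0:
                continue
            # run-length encode; zero runs are omitted
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                g_start = int(s) * bin_size
                g_end = min(int(e) * bin_size, chrom_lengths[chrom])
                fh.write(f"{chrom}\t{g_start}\t{g_end}\t{v:.10g}\n")


def write_bedgraph(cov: StrandedCoverage, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.plus.bedgraph`` and ``<prefix>.minus.bedgraph``."""
    prefix = Path(prefix)
    p_plus = prefix.with_name(prefix.name + ".plus.bedgraph")
    p_minus = prefix.with_name(prefix.name + ".minus.bedgraph")
    _write_one_bedgraph(cov.plus, cov.chrom_lengths, cov.bin_size, p_plus)
    _write_one_bedgraph(cov.minus, cov.chrom_lengths, cov.bin_size, p_minus)
    return p_plus, p_minus


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            out[chrom] = int(size)
    return out


def write_chrom_sizes(chrom_lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_lengths):
            fh.write(f"{chrom}\t{chrom_lengths[chrom]}\n")
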