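"""Interval algebra, annotation parsing, and the promoter-neighbour filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promptscan.genome_intervals import (
    AnalysisParams,
    AnnotationError,
    BedParseError,
    GeneModel,
    GenomicInterval,
    filter_nonneighbouring,
    intersect_intervals,
    merge_intervals,
    read_annotation,
    read_bed,
    subtract_intervals,
    write_bed12,
    write_gtf,
)

# ---------------------------------------------------------------------------
# per-base oracle helpers
# ---------------------------------------------------------------------------


def bitmap(intervals, length=10_000):
    m = np.zeros(length, dtype=bool)
    for iv in intervals:
        m[iv.start : iv.end] = True
    return m


def segments_from_bitmap(m, chrom="chr1"):
    padded = np.concatenate(([False], m, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]


def random_set(rng, n=50, length=10_000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, length - 1))
        e = int(rng.integers(s + 1, min(length, s + 400) + 1))
        out.append(GenomicInterval("chr1", s, e))
    return out


# ---------------------------------------------------------------------------
# GenomicInterval / GeneModel invariants
# ---------------------------------------------------------------------------


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 5, 10, "x")
    iv = GenomicInterval("chr1", 100, 200, "+")
    assert len(iv) == 100 and iv.opposite_strand() == "-"


def test_gene_model_tss_tes_by_strand():
    span_p = GenomicInterval("chr1", 1000, 2000, "+")
    span_m = GenomicInterval("chr1", 1000, 2000, "-")
    gp = GeneModel("gp", span_p)
    gm = GeneModel("gm", span_m)
    assert (gp.tss, gp.tes) == (1000, 2000)
    assert (gm.tss, gm.tes) == (2000, 1000)
    assert gp.exons == (span_p,)  # default exon = span


def test_gene_model_rejects_bad_exons():
    span = GenomicInterval("chr1", 100, 1000, "+")
    with pytest.raises(AnnotationError):
        GeneModel("g", span, exons=(GenomicInterval("chr1", 500, 1200, "+"),))
    with pytest.raises(AnnotationError):
        GeneModel(
            "g",
            span,
            exons=(
                GenomicInterval("chr1", 100, 400, "+"),
                GenomicInterval("chr1", 300, 600, "+"),
            ),
        )


# ---------------------------------------------------------------------------
# BED / GTF parsing
# ---------------------------------------------------------------------------


def test_read_bed(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\t.\t0\t+\nchr2\t0\t50\nchr1\t5\t6\t.\t0\t-\n")
    ivs = read_bed(p)
    assert ivs[0] == GenomicInterval("chr1", 100, 200, "+")
    assert ivs[1].strand == "."  # BED3: missing strand is unstranded
    assert len(ivs) == 3  # file order preserved


@pytest.mark.parametrize(
    "line",
    ["chr1\t100\t100", "chr1\tx\t200", "chr1\t300\t200"],
)
def test_read_bed_malformed_names_line(tmp_path, line):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t1\t2\n" + line + "\n")
    with pytest.raises(BedParseError, match=":2"):
        read_bed(p)


def test_gtf_coordinate_conversion(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(
        'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "g1";\n'
        'chr1\tsrc\texon\t1001\t1400\t.\t+\t.\tgene_id "g1";\n'
        'chr1\tsrc\texon\t1601\t2000\t.\t+\t.\tgene_id "g1";\n'
        'chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tgene_id "g2";\n'
    )
    genes = read_annotation(p, "gtf")
    g1, g2 = genes
    assert (g1.span.start, g1.span.end) == (1000, 2000)
    assert [(e.start, e.end) for e in g1.exons] == [(1000, 1400), (1600, 2000)]
    assert g2.exons == (g2.span,)  # no exon records -> span exon


def test_gtf_exon_outside_span_errors(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text(
        'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "g1";\n'
        'chr1\tsrc\texon\t1001\t2400\t.\t+\t.\tgene_id "g1";\n'
    )
    with pytest.raises(AnnotationError):
        read_annotation(p, "gtf")


def test_bed12_blocks(tmp_path):
    p = tmp_path / "a.bed12"
    p.write_text(
        "chr1\t100\t1000\tg1\t0\t+\t100\t1000\t0\t2\t200,300,\t0,600,\n"
    )
    (g,) = read_annotation(p, "bed12")
    assert [e.length for e in g.exons] == [200, 300]
    assert g.exons[1].start == 700


def test_gtf_bed12_round_trip(tmp_path, rng):
    genes = []
    for i in range(20):
        start = int(rng.integers(0, 50_000))
        length = int(rng.integers(500, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        span = GenomicInterval("chr1", start, start + length, strand)
        e1 = GenomicInterval("chr1", start, start + length // 3, strand)
        e2 = GenomicInterval("chr1", start + length // 2, start + length, strand)
        genes.append(GeneModel(f"g{i}", span, exons=(e1, e2)))
    gtf, bed = tmp_path / "x.gtf", tmp_path / "x.bed12"
    write_gtf(genes, gtf)
    write_bed12(genes, bed)
    for back in (read_annotation(gtf, "gtf"), read_annotation(bed, "bed12")):
        assert [(g.span.start, g.span.end) for g in back] == [
            (g.span.start, g.span.end) for g in genes
        ]
        assert [g.exonic_length for g in back] == [g.exonic_length for g in genes]


# ---------------------------------------------------------------------------
# set algebra vs. the per-base oracle
# ---------------------------------------------------------------------------


def test_intersect_subtract_simple_cases():
    a = [GenomicInterval("chr1", 0, 10)]
    b = [GenomicInterval("chr1", 5, 15)]
    assert intersect_intervals(a, b) == [GenomicInterval("chr1", 5, 10)]
    assert subtract_intervals(a, b) == [GenomicInterval("chr1", 0, 5)]
    assert intersect_intervals(a, [GenomicInterval("chr2", 0, 5)]) == []
    assert subtract_intervals(a, a) == []


def test_set_algebra_matches_per_base_oracle(rng):
    for _ in range(50):
        a = random_set(rng)
        b = random_set(rng)
        assert intersect_intervals(a, b) == segments_from_bitmap(
            bitmap(a) & bitmap(b)
        )
        assert subtract_intervals(a, b) == segments_from_bitmap(
            bitmap(a) & ~bitmap(b)
        )


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 80)),
        min_size=1,
        max_size=15,
    )
)
def test_merge_is_idempotent_and_bounds_preserving(pairs):
    ivs = [GenomicInterval("chr1", s, s + l) for s, l in pairs]
    merged = merge_intervals(ivs)
    assert merge_intervals(merged) == merged
    assert intersect_intervals(ivs, ivs) == merged  # self-intersection = union
    assert subtract_intervals(ivs, []) == merged
    # sorted, non-overlapping, within input bounds
    for x, y in zip(merged, merged[1:]):
        assert x.end < y.start
    assert merged[0].start == min(iv.start for iv in ivs)
    assert merged[-1].end == max(iv.end for iv in ivs)


# ---------------------------------------------------------------------------
# neighbour filter
# ---------------------------------------------------------------------------


def make_gene(gene_id, start, end, strand="+"):
    return GeneModel(gene_id, GenomicInterval("chr1", start, end, strand))


def test_single_gene_retained():
    assert len(filter_nonneighbouring([make_gene("a", 10_000, 15_000)])) == 1


def test_span_within_5kb_of_promoter_excludes():
    a = make_gene("a", 10_000, 15_000)  # TSS 10,000; window [5,000, 15,000)
    b = make_gene("b", 3_000, 8_000)  # span end 8,000 > 5,000 -> neighbour
    kept = filter_nonneighbouring([a, b])
    assert all(g.gene_id != "a" for g in kept)


def test_divergent_pair_both_excluded():
    a = make_gene("a", 5_000, 9_000, "-")  # TSS 9,000
    b = make_gene("b", 10_000, 14_000, "+")  # TSS 10,000
    assert filter_nonneighbouring([a, b]) == []


def test_neighbour_filter_matches_all_pairs_oracle(rng):
    d = AnalysisParams().neighbour_distance
    genes = []
    for i in range(30):
        start = int(rng.integers(0, 200_000))
        length = int(rng.integers(1000, 6000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i}", start, start + length, strand))
    kept = {g.gene_id for g in filter_nonneighbouring(genes)}
    expected = set()
    for g in genes:
        lo, hi = max(0, g.tss - d), g.tss + d
        if not any(
            o is not g and o.span.start < hi and lo < o.span.end for o in genes
        ):
            expected.add(g.gene_id)
    assert kept == expected


def test_neighbour_filter_order_independent(rng):
    genes = []
    for i in range(20):
        s = int(rng.integers(0, 100_000))
        genes.append(make_gene(f"g{i}", s, s + 2000))
    ids = {g.gene_id for g in filter_nonneighbouring(genes)}
    shuffled = list(genes)
    rng.shuffle(shuffled)
    assert {g.gene_id for g in filter_nonneighbouring(shuffled)} == ids
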