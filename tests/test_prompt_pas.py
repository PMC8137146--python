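"""PROMPT window geometry, fold-change classes, PAS scanning and density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promptscan.coverage import StrandedCoverage
from promptscan.genome_intervals import AnalysisParams, GeneModel, GenomicInterval
from promptscan.prompt_pas import (
    PasDensity,
    PromptRegion,
    define_prompt_windows,
    estimate_prompt_extent,
    pas_density,
    prompt_fc,
    scan_pas,
    split_density_by_class,
)

LENGTHS = {"chr1": 40_000}


def gene(gene_id="g", start=10_000, end=13_000, strand="+"):
    return GeneModel(gene_id, GenomicInterval("chr1", start, end, strand))


def pas_oracle(seq: str) -> list[int]:
    seq = seq.upper()
    return [
        i
        for i in range(len(seq) - 5)
        if seq[i : i + 6] in ("AATAAA", "ATTAAA")
    ]


class TestWindows:
    def test_plus_gene_geometry(self):
        (w,) = define_prompt_windows([gene()], 3000)
        assert (w.window.start, w.window.end, w.window.strand) == (7000, 10_000, "-")
        assert w.parent_gene == "g"

    def test_minus_gene_mirror(self):
        (w,) = define_prompt_windows([gene(strand="-")], 3000)
        # minus gene TSS = span end = 13,000
        assert (w.window.start, w.window.end, w.window.strand) == (13_000, 16_000, "+")

    def test_clipped_at_chromosome_start(self):
        (w,) = define_prompt_windows([gene(start=1000, end=4000)], 3000)
        assert w.window.start == 0 and w.window.length == 1000

    def test_window_overlapping_other_gene_dropped(self):
        other = gene("other", 6000, 9000, "+")
        ws = define_prompt_windows([gene()], 3000, all_genes=[gene(), other])
        assert ws == []

    def test_windows_never_touch_parent_body(self, rng):
        genes = []
        for i in range(50):
            s = int(rng.integers(5000, 30_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(gene(f"g{i}", s, s + 2000, strand))
        for w in define_prompt_windows(genes, 3000, LENGTHS):
            parent = next(g for g in genes if g.gene_id == w.parent_gene)
            assert not parent.span.overlaps(w.window)
            assert w.window.strand != parent.strand


class TestPromptFc:
    def make_cov(self, amp):
        cov = StrandedCoverage.zeros(LENGTHS)
        cov.minus["chr1"][7000:10_000] = amp
        return cov

    def test_identical_tracks_zero(self):
        ws = define_prompt_windows([gene()], 3000)
        cov = self.make_cov(5.0)
        prompt_fc(ws, cov, cov)
        assert ws[0].log2fc == 0.0 and not ws[0].upregulated

    def test_threshold_is_inclusive(self):
        # ctrl 0, cond equal to the pseudocount: (p + p) / (0 + p) = 2 exactly,
        # so log2fc is exactly 1.0 and must be classed upregulated (">= 1")
        ws = define_prompt_windows([gene()], 3000)
        ctrl = StrandedCoverage.zeros(LENGTHS)
        cond = self.make_cov(AnalysisParams().pseudocount)
        prompt_fc(ws, ctrl, cond)
        assert ws[0].log2fc == 1.0 and ws[0].upregulated

    def test_planted_fold_recovered(self, small_data):
        spec, genes, truth, cov_c, cov_d = small_data
        info = truth.set_index("gene_id")
        analysed = [
            g
            for g in genes
            if not info.loc[g.gene_id].low_expression
            and not info.loc[g.gene_id].neighbour_violation
        ]
        ws = define_prompt_windows(
            analysed, spec.prompt_window, spec.chrom_lengths, all_genes=genes
        )
        prompt_fc(ws, cov_c, cov_d)
        errs = [
            abs(w.log2fc - info.loc[w.parent_gene].expected_prompt_log2fc)
            for w in ws
        ]
        assert np.mean(np.array(errs) <= 0.2) >= 0.95
        classes = [w.upregulated == info.loc[w.parent_gene].prompt_affected
                   for w in ws]
        assert all(classes)


class TestScanPas:
    def test_basic_motifs(self):
        assert scan_pas("AATAAA") == [0]
        assert scan_pas("ATTAAA") == [0]
        assert scan_pas("aataaa") == [0]  # case-insensitive
        assert scan_pas("AATAAATTAAA") == [0, 5]  # overlapping hexamers
        assert scan_pas("AANAAA") == []  # N never matches
        assert scan_pas("AATAA") == []  # shorter than 6

    def test_matches_exhaustive_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(rng.choice(bases, size=500))
            assert scan_pas(seq) == pas_oracle(seq)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGTN", max_size=200))
    def test_matches_oracle_property(self, seq):
        assert scan_pas(seq) == pas_oracle(seq)

    def test_reverse_complement_consistency(self, rng):
        from Bio.Seq import Seq

        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(rng.choice(bases, size=300))
            rc = str(Seq(seq).reverse_complement())
            assert scan_pas(rc) == pas_oracle(rc)


class TestPasDensity:
    def test_density_arithmetic(self):
        genome = {"chr1": "C" * 500 + "AATAAA" + "C" * 494 +
                  "ATTAAA" + "C" * 494 + "AATAAA" + "C" * 500}
        pr = PromptRegion("p", "g", GenomicInterval("chr1", 0, 2000, "+"))
        (d,) = pas_density([pr], genome)
        assert d.n_sites == 3 and d.density == pytest.approx(1.5)

    def test_motif_free_sequence_zero(self):
        pr = PromptRegion("p", "g", GenomicInterval("chr1", 0, 1000, "+"))
        (d,) = pas_density([pr], {"chr1": "C" * 1000})
        assert d.density == 0.0

    def test_minus_window_scans_reverse_complement(self):
        # genomic forward TTTATT reverse-complements to AATAAA
        genome = {"chr1": "G" * 100 + "TTTATT" + "G" * 94}
        pr = PromptRegion("p", "g", GenomicInterval("chr1", 0, 200, "-"))
        (d,) = pas_density([pr], genome)
        assert d.n_sites == 1
        assert d.positions[0] == 200 - 106  # offset in transcript orientation

    def test_missing_chromosome_named(self):
        pr = PromptRegion("p", "g", GenomicInterval("chrZ", 0, 100, "+"))
        with pytest.raises(KeyError, match="chrZ"):
            pas_density([pr], {"chr1": "A" * 200})

    def test_length_scaling_identity(self):
        seq = "C" * 500 + "AATAAA" + "C" * 494
        genome = {"chr1": seq + "G" * 1000}
        d1 = pas_density(
            [PromptRegion("p", "g", GenomicInterval("chr1", 0, 1000, "+"))], genome
        )[0]
        d2 = pas_density(
            [PromptRegion("p", "g", GenomicInterval("chr1", 0, 2000, "+"))], genome
        )[0]
        assert d2.density == pytest.approx(d1.density * 1000 / 2000)

    def test_manifest_cross_check(self, small_data, small_genome):
        spec, genes, truth, _, _ = small_data
        genome, manifest = small_genome
        for row in manifest.itertuples():
            pr = PromptRegion(
                row.prompt_id,
                row.parent_gene,
                GenomicInterval(row.chrom, row.start, row.end, row.strand),
            )
            (d,) = pas_density([pr], genome)
            planted = (
                [int(x) for x in row.offsets.split(",")]
                if isinstance(row.offsets, str) and row.offsets
                else []
            )
            assert list(d.positions) == planted
            assert d.n_sites == row.n_planted


class TestSplitByClass:
    def make(self, densities_up, densities_stable):
        prompts, dens = [], []
        for i, v in enumerate(densities_up):
            pid = f"u{i}"
            prompts.append(
                PromptRegion(pid, pid, GenomicInterval("c", 0, 1000, "+"),
                             upregulated=True)
            )
            dens.append(PasDensity(pid, 1000, (), 0, v))
        for i, v in enumerate(densities_stable):
            pid = f"s{i}"
            prompts.append(
                PromptRegion(pid, pid, GenomicInterval("c", 0, 1000, "+"))
            )
            dens.append(PasDensity(pid, 1000, (), 0, v))
        return dens, prompts

    def test_partition_is_exhaustive(self):
        dens, prompts = self.make([0.5, 1.0], [2.0, 3.0, 4.0])
        out = split_density_by_class(dens, prompts)
        assert out["upregulated"]["n"] + out["not_upregulated"]["n"] == 5
        assert out["upregulated"]["median"] == 0.75
        assert out["not_upregulated"]["median"] == 3.0

    def test_empty_group_undefined(self):
        dens, prompts = self.make([1.0, 2.0], [])
        out = split_density_by_class(dens, prompts)
        assert out["not_upregulated"] == {"n": 0, "mean": None, "median": None}

    def test_planted_ordering_recovered(self, small_data, small_genome):
        spec, genes, truth, cov_c, cov_d = small_data
        genome, manifest = small_genome
        info = truth.set_index("gene_id")
        analysed = [
            g
            for g in genes
            if not info.loc[g.gene_id].low_expression
            and not info.loc[g.gene_id].neighbour_violation
        ]
        ws = define_prompt_windows(
            analysed, spec.prompt_window, spec.chrom_lengths, all_genes=genes
        )
        prompt_fc(ws, cov_c, cov_d)
        dens = pas_density(ws, genome)
        out = split_density_by_class(dens, ws)
        # upregulated PROMPTs were planted with fewer PAS motifs
        assert out["upregulated"]["median"] < out["not_upregulated"]["median"]


def test_extent_estimator_noiseless():
    cov = StrandedCoverage.zeros(LENGTHS)
    cov.minus["chr1"][10_000 - 4200 : 10_000] = 6.0
    est = estimate_prompt_extent(cov, gene(), max_extent=10_000, bin_size=100)
    assert est == 4200
    assert estimate_prompt_extent(StrandedCoverage.zeros(LENGTHS), gene()) == 0
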