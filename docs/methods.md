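# Methods

## Coordinate and signal model

All coordinates are 0-based half-open (BED convention); GTF input (1-based
closed) is converted at the parsing boundary. The TSS of a gene is
`span.start` on `+` and `span.end` on `-`; the TES is the opposite end.
Coverage is held per chromosome and strand at a fixed bin size (default
1 bp); a read overlapping a bin by ≥ 1 bp increments it. RPKM scales each
bin by `1e9 / (library_size · bin_size)`; normalisation never changes which
bins are zero. Region means are means of overlapped bins after clipping to
the chromosome; a fully off-chromosome window is an error at query time, not
at construction. bedGraph (one file per strand, zero runs omitted) is the
native interchange; bigWig import and plot rendering are deliberately out of
scope — profiles and matrices are exported as TSV.

## Windows and thresholds

| parameter | default | meaning |
|---|---|---|
| post_tes_window | 1000 bp | read-through window downstream of the TES |
| pre_tes_window | 500 bp | PAS-proximal window preceding the TES |
| neighbour_distance | 5000 bp | half-width of the promoter neighbourhood |
| tpm_min | 5 | expression inclusion cut (strict: < 5 removed) |
| upstream_filter_window | 1000 bp | read-in check upstream of the TSS |
| prompt_window | 3000 bp | upstream antisense (PROMPT) window |
| log2fc_up_threshold | 1.0 | upregulation class boundary (inclusive ≥) |
| fold_up_threshold | 2.0 | DE fold gate (inclusive ≥) |
| fdr_threshold | 0.05 | BH-adjusted p gate (inclusive ≤) |
| ratio_threshold | 0.70 | TMT candidate gate (strict <) |
| min_peptides | 5 | peptide-support gate (strict: < 5 discarded) |
| pseudocount | 0.01 | added symmetrically in every log2 ratio |

Design choices where the convention was genuinely open:

- **"Neighbour within 5 kb of the promoter"** is realised as *any other
  gene's span overlapping the symmetric window TSS ± 5 kb*. This removes
  divergent-promoter pairs as well as tandem neighbours. Span-overlap was
  chosen over TSS-distance because a long upstream gene body reaching into
  the promoter region contaminates the PROMPT window just as much as a
  nearby TSS does. The distance is configurable. The neighbour rule is
  evaluated within the expressed gene set when used as an analysis
  pre-filter (matching the published order: expression filter first, then
  neighbour exclusion).
- **Read-through denominator.** Two denominators are in circulation for a
  TES read-through statistic: the 500 bp pre-TES window and the whole gene
  body. Both are computed on every record; the body is the default and
  `denominator="pre_tes"` switches, so the ambiguity is exposed rather than
  buried.
- **Upstream-contamination cut-off.** The 1 kb upstream window is standard;
  the fold cut-off for calling a gene contaminated is not published, so the
  generic upregulation boundary (log2FC ≥ 1, i.e. 2-fold) is used and is
  configurable.
- **PROMPT window length** is not published; 3 kb brackets the normal
  (non-depleted) PROMPT extent while remaining shorter than typical
  intergenic spacing. Windows truncated by a chromosome edge keep their
  realised length in the PAS-density denominator; windows overlapping any
  other gene body are dropped with a warning.
- **PAS scanning** expands AWTAAA exactly (AATAAA | ATTAAA), reports
  overlapping matches, and scans only the transcript-sense strand (the
  caller supplies reverse-complemented sequence for minus-strand windows).
  A motif-probability framework adds nothing for a two-word exact pattern.
- **SE metaplots** sum the two strands before ratioing (eRNA is
  bidirectional); strand splitting is reserved for gene metagenes. The 95%
  halo is a percentile bootstrap over regions (default 1,000 resamples,
  seeded). A parametric (normal) band would be cheaper but assumes
  cross-region homogeneity that SE cohorts do not have.
- **Metagene body scaling** uses equal-width genomic slices with mean
  aggregation and no interpolation, so a flat track yields an exactly flat
  matrix and, at bin 1 with body_bins = region length, the row mean equals
  the region mean to 1e-9. Minus-strand rows are reversed so columns always
  run 5′→3′. Off-chromosome flank bins are masked, not zero-filled into the
  averages.

## Differential-expression stand-in

Re-implementing a negative-binomial GLM framework is out of scope. The
caller used for the fold ≥ 2 / padj ≤ 0.05 classification is deliberately
simple and loudly documented as a stand-in: median-of-ratios size factors
(genes with any zero excluded from the reference; total-count fallback),
Welch's t on log2(normalised counts + 1) with ≥ 2 replicates per side, an
exact two-sided binomial split of the pooled count for 1-vs-1 designs, and
Benjamini–Hochberg correction. It has no dispersion shrinkage, so its power
at low counts is below a proper NB model; the test suite verifies its type-I
control on fully null Poisson simulations (20 seeded runs of 2,000 genes,
3 vs 3) and full recovery of 6-fold changes at depth 200. The reported
log2FC uses the symmetric pseudocount, not the test statistic.

## Synthetic-data generator

The generator emulates the structure of a two-condition nuclear RNA-seq
depletion experiment. Genes sit in fixed 30 kb slots (singles, planted
tandem pairs 4 kb apart, planted divergent pairs 1.5 kb apart) on four
1.5 Mb chromosomes; SEs occupy a dedicated chromosome. Expected per-base
coverage is:

- gene body: `λ_g` (log-normal, median 150, σ = 0.4, floored at 50× so
  recovery is tested at realistic depth), sense strand; planted DE genes are
  multiplied by 6 in the depleted condition;
- post-TES tail: `λ_g · r · exp(−x / 500 bp)` with read-through fraction
  r = 0.05 in control, raised to 0.40 in depletion for 30% of eligible
  genes;
- PROMPT: an antisense plateau `q · λ_g` (q = 0.3) reaching 1.5 kb upstream
  in control; for 50% of eligible genes the depleted condition multiplies
  the amplitude by 2.5 and extends the plateau to 8 kb (stabilisation and
  extension). A hard-stop plateau rather than a decay makes the extent a
  crisp recoverable parameter;
- upstream read-in: a small sense baseline (0.05 λ_g) over the 1 kb upstream
  window, amplified 4-fold on depletion for 5 planted genes. It does not
  scale with a gene's own DE fold — it models leakage from outside the gene;
- SEs: 111 regions of 2 kb with bidirectional plateaus (5 units control,
  ×3 on depletion);
- observed coverage: independent Poisson per base (switchable off; the
  noiseless track equals the expectation exactly, which the closed-form
  tests exploit).

PROMPT window sequences are scrubbed of spontaneous AWTAAA hexamers (in
transcript orientation) and then receive planted motifs at recorded offsets
— few (0–3) for windows whose PROMPT is planted upregulated, more (4–9) for
stable ones, mirroring the observed direction that susceptible PROMPTs are
not PAS-enriched. The manifest lists every planted offset, and a
cross-module test requires the scanner to reproduce it exactly. Planted
low-expression genes use a depth of 0.02× (essentially silent), so the
TPM < 5 truth set is robust to counting noise by construction. The truth
table also stores closed-form expectations of the read-through delta and
PROMPT log2FC (including the pseudocount), which is what the recovery tests
and the acceptance script compare against.

The proteomics table draws null ratios from Normal(1, 0.1) truncated at 0
and depleted ratios from Uniform(0.30, 0.60); one of the four planted
proteins receives < 5 peptides so the peptide gate is exercised.

Randomness uses one master seed with labelled `SeedSequence` spawn keys per
stream (annotation, genome, coverage × condition × replicate, counts,
proteomics, reads), so all emitted files are byte-identical across runs.

What the generator does **not** model: splicing-aware coverage (bodies are
painted uniformly over the span although annotations carry two exons),
fragment-length and mappability artefacts, realistic base composition,
overdispersion beyond Poisson, and replicate-to-replicate library biases.
Passing the recovery suite therefore demonstrates correctness of the
*quantification arithmetic and filters*, not robustness to all features of
real sequencing data.

## Problem sizes

Module tests run a reduced cohort (40 genes, two 600 kb chromosomes, 24 SEs,
80 proteins); full study scale (200 genes, 111 SEs, 200 proteins) is used by
the acceptance suite and `scripts/acceptance.py`, chosen so the whole suite
completes in well under a minute of simulation time while keeping ≥ 45
read-through and 75 PROMPT planted effects for the ≥ 95% recovery
statements. The demo determinism check also runs at the reduced scale;
determinism is scale-independent because it rests on the seeding scheme, not
on problem size.

## Degenerate inputs and tie-breaking

All-zero tracks give read-through index 1 (p/p) rather than 0/0. Genes
shorter than the pre-TES window are skipped with a warning, as are windows
falling entirely off-chromosome. Metagene rows shorter than the body bin
count are masked. SE metaplots with < 2 regions return means without a
halo. TPM of an all-zero count vector is all zeros (no division error).
Proteomics candidates are ranked by mean ratio ascending with lexicographic
protein-id tie-breaks; proteins with fewer than two observed replicate
ratios are excluded (triplicate design, missingness policy chosen here).
Equal observed ratios yield their common value exactly, so a protein sitting
exactly on 0.70 is excluded by the strict gate regardless of replicate
count.
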