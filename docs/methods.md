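# Methods

## Signal model

Sequencing DOP-PCR amplified, flow-sorted chromosome DNA produces reads that
concentrate at discrete amplicon loci fixed by the primer's 3' hexamer
(`ATGTGG`).  Merging overlapping (or book-ended) reads gives *DOP-positions*;
the per-chromosome series of *pairwise distances* (PD) — `pd[i] = start_i −
end_{i−1}`, with `pd[0]` the distance of the first position to coordinate 0 —
satisfies the conservation identity `sum(pd) + sum(lengths) = end of last
position`, which the code asserts.  Sequence present on the sorted
chromosome appears as a run of PD values roughly an order of magnitude below
the whole-genome background (one amplicon per ~2 kbp versus ~40 kbp), so
region detection is mean-changepoint detection on the PD series.

## Decontamination

Each read carries a MAPQ pair from alignment to the target genome and to the
contaminant (human) genome.  A read is contaminant iff its contaminant MAPQ
strictly exceeds its target MAPQ (absent alignments count as 0; equal MAPQs
keep the read — conservative toward target signal).  Survivors must have
target MAPQ > 20 (strict).  Filtering is per mate, not per pair: no
pair-level rule is defensible from the data, and discarding a clean mate
loses signal.  The contaminant comparison is applied to raw MAPQs first and
the floor to the survivors; the order only moves reads between the two
"removed" counters, the kept set is identical either way.  Reads unmapped in
the target genome are dropped before statistics since they contribute no
coordinates.

## Outlier trimming

Two PD populations carry no regional information and are removed before
segmentation:

* `pd_low = 300` bp (default): near-zero gaps are usually two non-overlapping
  reads of one amplicon, not two amplicons; 300 bp sits just above the upper
  amplicon length mode (~200 bp).
* upper cut at the genome-wide 99.5th percentile (`pd_high_quantile =
  0.995`): the largest gaps are unmappable stretches — assembly gaps,
  repeats, centromeres — whose lengths say nothing about the local amplicon
  density.

Both are configurable; the quantile is computed over the pooled PDs of all
chromosomes so that a chromosome made mostly of target sequence does not
trim its own background.

## Circular binary segmentation

Implemented from scratch (no wrapping of existing CBS packages).  For an arc
of n values with mean mu and SD sigma, every candidate split is a window of
length k starting at i (wrap-around allowed at the first, chromosome-level
stage; recursions after a cut operate on linear pieces, where interior
(i, j) pairs are still tested).  The score is

    T(i,k) = |mean_in − mean_out| / (sigma · sqrt(1/k + 1/(n−k)))

maximised over all windows subject to every resulting piece having at least
`min_width = 4` positions.  Since mu and sigma are permutation-invariant, T
is evaluated as the equivalent `|W − k·mu| / sqrt(k(n−k))` (W the window
sum), which the permutation test can compare without recomputing variances.
The best window's p-value is estimated from `n_perm = 1000` label
permutations with a fixed seed, `p = (1+e)/(1+n_perm)`; the split is
accepted iff p < `alpha = 0.01`.  The permutation loop stops early once
enough exceedances make p ≥ alpha certain (acceptance always runs the full
set); within a permutation, scanning stops at the first window beating the
observed score.  These are speed-only shortcuts — tests assert the chosen
split equals an independent brute-force oracle.  Ties break to the earliest
window start, then the shortest window, so results are deterministic given
the seed; per-chromosome seeds derive from one `SeedSequence`.

Segmentation runs on `log2(PD+1)` by default (PD is heavy-tailed;
copy-number practice segments log signal), configurable to identity.
Reported segment means are always on the untrimmed bp scale.  A final
pruning pass re-merges adjacent segments whose means do not differ at alpha
(Welch t-test), largest-p first, until stable.  alpha, n_perm and min_width
are this package's defaults chosen for desk-scale runtime with conventional
copy-number-segmentation significance; they are not fitted to any dataset.

The numerically heavy kernels are numba-compiled with a pure-Python
fallback.

## Region calling

Segments are classified by 1-D 2-means on log2 mean PD; the low cluster is
target.  Guard rails, because the classifier is a provisional tool:

* no contrast (cluster centres within 4x linearly) → everything background,
  with a warning;
* segments within 2x of the cluster boundary → `ambiguous`, for visual
  review;
* target segments with fewer than 10 positions within 100 kbp of a
  chromosome end → `ambiguous` (spurious mapping of telomeric reads creates
  exactly such artifacts);
* runs of ≥ 3 consecutive low-PD positions outside called regions are
  reported separately as `candidate (visual)` — the programmatic counterpart
  of rescuing small regions by eye from the PD plot, which is how regions of
  a few tens of kbp below the CBS detection limit are found.

Adjacent target segments on one chromosome merge into one region (the
recursion tends to shatter long regions; adjacency in retained-index space
is the merge criterion).  Margins then get refined against the *full*
position table, in two passes:

1. *shrink*: a terminal run of < 10 positions separated from the region core
   by a gap > 8x the region's mean PD is a stray background cluster — at
   target density such a gap would contain dozens of positions — and is
   dropped.  A genuine internal deletion is not affected: the run beyond it
   is long.
2. *extend*: walk outward while the spacing stays within 2x the region's
   mean PD.  This recovers the region's true first position, whose PD value
   is the large entry gap from the background and which CBS therefore
   systematically assigns to the background segment (and which outlier
   trimming may have removed entirely).

The achievable margin resolution is the inter-amplicon spacing, ~2 kbp at
default density; simulations measure mean margin error ≈ 1.5–3.5 kbp.

## Deletions and genes

Putative deletions are maximal internal stretches of a target region with no
overlapping position and length ≥ `min_gap = 100 kbp` (the smallest deletion
worth reporting in the case studies is 140 kbp; the brocket mean is
~103 kbp).  Overlap with an assembly gap is annotated as a possible
explanation — unmappable reference sequence — not as evidence of absence.

Gene completeness: fully inside the region and clear of deletions →
complete; crossing a region margin → partial "(f)"; inside but overlapping a
deletion → partial "(f?)".  A gene doing both resolves margin-first (the
catalogs never double-flag).  Size accounting reports the summed region
lengths and the total net of deletions clipped to regions.

## Variant accounting

Callsets are matched exactly on (chrom, pos, ref, alt) after left-trimming
shared allele prefixes; no further normalisation (the source callsets follow
GATK conventions).  Subtraction of a relative's derived-position set strips
species-level divergence from the B-chromosome callset.  Densities are
`round(covered_bp / n_variants)` per feature class, with zero-variant
classes reported as undefined ("-"), never 0.  Feature classes overlap in
real annotations; reporting assigns one class per bp and per variant with
precedence coding > UTR > intron > intergenic (flagged in output as a
simplification — printed class counts need not sum to totals).  The effect
classifier translates the affected codon with and without the alternate
allele (standard code, strand-aware, multi-exon CDS); any CDS indel is
non-synonymous (frameshift or inframe).  Novelty applies the depth filter
before the known-set lookup.

## Simulator

`simulate_experiment` draws amplicon start sites as a Poisson process:
`target_rate = 0.5`/kbp inside truth regions (one per 2 kbp, as observed on
B-chromosome regions), `background_rate = 0.025`/kbp elsewhere (one per
40 kbp), zero in planted deletions and assembly gaps.  Amplicon lengths are
a 50/50 normal mixture, 100±10 and 190±10 bp — the two length modes seen
with tagmentation libraries.  Each amplicon emits one read pair covering its
two ends; 2% of reads are given contaminant-better MAPQ pairs (within the
1.1–4.3% observed range) and 5% sub-floor target MAPQs.  Variants are
planted only within covered intervals (target compartment: 1 variant per
23 bp, 60% het; background: 1 per 316 bp, 33% het — matching the observed
density regimes), so density accounting is exactly recoverable.  Everything
derives from a single seed; identical seeds give byte-identical output.

What the simulator does *not* model: read sequences and sequencing error,
mapping ambiguity, repeats, PCR duplicates, primer-site mutation, real
contamination genomics.  Passing tests therefore demonstrate the inferential
machinery (filtering, merging, segmentation, calling, accounting) under the
stated statistical structure, not robustness to alignment artifacts.  The
optional motif mode derives amplicon intervals deterministically from
inward-facing `ATGTGG` / `CCACAT` occurrences in a supplied sequence.

The ready-made study layouts are desk-scale by design: the roe-like
configuration plants the real region and deletion sizes (1.94 Mbp + 41 kbp,
deletions 420/140 kbp) on a 21 Mbp genome; the brocket-like configuration
plants all 26 real region sizes (23 kbp–1.83 Mbp) two per chromosome on a
42 Mbp genome.  Shrinking the background genome (not the regions) keeps CBS
runtimes at seconds per genome while preserving the density contrast that
drives detection.

## Shipped catalogs and synthetic stand-ins

`dopseg.deer` ships the bosTau7 coordinates of the roe and brocket
B-chromosome homology regions, the two roe deletions, gene completeness
flags and the per-sample covered-bp/variant-count tables, as plain TSV.
Gene *coordinates* and the individual brocket deletions are not part of the
published record — only names, flags, the deletion count (10) and total
(1.03 Mbp) are — so `synthetic_gene_models` and `synthetic_brocket_deletions`
construct synthetic intervals realising exactly those constraints; they are
labelled synthetic and exist so the completeness and accounting arithmetic
can be exercised end to end.

## Known limitations

* Region classification needs genome-wide contrast; a library that is almost
  entirely target (or entirely background) degrades to the warned
  "no-contrast" path and a manual threshold.
* CBS detection requires `min_width` positions; regions below ~10–20 kbp at
  default density surface only via the candidate scan.
* A chance cluster of background positions can still survive margin
  refinement if it is long (≥ 10 positions); observed as rare 20–35 kbp
  margin excursions in simulation.
* The effect classifier is transcript-naive (one model per gene, no splice
  variants, no NMD annotation) by design.
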