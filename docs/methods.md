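# Methods

## The analysis in one paragraph

An iMARGI library is a set of chimeric read pairs, each linking a
chromatin-associated RNA fragment (RNA end, Read 1) to the genomic locus
it was ligated to (DNA end, Read 2). After sequence-level cleaning,
deduplication and removal of *proximal* pairs (same chromosome, ends
within 200 kb — dominated by nascent transcripts hybridising near their
own locus), the remaining *remote* pairs describe where RNAs sit on the
genome away from their source. Independently, fusion-transcript calls
from tumor RNA-seq cohorts are reduced to a catalog of unique unordered
gene pairs ("Futra pairs") with per-sample recurrence. The central
question is statistical: are Futra pairs enriched for RNA–DNA
interactions in normal cells, relative to ordinary gene pairs of the
same class? The package answers it with an explicit overlap rule, a 2×2
contingency table, the odds ratio and a χ² test.

## Conventions that matter

* **Coordinates.** `.pairs` input is 1-based; BED annotation is 0-based
  half-open. Conversions happen only at I/O boundaries; all interval
  logic is 0-based half-open internally.
* **Proximal boundary.** "Within 200 kb" is inclusive: a pair at exactly
  200,000 bp is proximal. Distance is between the mapped 5′ positions of
  the two ends, the `.pairs` convention.
* **Deduplication.** Exact six-tuple equality (both chromosomes,
  positions, strands); first occurrence kept. No positional tolerance —
  a 1-bp shift is a different molecule.
* **Gene-pair distance.** The gap between gene *bodies*,
  `max(0, max(starts) − min(ends))`, zero for overlapping bodies. The
  200-kb neighbour removal in the catalog targets read-through
  transcription between adjacent genes, which a body-gap metric captures
  directly; TSS-to-TSS would misclassify long genes.
* **Overlap rule.** A read pair supports gene pair (A, B) iff its RNA
  end lies in one gene's body *on the gene's annotated strand* (sense
  mode, the default; antisense and ignore are switchable because library
  chemistry could imply the reverse convention) and its DNA end lies in
  the other gene's body ± 100 kb (clipped at chromosome bounds), in
  either orientation. The DNA-end strand is never tested. Implemented
  with per-chromosome interval trees; the O(n·m) double loop over reads
  × gene pairs is retained in the test suite as the oracle.
* **Enrichment test.** The background universe is all annotated
  unordered gene pairs of the same class (intrachromosomal with body gap
  > 200 kb, or interchromosomal), minus the Futra set; a background pair
  counts as "with interaction" under the same overlap rule. χ² uses the
  margin formula with Yates continuity correction by default (the R
  convention for 2×2 tables); the Woolf log-odds 95% CI is attached.
  Degenerate tables (a zero margin) report NaN with a reason rather than
  raising.

## The synthetic study

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is verified.

* **Genome.** Equal-length chromosomes (default 4 × 20 Mb), 200
  non-overlapping genes of 5–50 kb placed by a sorted uniform-spacing
  construction, strands random. This is a deliberately scaled-down
  genome: dense enough that flanking windows occasionally interact,
  small enough that the all-gene-pairs background universe (~20,000
  pairs) is enumerable in tests.
* **Read pairs.** Each pair draws a class from (proximal, distal,
  interchromosomal) = (0.35, 0.10, 0.55), the canonical class mix of a
  human iMARGI library. Proximal pairs take a uniform offset within the
  threshold (their law is immaterial; they are discarded downstream).
  Remote pairs are background with probability 0.9 — distal distances
  follow a truncated power law d^(−1.5) beyond 200 kb, reproducing a
  monotone distance decay without asserting any particular empirical
  exponent — or *gene-assigned* with probability 0.1
  (`gene_assign_fraction`): an eligible gene pair of the matching class
  is drawn with weight `enrichment_factor` (default 20) for the
  susceptible pairs and 1 otherwise; the RNA end falls uniformly in one
  body (on that gene's strand), the DNA end in the other. The 0.1 keeps
  the expected read count per background gene pair well below 1, so the
  background universe is sparse — as in real libraries, where reads are
  spread over ~2×10⁸ gene pairs — and the enrichment contrast is
  informative rather than saturated. Gene-assignment for distal reads is
  restricted to same-chromosome gene pairs with body gap > 200 kb, so a
  gene-assigned "distal" read can never be proximal.
* **Fusion cohort.** 500 samples; per sample each susceptible pair
  fires with probability 0.004 and each other pair with 5×10⁻⁶. The
  background mass (~50 expected one-off pairs) dominates the unique-pair
  count, giving the mostly-singleton recurrence profile characteristic
  of cohort fusion catalogs, while the per-pair rate ratio (800×) keeps
  the catalog preferentially susceptible. A planted 20%
  (`filter_fail_fraction`) of calls carry support counts that fail the
  call filter, so the filter is exercised on realistic input.
* **FISH fields.** Gaussian spots (σ = 1.5 px, amplitude ≫ noise) at
  mutually separated centers; a planted fraction of channel-A centers is
  shared (with sub-pixel jitter) with channel B. Spot detection uses
  8-connected components above a threshold chosen at the midpoint
  candidate of the longest run of consecutive thresholds with unchanged
  count (ties to the lowest run — deterministic and sensitive);
  candidate thresholds default to 100 levels between the 50th and 99.9th
  intensity percentiles. Matching is mutual-nearest-neighbour within
  2 px by default, one-to-one, ties broken on (distance, index).

What the generator does **not** emulate: alignment error, mappability,
chimeric artifacts, copy-number structure, expression heterogeneity
across genes, cell segmentation, or 3D image stacks. Passing tests
therefore demonstrate the correctness of the pipeline's logic and
statistics under known ground truth, not the biological effect sizes of
any real dataset.

## Replicate-level calibration

Two batteries of 50 seeded replicates (30,000 read pairs each — sized so
one battery runs in seconds on one core) check the enrichment statistic
end to end: with no planted signal (enrichment factor 1, equal fusion
rates) the 95% log-odds CI covers 0 in ≥ 90% of replicates; with the
default planted conditions the test returns OR > 1 at p < 0.05 in ≥ 90%.

## Numerical and degenerate-input choices

* Power-law sampling by inverse CDF, with the α = 1 logarithmic case
  special-cased.
* Empty pair sets summarize to zero counts with NaN fractions/ratios,
  not errors; an all-distal set has remote ratio 0; a distal-free set
  with interchromosomal pairs reports ∞.
* Row normalization leaves all-zero rows untouched and refuses to run
  twice.
* Pearson correlation of a zero-variance profile is NaN.
* A flat image yields zero spots with a degenerate threshold scan. Spot
  counts are non-increasing in the threshold for well-separated spots
  (the regime the plateau search assumes); a single component with
  multiple peaks can split as the threshold rises, so global
  monotonicity is not asserted.
* The fusion map places each gene at its body midpoint so a
  boundary-straddling gene has a unique bin; symmetric cells are
  mirrored and same-bin pairs counted once on the diagonal.
* The decay curve counts *ordered* (RNA bin, DNA bin) cells at each
  separation; its bin size defaults to 1 Mb and is a parameter.

## Known limitations

* Gene identity is by `gene_id`; symbol resolution must happen upstream.
* The background universe for enrichment is the annotated gene-pair set;
  restricting to expressed genes is the caller's responsibility (pass a
  filtered annotation).
* MAPQ/multimapping filtering is assumed done upstream of the `.pairs`
  input.
* Recurrence counts distinct samples, never call records.
* FISH detection is threshold-plus-centroid; no PSF fitting, no
  deconvolution, 2D only.
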