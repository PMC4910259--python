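# Methods

## The FM-bias model

The test treats the somatic mutations observed in a genomic element across
a tumor cohort as draws from a local mutational process and asks whether
their mean functional-impact (FI) score is larger than that process would
produce.  The null model is fully specified by two ingredients:

* the element's **substitution space** — every (position, alternate
  allele) pair inside the element's segments, each with an FI score from a
  pluggable provider (CADD-style deleteriousness, RNA-structure disruption,
  or the synthetic provider bundled here);
* a **96-channel trinucleotide signature** — probabilities over
  substitution classes `5'[ref>alt]3'` with the mutated base collapsed to
  the pyrimidine strand.  Collapse is what yields exactly 96 classes
  (64 contexts × 3 alternates = 192 raw pairs, identified pairwise with
  their reverse complements).

Background sets of size *k* (the observed mutation count) are drawn **with
replacement**, each candidate weighted by the signature probability of its
channel, normalized within the element.  With-replacement sampling matches
an i.i.d. mutational-process model and keeps the exact enumeration oracle
(all weighted *k*-tuples) tractable for testing.  The observed mutations'
own entries remain in the pool.

The empirical p-value is `count / N` with ties counted as exceedances
(`≥`), the conservative reading; a `strict_ties` flag switches to `>`, and
a `pseudocount` flag to `(count+1)/(N+1)`.  When the count is zero, *N*
doubles (fresh draws from the same per-element stream) up to
`escalation_max` (default 10⁶); a still-empty count is reported as the
one-sided bound `1/escalation_max`.  A `tail="left"` option computes the
lower tail, probing negative selection instead.

Benjamini–Hochberg runs over elements mutated in at least
`min_samples_for_fdr` distinct samples (default 2; 5 is the pan-cancer
preset); sub-threshold elements keep their p but receive no q.

### Counting conventions

* Recurrent mutations count once per occurrence (a position mutated in 3
  samples contributes k = 3), matching needle-plot recurrence semantics.
* Mutations at positions without scores are excluded from the observed
  mean, and *k* is reduced accordingly — symmetric with their absence from
  the sampling pool.  How the original method handled unscored mutations is
  not documented; exclusion is this package's choice.
* A mutation inside two overlapping elements is tested in each
  independently.
* ref/alt are always expressed on the + strand; internal coordinates are
  0-based half-open, file formats 1-based.

## Element catalog

From a Gencode-style GTF (`gene_type`/`transcript_type` attributes):

* **cds** — merged CDS of genes where both biotypes are protein-coding.
* **splice** — the first and last 50 bp of each protein-coding intron;
  intron edges are clipped and merged when introns are ≤ 100 bp, so no
  base is double-counted.
* **utr5/utr3** — annotated UTRs minus any CDS annotated anywhere in the
  genome and minus 10-bp short intron edges; 5′ UTRs additionally lose 3′
  UTR overlaps.  Plain Gencode `UTR` features are classified 5′ vs 3′ by
  their position relative to the transcript's CDS extent (strand-aware);
  features fully inside or spanning the CDS extent are ambiguous and
  skipped with a warning.
* **promoter** — 2500 bp upstream of the gene's TSS (the most 5′
  protein-coding transcript start; one promoter per gene), minus global
  CDS, UTR, and short-splice masks, clipped at chromosome bounds.
* **lncrna** — merged exons of lincRNA genes minus the same masks.

Masking is global ("previously annotated" anywhere): any gene's CDS masks
any gene's promoter or UTR.  Two readings the annotation source leaves
open: promoter masking uses the 10-bp short splice sites (not the 50-bp
test elements), and promoter windows are not clipped by upstream gene
bodies beyond the listed masks.  Irreproducible manual curation is
replaced by an optional id blacklist.

## Randomized negative control

Each mutation is repositioned uniformly among the positions of its window
whose reference trinucleotide matches the mutation's collapsed context in
either orientation, with the alternate allele mapped so the 96-channel
class is preserved exactly.  Windows are fixed 50-kb tiles
(`floor(pos/50000)`), which makes the scheme deterministic and
order-independent; a `centered` option uses ±25 kb around each mutation.
Mutations at chromosome edges or without an in-window match keep their
position (counted in the report).  Per-sample counts and the channel count
vector are conserved exactly by construction; repositioned mutations may
collide, as real recurrences do.

## Synthetic study conditions

The generator's defaults define the study scale: one 2-Mb chromosome at
GC 0.5; 38 protein-coding genes (three exons, two 500-bp introns, 150/250
bp UTRs, 2500-bp promoters) and 10 lincRNA genes on a deterministic grid,
giving 200 elements (~147 kb under test); 50 samples with
Poisson(40) mutations each.  FI scores are per-position
Exponential(scale = 3) base values plus N(0, 0.3) alt-specific jitter —
an exponential-tailed score, emulating the long right tail of
deleteriousness metrics; 1% of entries per element (minimum 3) are raised
above the element's maximum, serving as hotspots and exceeding the 99th
percentile by construction.  The generating signature enriches C>T
channels fivefold (deamination-like) while keeping all 96 channels
possible.

Null cohorts draw every mutation from the pooled element substitution
space with signature weights, **reusing the test's own sampling machinery**
(`ElementScorer`), so null calibration is a genuine self-test: a
non-uniform p-value distribution indicates a bug, not model mismatch.
Driver injection adds one mutation from each of 10 distinct samples to the
chosen element, hitting a hotspot entry with probability 0.8.

What the toy world deliberately lacks: mutations outside tested elements
(real cohorts are mostly intergenic), covariate structure such as
replication timing or expression (the local test is covariate-free by
design), heavily tied/discretized scores (real CADD tables quantize, which
makes the `≥` tie rule conservative on real data), indels, and multiple
chromosomes.  Passing tests therefore validate the statistics and the
plumbing, not score-model realism.

## Numerical and design notes

* Per-element RNG streams derive from `SeedSequence([master_seed,
  blake2b(element_id) mod 2^31])`, so results are independent of element
  iteration order and parallelization; runs are bit-identical given a
  seed.
* Element probabilities are renormalized per element; if every candidate
  has zero signature probability the element aborts with a
  signature-mismatch diagnostic rather than silently reverting to uniform.
* Signature estimation skips mutations at chromosome edges (no context)
  with a logged count; zero-count channels keep probability 0 (no
  pseudocount); per-sample mode requires at least one countable mutation
  per sample.
* Statistical test sizes used by the test-suite: N = 10,000 iterations
  (the default) for cohort-level runs, N = 200,000 for the
  exact-enumeration comparison on micro elements (≤ 6 entries, k ≤ 3),
  20 fixed seeds for seed-fraction checks.
* The `qq_data` expected quantiles are `i/(n+1)`; `fold_enrichment`
  normalizes by the truth-set proportion over the full ranked list and
  returns 0 when the overlap is empty.

## Known limitations

* BH at q < 0.1 under a global null is a Simes-type test with ~10%
  per-cohort family-wise false-positive probability when p-values are
  well calibrated and continuous; with the toy world's continuous scores,
  roughly one randomized cohort in ten shows a (spurious) significant
  element.  This is a property of FDR control itself, not of the
  background model, and is weaker on real, heavily tied score tables.
* The `count/N` estimator is slightly anti-conservative at thresholds near
  its resolution (P(p̂ ≤ t) ≈ t + 1/N); the `pseudocount` flag removes
  this at the cost of a p-value floor.
* Only SNVs are modeled; indels/MNVs are dropped in QC.  Score providers
  are consumed, never computed; elements with unscored positions are
  tested on their scorable subspace and flagged.
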