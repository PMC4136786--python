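# Methods

## Scope and model

`cfexome` models ctDNA monitoring with a fixed panel of patient-specific
somatic SNVs. Indels, copy number, rearrangements and UMI-based
deduplication are out of scope. Coordinates are 0-based half-open
internally; emitted SAM records follow the format's 1-based convention.

## Synthetic cfDNA generator (`synth`)

The generator emulates the features of a cfDNA library that the
downstream stages exploit, with exact provenance for every read:

- **Fragment sizes**: truncated normal, default mean 180 bp, SD 40 bp,
  truncated to [50, 2x read length + 50]. Real cfDNA shows a ~180 bp
  mononucleosomal peak; the parametric form is our choice — real size
  distributions are asymmetric with a di-nucleosomal shoulder, which is
  not modelled.
- **Reads**: 2x100 bp pairs with correct reverse-complement mate
  geometry; fragments shorter than a read are emitted pre-trimmed to the
  template (adapter read-through is represented by trimming, not by
  adapter sequence).
- **Mutations**: a molecule covering one or more panel sites is
  tumor-derived with probability `ctdna_fraction` and then carries the
  alternate allele at every covered site.
- **Duplicate families**: geometric family sizes (support ≥1) with
  configurable mean, default 3 reads per molecule — a mid-depth library;
  saturation-sequenced libraries with ~80% duplicate rates correspond to
  a mean near 5.
- **Two error channels**: PCR errors are injected once per family
  template (default 1e-4 per base, an aggregate of polymerase errors over
  the amplification; no published per-base value exists for this kit
  chain), sequencer errors per read (default 0.0029 per base, the
  empirical cfDNA short-read substitution rate). Both are uniform
  substitutions; no indels, no per-cycle or sequence-context quality
  structure, no GC or capture bias.
- **Base qualities** are constant (q30) by default; quality separation
  between pipeline stages arises from merge/consensus boosting, which is
  the property the cutoff sweep uses. Consequences: cutoff sweeps on raw
  synthetic data are degenerate (all-or-nothing), which the tests
  acknowledge by constructing quality-mixed fixtures where a graded sweep
  is needed.

Because the aligner is out of scope, `truth_alignments`/`write_alignments`
place reads at their true coordinates. Passing tests therefore show
correctness of the pipeline logic given correct alignments, not
robustness to mapping error (the eligibility mask is the production
defence there).

## Overlap merging (`merge`)

The merger scans every offset of the reverse-complemented mate 2 against
mate 1 and accepts the offset with the most matches subject to overlap ≥
`min_overlap` (default 15) and mismatch fraction ≤ `max_mismatch_rate`
(default 0.1); ties prefer the longer overlap. `N` counts as a mismatch,
and an `N` in either mate of an overlap column masks the column. The
thresholds are conventional merge-tool defaults; the published tool's
values are not recorded. Concordant overlap columns get quality
`min(q1+q2, 45)`; discordant columns `N`/q2. With 2x100 bp reads, only
fragments ≤ 200 − `min_overlap` = 185 bp can merge; longer pairs pass
through unmerged, which matches the behaviour on real libraries.

## Duplicate consensus (`dedup`)

Merged single-end reads are keyed on (chrom, strand, 5' coordinate,
template length); unmerged pairs on both outer coordinates plus
orientation. The length-aware key is a strict refinement of the
start-only key, so retained unique coverage can only grow; on
variable-length cfDNA libraries the gain is strictly positive.

Consensus per column: the modal non-`N` base is kept iff its count ≥
0.75 x family size (inclusive: 3 of 4 passes; `N`s count toward the
family size but never toward the modal base; a modal tie necessarily
fails). Its quality is the sum over the reads *carrying that base*
(reads with a different base do not contribute), capped at 50. Failing
columns become `N`/q2. Singleton families pass through byte-identical.
Boosted qualities downstream serve only as a multi-source-support filter
score, never as calling-evidence weights.

## Eligibility mask (`mask`)

Excluded: low-mappability intervals expanded by `flank` (default 50 bp,
inclusive distance — a site exactly 50 bp from the interval is excluded,
51 bp is eligible), simple-repeat intervals, and germline positions
(population SNPs and cohort germline calls enter as separate tracks but
are treated identically). The mappability track is consumed already
thresholded (mappability < 1); computing mappability from sequence is
out of scope. Removal reports count per-source hits (a site in two
sources counts toward both) plus the distinct total.

## Noise model (`noise`)

Noise rate = Σmut / (Σmut + Σref) over the pooled background at tracked
sites. (The alternative convention Σmut/Σref differs at O(rate²), far
below any decision threshold here; the mut/(mut+ref) form is fixed
throughout.) Pools are leave-one-out per sample and exclude, per site,
any sample whose own tumor carries the same mutation. The cutoff sweep
reports, per quality threshold q: noise rate, `fraction_data_left`
(reference reads retained relative to q=0, monotone non-increasing) and
the log2 ratio of retained mutant vs reference proportions.
`optimal_cutoff` takes the argmin of the noise rate, breaking ties
toward higher retention, then smaller q. The per-base score filtered on
is the merge/consensus-boosted base quality (caps 45/50); an
alignment-aware recalibrated score can be supplied externally by
populating fragment qualities before counting, but no hidden-Markov
realignment is performed here, so numeric cutoffs are tied to this
package's quality scale.

## Pooled detection (`detect`)

All of a patient's eligible sites are pooled into one 2x2 table
(sample alt/ref vs background alt/ref) and tested one-sided
(alternative: sample fraction greater) with the exact hypergeometric
tail, computed via the hypergeometric survival function; `sample_alt = 0`
gives p = 1 exactly. The ctDNA fraction is reported raw
(alt / (alt + ref)) without background subtraction, and no
multiple-testing correction is applied across patients; α defaults to
0.05 and the detected flag is `p < α`. Pooling assumes exchangeable
error rates across sites — site-specific error structure is deliberately
not modelled (the mask removes the worst offenders).

## Sensitivity simulation (`sim`)

Per (fraction f, input mass m): pooled depth

- exome mode: `round(m·1000 / 3.218 x efficiency x n_variants x kept)`,
  with 3.218 pg per haploid genome copy, efficiency default 0.047 (the
  saturation estimate; the cohort-wide 3.8% average is a config away),
  50 variants, kept fraction 0.61;
- WGS mode: `round(coverage x n_variants x kept)`, default 30x and 3000
  variants.

Sample mutant reads ~ Binomial(depth, f); no sample-side noise reads are
added — background noise enters only through the fixed background table,
default 517,973 reads with `round(517973 x noise_rate)` mutant (rate
default 1/35,419). The kept fraction scales depth multiplicatively
rather than by post-hoc read subsampling (equal in expectation).
Sensitivity = share of iterations (default 1000) with p < 0.05; the 95%
detection limit is the smallest grid fraction reaching 0.95, refined by
log-linear interpolation against the preceding grid point; the default
grid is 40 log-spaced fractions over [1e-5, 0.05].

Iterations use common random numbers: one uniform vector is pushed
through the binomial quantile function at every (depth, f), making the
sensitivity curve monotone in fraction and depth draw-by-draw rather
than merely in expectation, at identical marginal distributions. An
empirical-pool mode distributes depth over observed per-site read pools
instead of one pooled binomial; it is marginally equivalent and provided
for fidelity to resampling-based designs.

Two numerical caveats the tests encode explicitly:

- Near the null fraction, the discrete Fisher critical value shifts with
  depth, so draw-by-draw monotonicity in mass holds only in the power
  region (asserted where sensitivity ≥ 0.2).
- Depth is linear in input mass, so the 30→60 ng improvement is
  sublinear (doubling mass less than halves the limit — the background
  mutant expectation grows with depth) but not negligible; full
  saturation sets in only once pooled depth reaches the
  background-dominated regime (~3.5x10⁴ reads at the default noise
  rate). Stronger saturation would require a capture-yield model that is
  not specified here.

## Problem sizes used by the test-suite and acceptance script

Synthetic libraries in the tests use 12-40 panel sites, 300-2000
molecules and 12-30 kb genomes — the smallest sizes at which the
statistical assertions (binomial CIs, noise-rate orderings) have power.
The noise-ordering fixture raises the sequencer error rate to 0.02 so
each pipeline stage's pool sees enough error events for a stable
comparison; the ordering itself is rate-independent. The acceptance
script runs the full 1000-iteration, 40-fraction Monte-Carlo per
parameter set (~2 s total).

## Known limitations

- No alignment, so mapping artefacts are exercised only through the mask.
- Uniform, context-free errors; constant base qualities.
- Unmerged pairs are deduplicated but not consensus-collapsed (their
  family redundancy is not exploited).
- The detection-limit model ignores per-site depth variance beyond the
  pooled binomial draw and capture-bait dropout heterogeneity.
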