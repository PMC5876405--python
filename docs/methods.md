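# Methods

## Data model and counting semantics

RNase V1 cleaves base-paired RNA and leaves a 5′ end one nucleotide
downstream of the cut. A single-end read whose first mapped base is
1-based position *p* therefore contributes one count to position
*p* − 1 of its reference; reads starting at position 1 are dropped (the
inspected position would be 0), and by symmetry a count at the final
transcript position can never arise (the read would start past the
end). Only uniquely mapped primary alignments are counted,
operationalized as: not secondary/supplementary and MAPQ ≥ 1 (an
aligner emitting one alignment per read assigns positive MAPQ to unique
placements). Reverse-strand alignments are dropped by default because
transcriptome alignments of V1 libraries are expected forward; a flag
retains them using the read's 5′ end in reference coordinates.
Coordinates are 1-based and fully closed everywhere.

## Differential model

Counts at a position are modeled as negative binomial with variance
μ + φμ², with a **single common dispersion φ** shared by all positions.
φ is estimated by conditional maximum likelihood: counts are scaled to
a common effective library size and rounded (pseudo-counts), and the
likelihood of the within-group counts *given their per-position total*
— which is free of the unknown means — is maximized over φ across all
replicated condition groups. The estimate is floored at 0 (the Poisson
boundary). Tagwise or trended dispersions are out of scope; the
segment statistics only require approximately calibrated p-values, not
per-position variance modeling.

Library sizes are normalized with trimmed-mean-of-M-values (TMM) scale
factors by default (30% log-ratio trim, 5% abundance trim, precision
weights), with plain library-size scaling as a fallback for degenerate
inputs.

Significance at each position comes from an **exact test conditional on
the total count**: group sums of *n* replicates with common mean μ are
NB(*n*μ, φ/*n*); conditioning on the total *t* (with μ̂ = *t*/(*n_A* +
*n_B*) under the null) gives a discrete conditional distribution over
the splits, and the two-sided p-value doubles the smaller inclusive
tail, capped at 1. At φ = 0 with equal libraries this is the two-sided
binomial exact test on the split; a total of 0 returns p = 1. The
p-value source is pluggable: any per-position p-value array (e.g. from
an external count-model package) can be scored instead.

Fold-change is log₂ of the ratio of normalized group means with a 0.5
pseudo-count per mean. The abundance threshold *a* > 1 (average
normalized counts per sample per position, default 1, configurable) is
applied after normalization.

Null p-values from this test are *tail-calibrated* rather than exactly
uniform: being discrete and doubled-tail, they carry an atom at 1
(~5–10% mass) and are mildly conservative, with P(p ≤ α)/α ≈ 0.8–0.95
across α ∈ [10⁻³, 0.5] at realistic coverage. The extreme-value
calibration below depends only on this small-p behavior.

## Scores, segments, significance

Tested positions are scored *s<sub>i</sub>* = ln(0.1) −
ln(pval<sub>i</sub>); positions failing the abundance threshold score
exactly −10. Zero p-values (numerically possible at extreme counts)
are clamped to the smallest positive double with a warning.

All disjoint maximal-scoring segments of the per-transcript score track
are found with the **Ruzzo–Tompa** algorithm; the single best segment
is the Kadane maximal-subarray answer and is available as a mode. A
segment is reported with minimal extent under score ties (it never
starts or ends on a non-positive score); ties between disjoint segments
rank leftmost-first, then shortest. Penalized (−10) positions can sit
inside a segment when the flanking scores more than pay for them.
Transcripts are searched independently; segments never span transcript
boundaries.

Segment significance uses Karlin–Altschul statistics,
E<sub>v</sub> = K e<sup>−λS</sup>:

* λ solves Σ p<sub>i</sub> e<sup>λs<sub>i</sub></sup> = 1 under the
  U(0,1) null, i.e. 0.1<sup>λ</sup>/(1 − λ) = 1, by Brent's method on
  [0.5, 0.999999] (the interior root; x = 0 is trivial). λ = 0.862871…
* K equals the prefactor C\* in the dense-score-lattice limit (the
  lower/upper lattice bounds K⁻, K⁺ coincide as the score span δ → 0).
  With S<sub>k</sub> = k ln(0.1) + X<sub>k</sub>, X<sub>k</sub> ~
  Γ(k, 1):

  C\* = exp(−2 Σ<sub>k≥1</sub> (1/k)·[E(e<sup>λS<sub>k</sub></sup>;
  S<sub>k</sub> < 0) + P(S<sub>k</sub> ≥ 0)]) / (λ E(S₁e<sup>λS₁</sup>)),

  where the denominator has the closed form
  λ·0.1<sup>λ</sup>·(1 − (λ−1)ln 0.1)/(λ−1)².

  Because 0.1<sup>λ</sup>/(1 − λ) = 1 at the root, the truncated
  expectation reduces **exactly** to a regularized lower incomplete
  gamma, E(e<sup>λS<sub>k</sub></sup>; S<sub>k</sub> < 0) =
  P(k, (1 − λ)·k·ln 10), and P(S<sub>k</sub> ≥ 0) = Q(k, k·ln 10).
  The default evaluation uses these closed forms; adaptive
  Gauss–Kronrod quadrature of the original gamma integrals (log-space
  integrand to avoid overflow at large k) is retained as a cross-check
  and agrees to ~10⁻¹⁰. Both series terms decay geometrically; the
  series is truncated at k_max = 200 with a 10⁻¹² term tolerance and
  fails loudly if the last term is above tolerance. C\* = K =
  0.0809635…

The default E-value is the plain K e<sup>−λS</sup>; an optional mode
scales by the number of searched positions (K·N·e<sup>−λS</sup>, the
standard search-space scaling). We do not silently pick one: the plain
form is the package default and length scaling sits behind a flag,
because the two differ materially only in how strict the E-filter is.
The penalty score (−10) is excluded from the null score model — the
derivation assumes only tested positions — and shapes segment
boundaries only.

A Monte-Carlo verifier (`calibrate_null`) simulates uniform-p tracks,
scores and segments them, and compares observed counts of segments
above score thresholds with K·N·e<sup>−λS</sup>; at N = 10⁶ the
observed counts sit within ~10–20% of prediction and the log-survival
tail slope of segment scores is within a few percent of −λ. Note that
a naive Monte-Carlo check of the denominator λE(S₁e<sup>λS₁</sup>) is
*not* valid: S₁e<sup>λS₁</sup> has tail index 1/λ ≈ 1.16 < 2 and hence
infinite variance, so sample-standard-error bounds do not apply; the
test suite verifies it by numeric quadrature instead.

## Call filters

A segment becomes a candidate when it passes all of: E<sub>v</sub> ≤ 10
(inclusive by default; a flag switches to strict), at least one
position with |log₂FC| > 1 (fold-change > 2), at least one position
with relative abundance above the transcript median + SD, and minimum
Bonferroni-corrected p < 10. The Bonferroni factor is the number of
abundance-passing tested positions in the analysis; the corrected value
is uncapped and compared to the threshold as stated. Relative
abundance per position is the mean normalized count over all samples;
the transcript median and SD are computed over nonzero-coverage
positions only, so untranscribed tails do not deflate the SD. All
segments are retained in the output with per-filter flags; `called`
marks the all-pass rows. A multi-position call's region class is the
majority vote of its per-position classes after the 5′UTR > CDS/operon
> 3′UTR precedence; calls with no annotated position are
"unannotated".

A structural property of these thresholds is worth knowing: under a
calibrated uniform null, the expected number of positions passing the
Bonferroni filter is *exactly* the threshold (10) regardless of problem
size, each such position is its own positive segment, and the unscaled
E-value filter cannot exclude it (K e<sup>−λS</sup> ≤ K ≈ 0.081 < 10
for every positive segment) while a significant position almost always
also exceeds the fold-change cutoff. Only the relative-abundance
filter (~0.1 pass rate) thins these singles, so roughly one
single-position false candidate per null comparison is expected — the
control-vs-control specificity test in the acceptance suite documents
this honestly and fails the stricter zero-call expectation. On real
sparse libraries the discrete exact test is substantially more
conservative at small p, which suppresses such singles; with the
length-scaled E-value mode and genome-scale search spaces the E-filter
additionally removes single-position segments. Users wanting strict
null behavior should lower the Bonferroni threshold or enable length
scaling.

## Synthetic data generator

The generator emulates the data model the statistics assume: NB counts
(gamma–Poisson, exact Poisson at φ = 0) around per-position baseline
means shared by all libraries, with a log-normal transcript-level
expression factor (σ = 0.75 by default) times log-normal position-level
cleavage preference (median 5 counts/sample, σ = 1), four conditions
(TPP/FMN/SAM/control) in duplicate, and φ = 0.1. Implanted windows
multiply the mean of the affected condition only (multipliers < 1 model
structure loss); a window may pin its baseline mean to a fixed value so
power conditions are exact. Randomness uses the counter-based Philox
generator keyed by (seed, transcript index): any transcript regenerates
in isolation and results are independent of generation order.

What the generator does **not** emulate: sequence-dependent cleavage
and mapping biases, correlated neighboring positions, read-level errors
or adapter artifacts, between-replicate batch effects, and the extreme
sparsity of real libraries (most real positions sit near the detection
limit, where the exact test is much more conservative). Passing tests
on this generator therefore demonstrate correctness of the statistics
under their own assumptions, not field performance on real probing
data.

Fixture SAM files invert the counting rule (a count at p becomes a read
at p + 1, samples encoded as read groups) and round-trip exactly
through the counter.

## Problem sizes used in the test suite

Calibration uses 1000 null transcripts of 1000 nt (10⁶ positions);
dispersion recovery uses 2000 positions × 4 replicates; the end-to-end
experiments use 3–5 transcripts of 300 nt across 50–100 seeds with
30-nt, 4-fold windows at baseline mean 20, chosen as the smallest sizes
at which the measured quantities are stable.

## Known limitations

* Common dispersion only; strong per-position variance heterogeneity
  will miscalibrate the exact test.
* One-vs-rest pooling means a window implanted in condition A also
  perturbs the "rest" pool of every other contrast (diluted ~(k−1)-fold
  with k conditions); signals are attributed to the contrast where they
  score highest.
* The U(0,1) null for λ and K is an approximation to the discrete,
  mildly conservative exact-test p-values; measured calibration error
  of the extreme-value law is within ~20% at desk scale.
* Paired-end data, overlapping gene models, and genome-coordinate
  searches with strand resolution are out of scope; counting happens in
  whatever reference space the alignments use.
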