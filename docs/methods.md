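# Methods

## Scope and data model

`mirflow` analyses mature-miRNA abundance across an ordered three-state
differentiation design (by default hESC → self-renewing NSC →
differentiating NSC, with 3/8/6 replicates). The in-memory objects are a
`CountMatrix` (miRNA × sample integers plus a sample sheet), a
`NormalizedMatrix` (counts over size factors), per-contrast DE tables, and
per-miRNA trajectory calls. All coordinates are 1-based inclusive (GFF3
convention); any half-open arithmetic converts at the boundary.

## Read preprocessing

Filters run in a fixed order and are not commutative; the pipeline does not
offer reordering:

1. **Adapter trimming.** The read is truncated at the leftmost position
   where the (known) 3′ adapter matches with at most 1 mismatch over at
   least 6 nt of overlap. Reads with no adapter evidence are discarded
   (`no_adapter`): in this protocol an insert shorter than the read length
   guarantees read-through into the adapter, so a missing adapter indicates
   a failed ligation or a non-miRNA insert. The adapter is supplied
   explicitly (default: the NEB small-RNA kit 3′ adapter); an optional
   k-mer over-representation scan (`infer_adapter`, most frequent 12-mer in
   the 3′ halves of the first 10,000 reads) is provided as a clearly
   labelled heuristic fallback.
2. **End trimming.** Bases with Phred < 5 are stripped from both ends
   inward until a base ≥ 5.
3. **Quality rule.** The read fails unless ≥ 85% of remaining bases have
   Phred ≥ 10.
4. **Length window.** 16–27 nt inclusive, the mature-miRNA size range.

Assignment matches the surviving read ungapped and end-to-end within each
mature sequence and each contaminant sequence (minimum Hamming distance
over all placements; the read must fit inside the reference). A read is
`contaminant_excluded` only when a contaminant matches with *strictly*
fewer mismatches than the best miRNA — a tie stays with the miRNA, since
exclusion is warranted only by positive evidence that the contaminant
explains the read better. Defaults: `max_mismatches = 1` (exposed in
config, as aligner mismatch allowances vary), fractional 1/k weights for
equally good multi-mapping hits (a "first-best" mode exists), matrix cells
rounded half-even to integers after summation. Phred+33 is assumed;
qualities decoding above Q41 abort with a Phred+64 diagnosis. There is no
genome alignment: matching is against the mature + contaminant sets only,
which suffices for quantification and keeps the tool dependency-free.

## Normalization, filtering, differential expression

Size factors are median-of-ratios over miRNAs with positive counts in all
samples, rescaled so their geometric mean is exactly 1. A consequence of
the geometric-mean anchor is that scaling one sample's counts rescales
*all* size factors by a common constant; cross-sample structure of
normalized counts is what is invariant.

The abundance filter keeps a miRNA when some cell type has normalized
counts strictly above 50 in at least two of its samples. Both thresholds
are configurable; a cell type with fewer than two samples is warned about
and cannot qualify miRNAs on its own.

The NB Wald test per contrast (a, b):

- group means `μ̂_g = Σ_j K_ij / Σ_j s_j` (size-factor-weighted means of raw
  counts);
- per-miRNA dispersion: pooled within-group method-of-moments on
  normalized counts, solving `pooled residual variance = μ + αμ²` with
  (n_g − 1) weights, floored at 1e-8;
- a mean–dispersion trend `α(μ) = a₀/μ + a₁` fitted by least squares over
  all tested miRNAs;
- the working dispersion is the 50/50 average of the per-miRNA estimate and
  the trend, **floored at the trend**. The floor is deliberate: with 3–8
  replicates the per-miRNA moment estimate has ~4–12 degrees of freedom,
  and letting it pull the shrunk value below the trend makes the
  normal-reference Wald test anticonservative (measured null false-positive
  rates of 6–8% at nominal 5% without the floor, 4–5% with it). Treating
  the trend as a per-gene lower bound is the classic conservative choice
  for small-replicate NB testing;
- `log2FC = log2((μ̂_b + ½)/(μ̂_a + ½))` — the ½ pseudo-mean avoids
  infinities; no posterior fold-change shrinkage is applied;
- delta-method SE: `Var(μ̂_g) = Σ_j (s_j μ + α s_j² μ²) / (Σ_j s_j)²`
  propagated through the log, two-sided normal p-value, and
  Benjamini–Hochberg adjustment within the contrast over the
  filter-retained universe only.

This is one fully specified test, not a re-implementation of any external
tool's numerics; agreement with DESeq2/edgeR point estimates is a non-goal.
Covariate GLMs, outlier handling and independent-filtering optimisation are
out of scope.

## Trajectory groups

Transition calls use strict inequalities exactly as thresholded
(`padj < 0.05`, `log2FC > +0.6` / `< −0.6`); a large fold change without
significance is STABLE. The (state1, state2) → group mapping is data (a TSV
can replace the default) and must be injective over the eight non-stable
pairs. The default mapping encodes: G1/G2 change only at the first
transition and revert (NSC-specific), G3–G6 change during differentiation,
G7/G8 are stem-stable and change only at terminal differentiation. Top-N
rankings order significant miRNAs of one sign by ascending padj, ties by
|log2FC| descending then name — note ranking requires significance and sign
only, while grouping additionally requires |log2FC| > 0.6; both behaviours
are intentional. Doubling time is `Δt·ln 2 / ln(N_end/N_start)` over a 48-h
window.

## Clusters, families, contributions

Clusters are derived by single-linkage over same-chromosome, same-strand
loci with inter-locus gaps ≤ 10 kb (the common convention for polycistronic
miRNA clusters); cluster membership can instead be read from a user TSV,
which takes precedence when supplied. A mature mapping to several loci
joins every locus for clustering but is kept only in the cluster of its
leftmost locus if those disagree (warning emitted), so each mature has at
most one cluster; it counts once in contribution analysis regardless.

The contribution of a unit (cluster or family) in a cell type is the
unit members' share of the type's total normalized reads, aggregating each
type by the **mean** over its replicates (invariant to replicate number;
sums would weight types by their sample counts). The denominator is the
filter-retained universe, matching the post-filter analysis; a flag could
widen it to all detected miRNAs. Diversity is summarised as the effective
number of units, `exp(Shannon entropy)` of the non-zero unit fractions,
with the unassigned pool counting as one unit.

## Synthetic data

The generator emulates the study conditions: 3/8/6 replicates; NB counts
with `variance = μ + αμ²`; baseline means log-normal(log μ₀, σ = 1) around
μ₀ = 500 to emulate a realistic abundance spectrum; planted trajectory
groups at ±2 log2-fold per changing transition; planted cluster-dominance
fractions implemented by rescaling member means and renormalizing
non-members so the type total is preserved in expectation (the planted
fraction is exact in expectation conditional on the drawn baselines). Raw
reads are insert + adapter + random filler to 75 nt (75-cycle run), with
per-base errors at 0.001, 10% contaminant reads, and two-state qualities
(high ≈ Q34, low = Q6, end defects at Q2) so every filter is exercised;
defect fractions are configurable. All randomness flows from one integer
seed through a counter-based generator — no hash-order dependence — so
equal seeds give bit-identical outputs.

Not emulated: ligation/sequence bias, UMIs, isomiRs, batch effects, and
library-size heterogeneity beyond size-factor scale. Passing tests on this
generator therefore demonstrate correctness of the algorithms under the
stated model, not robustness to those real-data artefacts.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 1,500 reads for the
preprocessing oracle comparison, 2,000 miRNAs for null calibration, 500
miRNAs (320 planted) for trajectory recovery, and 35 miRNAs for
cluster-fraction recovery — sizes at which the binomial/NB sampling error
of each check is far smaller than its tolerance while the whole suite runs
in seconds. Ties in adapter search resolve leftmost; equally good miRNA
hits split evenly; BH uses the standard step-up running minimum; all-zero
miRNAs in a contrast get `log2FC = 0, p = 1`. Dispersion floor 1e-8 guards
degenerate exact-equal replicates.

## Known limitations

- The NB test's normal reference is approximate at n = 3; calibration is
  enforced empirically (null simulations) rather than by a t-correction.
- Median-of-ratios normalization assumes most miRNAs are stable; heavily
  asymmetric differential expression (a large one-directional fraction)
  biases size factors and hence fold changes, as with any global-scaling
  method.
- The packaged locus fixture uses approximate hg38 coordinates; analyses
  needing exact coordinates should supply a real GFF3.
- No isomiR or novel-miRNA discovery; quantification is against the given
  mature catalogue.
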