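# Methods

This note documents the models, parameter choices, and numerical decisions
behind `cnax`, in the order the pipeline runs them.

## Segmentation (CBS)

Each chromosome of each sample is segmented independently by circular
binary segmentation: the current segment is treated as a circle, and the
arc whose mean most differs from its complement is the candidate change
point. The arc statistic is the **between-segment sum of squares**,
n₁n₂/n · (m₁ − m₂)² — the squared two-sample t with the segment-wide
variance as a constant scale. Its argmax is exactly the split minimizing
within-segment SSE, which makes the exhaustive-search oracle in the test
suite an identity rather than an approximation. We deliberately did not
use a per-arm (Welch) variance: on clean planted signals a short arc with
incidentally tiny within-arc variance gets an inflated Welch t, misplacing
the boundary of an otherwise obvious segment (observed in development: a
10-probe gain at +1.5 split as a 6-probe arc, stranding 4 probes below the
width floor).

A split is accepted when its permutation p-value, computed by permuting
the probe values within the segment and re-maximizing the statistic, is
below `alpha` (default 0.01), and every resulting linear piece keeps at
least `min_width = 5` probes (candidate arcs that would strand a shorter
edge piece are excluded up front, so emitted segments never fall below
the floor). Accepted splits recurse until nothing more is significant.

Numerical details:

* p = (1 + #{perm ≥ observed}) / (1 + n_perm), default n_perm = 10,000.
  The heavy synthetic runs use n_perm = 128: the smallest attainable p is
  then 1/129 ≈ 0.0078 < alpha, so clearly significant splits are still
  accepted, and permutations for a segment are abandoned early as soon as
  enough exceedances accumulate to make p ≥ alpha certain — the
  accept/reject decision is identical to running all permutations.
* The permutation stream of a segment is seeded from (run seed,
  chromosome index, segment bounds), so decisions are independent of
  recursion history; this also makes the number of accepted splits
  monotone in alpha for a fixed seed, a property the suite asserts.
* Ties in the arc statistic break toward the smaller start index, then
  the shorter arc: output is fully deterministic.
* Chromosomes with fewer than `min_width` probes are returned whole,
  flagged "too short to split".
* The scan over all admissible arcs is O(n²) per evaluation and runs as a
  numba kernel over cached candidate-index arrays.

Segments are summarized by their probe-mean log2 ratio, assigned back to
every member probe ("smoothed" values). X/Y exclusion is an input-level
concern: the synthetic genome contains autosomes only, and real input is
expected pre-filtered (the readers enforce sorted autosomal tracks).

## CNA calling and genome patterns

States come from two strict thresholds on |smoothed|: > 0.5 → ±1 (gain /
loss), > 1.0 → ±2 (amplification / deletion). Homozygous deletions are
reported as −2 (no deeper threshold is defined under a modal diploid
assumption). Alteration burden is the percentage of non-neutral probes.

The qualitative genome-pattern classes are reproduced with a declared,
configurable rule (the literature describes them verbally): *complex
firestorm* if some chromosome carries ≥ 2 high-level segments within
20 Mb (a clustered amplicon); otherwise *complex sawtooth* if the profile
has ≥ 40 altered segments or ≥ 20% altered probes; otherwise *simplex*.
The rule is invariant to chromosome relabeling and is tested against its
own definition.

## Recurrence scoring

Per probe and direction, score = f × ā with f the fraction of samples
altered in that direction and ā the mean |smoothed| among them. The null
preserves each sample's alteration burden while destroying locus
recurrence: per iteration every sample's (state, amplitude) pairs are
permuted across probe positions independently; null scores are pooled
across probes and iterations, and p = (1 + #null ≥ obs) / (1 + N) with an
add-one correction (an exhaustive mode enumerating all per-sample
permutations exists for tiny instances and drops the correction).
Contiguous significant probes (p < 0.05) merge into regions within
chromosomes. A gene counts as altered if any of its probes is; its
recurrence frequency is the max over member probes.

A pooled permutation null is anti-conservative on extremely sparse
burdens (a probe altered in a single sample can reach p < 0.05 simply
because most null entries are zero); the null-control tests therefore
distinguish the stated "pure-noise" condition (no events at all) from a
sparse-background condition, which is checked against alpha with an
explicit tolerance.

## Differential screen and exact tests

Per gene and level (gain/amp/loss/del), a 2×2 Fisher exact test compares
altered vs not between groups; genes altered in fewer than 2 samples are
excluded before testing; BH-FDR is applied across tested genes per level
and results kept at q < 0.05. Fisher is two-sided by the probability-mass
criterion; r×c tables (grade, subtype, genome pattern) use the
Freeman–Halton extension computed by exact enumeration of all tables with
the observed margins in log-gamma space — adequate for clinical-annotation
table sizes, and cross-checked in the suite against enumeration oracles
and reference values from an independent implementation. Continuous
annotations use the two-sided Mann–Whitney test.

## Integration

Expression probe sets collapse to genes preferring bare `_at` ids, then
`s_at`, then everything else, breaking ties by highest median expression
(then id order). Over/underexpression calls compare each sample to the
normal-pool reference at ±1 log2 (twice / half the pool level, boundary
inclusive).

Candidates must already be differential genes, then pass all of:
(i) Fisher p < 0.05 on combined-event (state ≥ +1 AND overexpressed for
gains; ≤ −1 AND underexpressed for losses) vs group; (ii) dosage
association — Student (equal-variance) t of expression between altered
and unaltered samples over the full cohort, BH q < 0.05 across tested
genes, sign-concordant; genes altered in < 2 samples or in all samples
are skipped with a recorded reason; (iii) Student t of expression between
groups, p < 0.05, sign-concordant. Criteria (i) and (iii) use raw p
(FDR is stated only for the frequency screen and the dosage test);
the dosage test is joint over both groups. Both directions are screened
even though gains dominate the planted truth. The cutoffs are parameters;
tightening any of them can only shrink the candidate list.

## Classifier

The signature is a maximum-likelihood logistic regression on candidate
gene log2 expression with an optional ridge penalty on the gene
coefficients (default 1e-3; 0 reproduces the plain ML fit). The penalty
exists because dosage-coupled candidates often separate synthetic cohorts
perfectly, where the unpenalized likelihood has no finite maximizer;
perfect separation at ridge 0 is detected, warned about, and coefficients
are capped at |30|. Scores are affine in expression; class = "IBC-like"
iff score > 0, exactly at the threshold 0 convention. LOOCV refits the
model n times. External application first collapses probes per gene by
highest within-dataset variance, requires ≥ 70% of model genes to map,
and otherwise classifies on the mapped subset with a warning.

## Survival

Kaplan–Meier estimation, Greenwood confidence bands, the two-group
log-rank test, and Cox regression are delegated to lifelines (Efron tie
handling, Wald tests); `cnax.survival` fixes the conventions: times in
months, 5-year read-outs at exactly 60 months (flagged when follow-up
ends earlier), complete-case exclusion for missing covariates, and a
hard error when no events remain.

## Synthetic cohorts

The generator emulates the analysis inputs, not raw microarray physics
(no probe-level intensity or two-color channel simulation). Per sample:

* genome = Σ planted amplitudes (carriers drawn per group with freq_a /
  freq_b) + background segments (Poisson per chromosome, uniform
  breakpoints, amplitudes N(0, 0.3) truncated to |a| < 0.5 so they stay
  below the call threshold) + i.i.d. N(0, probe_noise_sd);
* expression_g = baseline_g (+ dosage_slope × amplitude for carriers of
  coupled genes) + N(0, expression_noise_sd); the normal pool is the
  noise-free baseline vector; baselines sit at log2(floor_offset) = 8 ±
  1 so only a small tail of genes is removed by the 100-unit floor;
* annotations (grade, ER, ERBB2, P53, subtype) follow group-conditional
  frequencies modeled on the published two-group clinical table;
* survival is exponential with hazard h₀·exp(log-HR · [group A]) and
  uniform censoring.

Reference conditions (`default_cohort_config`): 49 + 124 samples, 15
chromosomes × 200 probes at 0.5 Mb spacing (3,000 probes — a deliberately
desk-scale genome; the probe count sets only resolution, not the
statistical structure), 5,000 genes, probe noise 0.15, expression noise
0.4, dosage slope 1.1, and 24 planted group-A dosage-coupled gains in 8
regions (amplitudes alternating 0.9 and 1.5, carrier frequencies
0.55 vs 0.04) plus two group-shared gains and one group-B loss that the
screens must reject. Effect sizes were fixed a priori by power analysis:
at 49/124 samples a 0.9-amplitude gain with slope 1.1 gives a combined
gain+overexpression frequency near 0.27 vs 0.02, putting each of the
three criteria far from its threshold while leaving the uncoupled and
shared events comfortably non-significant.

What passing recovery tests on these cohorts does *not* show: robustness
to normal-cell contamination, ploidy shifts, GC/wave artifacts,
platform-specific probe effects, or non-exponential survival — none of
which the generator emulates.

## Known limitations

* No "undo splits" pruning pass after CBS and no smoothing/outlier
  trimming before it; segmentation operates on raw log2 ratios.
* No peel-off or arm-vs-focal decomposition in the recurrence scorer; the
  score is the declared f × ā.
* Freeman–Halton by full enumeration is for small tables (annotation
  screens), not genome-scale r×c testing.
* Bootstrap cluster support uses plain gene-resampling co-membership
  (exact member-set recurrence at the same k), not multiscale bootstrap
  AU p-values; the 90% robustness threshold is kept for interface parity.
* The nearest-centroid subtype assigner ships no centroid table; centroids
  are user input (tests use generated ones).
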