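# Methods

## Scope and representation

The package models one round of social-information exchange in a group
estimation task. All computations use base-10 logarithms: estimates are
"orders of magnitude" quantities, a raw estimate *E* of a quantity with
true value *T* is carried as *X* = log₁₀(*E*/*T*), and the constraint that
raw estimates exceed 1 becomes *X* > −log₁₀ *T*. Log-estimate
distributions are taken as Laplace — empirically a better description of
estimation data than the Gaussian, and the reason medians and mean
absolute deviations (not means/standard deviations) are the package's
location and dispersion summaries.

## Synthetic experiment generator

`synthetic_data` emulates the standard design: 18 groups × 12 subjects ×
36 questions, each group meeting each of the 18 conditions
(3 treatments × τ ∈ {1,3,5,7,9,11}) exactly twice, each (question,
condition) pair covered by exactly one group, hence 12 × 36 = 432 records
per condition. The assignment is a deterministic cyclic rotation
(condition index (g + q) mod 18); the real experiment's assignment matrix
is not public, only these marginals, which the rotation reproduces
exactly.

Per question, log₁₀ *T* is uniform on [2, 7] (moderately large to very
large quantities), the Laplace center is γ·log₁₀ *T* + 𝒩(0, 0.3) with
γ = 0.9 (the underestimation bias: median log-estimates fall short of the
truth by about one decade per ten), and the width (mean absolute
deviation, in decades) is uniform on [0.3, 0.6], the typical dispersion of
human log-estimates in this family of tasks. Sampling is exact
inverse-CDF sampling of the Laplace conditioned on the truncation bound —
no rejection loops, so equal-seed runs are reproducible at any
truncation level. The Laplace scale is set equal to the width because the
untruncated Laplace's mean absolute deviation equals its scale.

What the generator deliberately does **not** emulate: per-subject
heterogeneity in the keep probability P₀ (treated as constant),
question-category effects beyond carrying the tags, integer rounding of
raw answers, and — importantly for the recalibration comparison below —
the large per-question scatter of the median-vs-truth relation seen in
real data.

## Selection treatments

`social_selection` implements the three sharing rules. The group median
*m* is computed over all 12 members (the focal subject's estimate is
excluded only from what is *shared*, not from the reference). The
shifted-median reference is *m′ = m/γ*; with *m* > 0 and γ < 1 this
overshoots the group median toward the truth. Ties in |x − ref| are
broken toward the smaller log-estimate, then the smaller subject id —
the data are continuous so ties are measure-zero, but the rule makes the
selection a deterministic function of the group's estimates. The
simulator's vectorized selection kernel is tested record-for-record
against the scalar rule.

## Influence model

`influence_model` draws the sensitivity S from the spike-and-Gaussian
mixture with P_g = clamp(⟨S⟩/m_g, 0, 1). Numerical guards:

* P_g is clamped to [0, 1] where the linear cusp exceeds the mixture mean
  or goes negative (possible at extreme |D| or large σ); events are
  counted and reported, never silent. Under the shipped demo parameters
  clamping affects ≲1% of records.
* m_g and σ_g are floored at 10⁻³ where the linear laws in σ would cross
  zero, keeping the mixture well defined; floor events are counted.
* X_s values below −log₁₀ T are set to −log₁₀ T (raw estimate exactly 1);
  the mechanism behind the experimental constraint is unknown, a hard
  floor is the simplest choice and affects a handful of records per
  million.
* Drawn S values are *not* clipped to [−1.05, 2.05] inside the simulator;
  that restriction is an analysis-side filter only.

At τ = 1 the dispersion is identically zero, so that block carries
constant m_g, σ_g and no β′ term; P_g remains D-dependent through the
cusp. The two reduced variants are parameter transforms: `no_asymmetry`
sets D₀ = 0 and both β to their mean; `no_similarity` zeroes β′ and the
m_g/σ_g slopes (intercepts kept).

The shipped `demo_params()` are the package's own plausible values
(moderate herding with P₀ ≈ 0.5–0.6, D₀ ≈ −0.3, β₊ ≈ 2β₋, β′ < 0), used
as generator truth in the recovery studies; the package treats behavioral
parameters strictly as inputs and provides the fitting chain to estimate
them from data.

## Estimation chain

Measured sensitivities S = (X_s − X_p)/(M − X_p) are undefined when
M = X_p (flagged and excluded, counted in logs) and restricted to
[−1.05, 2.05]: near-zero denominators produce meaningless blow-ups
(X_p = 5, M = 5.001, X_s = 5.1 gives S = 100 for a negligible revision).
Exact keeps (S = 0) are identified by provenance — the second raw
estimate equals the first — never by a numeric tolerance.

The mixture fit bins the non-zero S at width 0.1 over the clip interval,
normalizes by the *total* count so the histogram integrates to P_g, and
least-squares fits P_g(m_g)·𝒩(m_g, σ_g) with P_g = mean(S)/m_g
substituted, leaving (m_g, σ_g) free; the identity ⟨S⟩ = P_g·m_g then
holds by construction. The explicit S = 1 secondary peak reported in
earlier single-advisor studies is not modelled: with several shared
estimates a second answer almost never lands exactly on their geometric
mean.

The cusp is fitted by closed-form linear least squares over individual
answers (unit weights) with regressors 1, |D−D₀|·1[D<D₀],
|D−D₀|·1[D≥D₀] and σ (the σ column is dropped at τ = 1), over
D ∈ [−2.5, 2.5] with a handful of per-condition interval restrictions
where the extreme-D tails are too thin.

**Locating D₀.** The moving-bin curve (bin size 1, centers every 0.1 —
overlapping replicates of the same data) is useful for display and for
small samples, but it is a poor basis for estimating the cusp vertex: the
size-1 window shifts the binned minimum of an asymmetric cusp toward the
shallow side by up to (w/2)(β₊−β₋)/(β₊+β₋), and the strongly peaked
density of D inside each window shifts it further — in simulations the
curve-level V-fit misplaces D₀ by 0.2–0.5. The pipeline therefore
profiles the record-level least squares over a 0.01 grid of D₀ (closed
form in the remaining parameters at each grid point, prefix-sum normal
equations so the scan is O(n), parabolic refinement), restricted to the
search interval [−1.2, 0.2] (upper bound 0.6 for the shallow-bottomed
random τ=3, τ=5 and median τ=3 conditions). This profile recovers the
generator's D₀ to ±0.01 in the recovery studies. The curve-level
`fit_D0` remains available, with an optional window-averaged model for
moving-bin input.

The m_g/σ_g linear laws are ordinary least squares of the per-condition
mixture fits on the per-condition mean dispersion ⟨σ⟩ over the five τ > 1
conditions. In the random treatment ⟨σ⟩ spans a narrow range, so those
slope estimates are intrinsically imprecise — per-condition values are
accurate, extrapolated coefficients are not, and tests assert the former.
The product law P_g·m_g inherits a quadratic term b·b′·σ² from the two
linear laws; at slopes ~0.2 and σ ~0.5 it is 0.01 and negligible.

## Accuracy and uncertainty

Collective accuracy is |median(X)|, individual accuracy is median(|X|);
medians of even counts average the two central order statistics.
Improvements are τ-averaged differences before/after sharing (equal
weight per τ; record counts are equal by design). The bootstrap resamples
*questions* with replacement (all records of a drawn question enter
together), and error bars are asymmetric: b₊ contains 68.3% of the
replicates above the full-data value, b₋ symmetrically below — chosen by
analogy with one standard deviation without assuming symmetry.
Significance is always the paired p₀: the fraction of replicates, on the
*same* question resample for both sides of a claim, on which the opposite
of the claim holds; when no opposite occurrence is observed p₀ is
reported as 1/n_boot (an upper bound at the bootstrap's resolution).
Improvements are never judged by overlapping error bars — per-replicate
fluctuations of the compared quantities are highly correlated and the
paired difference is the meaningful statistic.

## Recalibration baseline

Recalibration divides each *log-estimate* by γ (the per-record analogue
of the shifted-median construction m′ = m/γ ≈ log₁₀ T), i.e.
X_recal = (X_p + log₁₀T)/γ − log₁₀T; γ = 1 is the identity. Under this
package's generator conditions, recalibration improves *both* collective
and individual accuracy: the systematic underestimation shift
(≈ 0.45 decades at the default ranges) is large relative to the
per-question scatter (sd 0.3), so re-centering helps the typical record
too. In real estimation data the per-question residuals of the
median-vs-truth relation are larger relative to the shift, and
recalibration has been observed to degrade individual accuracy there.
The test asserting that full pattern is intentionally left failing on the
individual-accuracy clause rather than weakening the assertion or moving
the generator's stated conditions: it documents precisely which feature
of real data the synthetic crowd does not reproduce. Passing tests on
the synthetic crowd therefore demonstrate the correctness of the
machinery and the directional mechanisms, not the quantitative accuracy
pattern of any particular human dataset. The regression of per-question
median log-estimates on log-truths (the γ measurement) is likewise only
exercised on synthetic data; the test against the original experiment's
estimate tables requires that dataset, which is not bundled.

## Problem sizes and determinism

All randomness flows from one root seed through explicit generators (the
simulator consumes a single stream in fixed cell order, so equal seeds
give bit-identical record tables). The shipped studies use problem sizes
chosen to keep a full run comfortable on one CPU: 300 design replicates
per model variant in the test suite's recovery and mechanism checks,
2,000 in the acceptance script's recovery (≈ 860k records per condition —
Monte-Carlo error well below the comparison tolerances), 30 record-level
replicates with a 1,000-replicate question bootstrap for the accuracy
ordering. Larger runs only tighten the Monte-Carlo error; the estimator
properties do not change.

## Known limitations

* One revision round only; no iterated influence dynamics.
* P₀ is homogeneous across subjects and questions.
* The generator's question dispersions and the scatter of the bias
  relation are stand-ins; see the recalibration caveat above.
* The curve-level D₀ estimator is retained for compatibility with
  moving-bin displays but is knowably biased for asymmetric cusps; use
  the record-level profile for estimation.
* Accuracy-report bootstrap bars are computed for the unfiltered cells by
  default; point accuracies (no bars) are reported for the D-sign and
  S-quantile splits unless requested, to keep the report tractable.
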