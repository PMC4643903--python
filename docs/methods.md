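# Methods

## The estimation model

Estimates of positive quantities are treated in the log domain,
`y = log x` (natural logarithm throughout; the base cancels in the social
weight and in z-scores but must be consistent).  Before social influence a
group's log estimates are modelled as Gaussian, N(μp, σp), i.e. raw
estimates are log-normal.  The social signal shown to subjects is the
geometric mean of the group's first estimates under the full-information
condition and the arithmetic mean under the aggregated-information
condition; in both cases the model works with its logarithm μs.

Each individual revises by a linear combination in the log domain,
`y₂ = (1-ws)·y₁ + ws·μs`, equivalently a weighted geometric mean in the raw
domain.  The social weight `ws` is the individual's behavioural trait of
interest: 0 means the subject kept their private estimate, 1 means they
adopted the signal, and values outside [0, 1] (overshoot or contrarian
moves) occur and are retained.  The per-individual inversion
`ws = (y₂-y₁)/(μs-y₁)` is undefined when the private estimate coincides
with the signal; the implementation flags subjects with |μs - y₁| ≤ 1e-8
as undefined, excludes them from weight-based analyses, and counts them in
the pipeline report.

At the population level the post-influence distribution is
N((1-ws)μp + ws·μs, σp·√(1-ws)).  For a geometric-mean signal
μs ≈ μp (the sample geometric mean of log-normal data estimates the
median), so only the SD changes; for an arithmetic-mean signal
μs ≈ μp + σp²/2, so the mean also shifts by ws·σp²/2.  On z-scores
standardized per experiment with *round-1* μp and σp, the predictions are
N(0, √(1-ws)) and N(ws·σp/2, √(1-ws)).

### Reconciling the individual rule with the population prediction

The deterministic update alone contracts every deviation by (1-ws), which
would shrink the pooled z-SD by (1-ws), not √(1-ws).  The two levels are
consistent once the second estimate carries log-domain noise around the
deterministic rule: with noise SD σp·√(ws(1-ws)),
Var(z₂) = (1-ws)² + ws(1-ws) = 1-ws.  The synthetic generator exposes this
value as `model_consistent_noise_sd(sigma_p, ws)`; distribution-level
simulation checks use it, while identifiability checks (exact recovery of
ws) set the update noise to zero.  An equivalent mechanism is weight
heterogeneity — e.g. ws ∈ {0, 1} with mean w̄ also gives Var ratio 1-w̄ —
which is in fact the shape real weight distributions take (peaks at 0 and
1); the noise term is the single-knob idealization.

A z-SD fitted from data inverts the prediction: `ws = 1 - sd(z₂)²`.  At
the value fitted from real full-information data, ws = 0.53, the predicted
SD ratio is √(1-0.53) = 0.6856.

## The ω-sweep and the resist estimators

Subjects are removed from highest to lowest |ws|; the subgroup at
threshold ω is everyone with |ws| ≤ ω, so the sweep visits each observed
distinct |ws| value and the subgroups are nested.  No interpolation is
done between observed values: the subgroup geometric mean and its p-value
are step functions of ω.

Each subgroup of size k is scored against the whole crowd's geometric mean
(WOC) by resampling: draw size-k subsets without replacement
(10⁵ by default) and report the fraction whose geometric mean lies at
least as far from the WOC as the subgroup's.  Distance is measured on the
log scale, making the test symmetric under reciprocal units.  Ties count
toward the tail, so p is never 0 and the whole crowd always has p = 1.

With q(ω) = 0.05 - p(ω) when p(ω) < 0.05 and 0 otherwise, the three
aggregators over ω ∈ [0, 0.5] (the ceiling is configurable) are

* resist 1 = ∫q(ω)·gm(ω)dω / ∫q(ω)dω, computed exactly by
  piecewise-constant integration over the sweep steps;
* resist 2 = the same with q replaced by the indicator p < 0.05;
* resist 3 = gm at the single ω with minimal p (ties broken toward the
  larger subgroup, which carries more data).

All three are undefined — reported as absent, not as a number — when no ω
in range reaches p < 0.05.  No multiple-testing correction is applied
across ω values; the p-values are descriptive weights, not family-wise
claims.  Subgroups of size 1 are allowed (a configurable floor exists,
default 1).

## Kernel smoothing and the peak method

Densities use fixed-bandwidth Gaussian kernels with the bandwidth rule
σ = σ̂·n^(−1/γ), where σ̂ is a sample SD and γ the *resolution
coefficient*.  Smaller γ gives a smaller bandwidth, hence higher
resolution (n^(−1/2) < n^(−1/6)); γ = 6 on the log-estimate axis is
treated as the optimal smoothing, and the social-weight axis is swept over
γws ∈ {2, 3, 4, 6} to look for separating peaks.  For the 1D weight
density the bandwidth SD is computed after discarding values outside the
open interval (-1, 2) — extreme tail weights would otherwise inflate it —
while all values keep their kernel mass; γ = 5/2 (half the optimal value)
is the 1D default.  The 2D density uses all points, no trimming, with an
axis-aligned product kernel and independent per-axis bandwidths.  A sample
SD floor of 1e-6 prevents zero bandwidths on degenerate data.  Grids are
256 points per axis covering the data range ± 3 bandwidths; reported
maxima are grid-stable at this resolution (doubling the grid moves them by
under 1%).

The peak method keeps the points whose density — evaluated exactly as the
kernel sum, not by grid interpolation — is at least half the grid maximum,
then fits a two-component bivariate Gaussian mixture by EM (best of 10
random initializations, tolerance 1e-8 on the log-likelihood, at most 500
iterations, ridge 1e-6 on near-singular covariances).  EM runs in
coordinates standardized by the kernel bandwidths so the half-max zone and
the mixture see the same geometry; means and covariances are mapped back
to raw coordinates for reporting.  Points are hard-assigned to their
maximum-responsibility component; the component with smaller mean ws is
labelled low-ws (ties broken by the smaller mean log estimate).  The
cluster's central value is the geometric mean of its members' raw
estimates, with the exponentiated component mean reported alongside as
`peak_value`; 95% ellipses come from the chi-square(2 df) 0.95 quantile of
each covariance.

The method presumes two comparable, separated peaks.  A minority below
roughly a third of the crowd produces a peak under half the maximum and is
excluded by construction — in that regime the sweep, not the clustering,
is the right tool — and data with three or more peaks at high resolution
are outside the model (the component count is fixed at two by design).

## Significance machinery

* Permutation test for a change in mean or variance (used on pooled
  z-scores before vs after influence): mix both samples, re-split
  preserving the original sizes, 10⁶ permutations by default; p is the
  fraction of permuted |θ₁-θ₂| at least as large as observed ("at least"
  keeps p > 0).  Sample variance uses the n-1 denominator.
* Overlap of resisting subgroups across questions: exact upper-tail
  hypergeometric probability that two random subsets of sizes k₁, k₂ from
  a population of n share ≥ m members.  The resisting/non-resisting split
  for this test is ws < 0.5.
* Declared-confidence control: the subgroup test applied to subjects
  declaring confidence ≥ κ for κ = 1..6.  Per level the test is calibrated
  (≈5% null rejections), but "no κ significant anywhere" is a family-wise
  event across ~5 correlated levels and occurs in only ~80-84% of null
  runs; a single question showing one p < 0.05 level is therefore
  unremarkable.

## The synthetic generator

`generate_experiment` draws subjects from a mixture of subpopulations,
each with a fraction, a multiplicative bias exp(log_bias) relative to the
truth, a within-subpopulation log-SD, and a Gaussian social-weight
distribution.  Round 1 is log-normal per subpopulation; the signal follows
the condition; round 2 applies the update rule plus optional log-normal
update noise; the no-information condition repeats round 1 plus noise.
Weights are not truncated by default (the real distribution has ws < 0 and
ws > 1 tails); an optional clip interval exists.  Declared confidence, when
requested, is drawn independently of the estimate — deliberately carrying
no signal — from a distribution concentrated on low values
(0.30, 0.25, 0.20, 0.12, 0.08, 0.05), as real groups mostly declare low
confidence.

Two presets encode the regimes of interest.  `study_subpopulations` is an
unbiased crowd with the bimodal weight structure (half resisting near
ws = 0.05, half conforming near 0.9) and within-group log-SD 1.39, the
mean pre-influence dispersion of real experiments.
`biased_crowd_subpopulations` is the regime the method exists for: 25%
unbiased resisters and 75% conformists biased by e⁻¹, each with
within-subpopulation log-SD 0.6 — the within-cluster spread seen in real
groups (clusters of 512 ± 269 and 216 ± 157 on a border-length question),
distinct from the pooled SD, which the between-subgroup bias inflates.
`generate_study` lays out groups × questions (default 12 groups of 12, six
questions, two per condition) with per-cell seeds derived from the study
seed.

What the generator does *not* emulate: within-subject estimation noise in
round 1, multi-round iterated influence (the analysis uses one
before/after pair; real protocols had five rounds and the pair is
configurable), heavy-tailed or multimodal within-subpopulation estimate
distributions, and any dependence of declared confidence on accuracy.
Passing tests therefore show that the machinery is correct under the
model's own assumptions, not that real crowds satisfy them.

## Problem sizes and numerical choices

Library defaults follow the published procedure (10⁵ subgroup resamples,
10⁶ permutations).  The test suite and simulation checks scale these down
(2 000-60 000 resamples, crowds of 48, 200 replicates for recovery rates,
10⁴ subjects for distribution-level laws) — sizes chosen so Monte-Carlo
error is well inside each assertion's tolerance.  All stochastic routines
take explicit seeds; sweeps and multi-question pipelines derive per-task
seeds from a root `SeedSequence`, so reports are bit-reproducible.

Known limitations: the weight is identified from a single before/after
pair and is noiseless by assumption, so measured ws mixes trait and noise;
subgroup p-values are conditional on the observed weights (the sweep
threshold is data-dependent); the half-max rule cannot see minority peaks
below half the modal density; and the resist estimators are undefined on
questions without a significantly resisting subgroup — by design they
report absence rather than falling back to the WOC.
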