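# Methods

This note records the models behind each stage, the parameter choices that
matter, what the synthetic generators do and do not emulate, and the
numerical conventions — in enough detail that a reader can judge what a
passing test suite does and does not establish.

## Sleep diaries and total sleep time

Clock times live on a noon-to-noon axis: hours after midnight of the diary
date, in [12, 36), so a night's sleep never straddles a representation
boundary. Bedtimes printed in mixed conventions (24.77 vs 01.85) are a
display-level difference only.

Diaries of this kind record bed and rise times plus the *number and total
duration* of naps and night awakenings. Daily TST is defined as
sleep-period duration − awakening minutes + nap minutes, clamped at zero.
This is a package convention, not a universal standard: "total sleep time"
conventionally excludes wake-after-sleep-onset and, for 24-h totals,
includes naps, and the bundled cohort's TST values are consistent with that
reading (TST below time-in-bed for most participants), but other datasets
may define TST without naps. Per-participant TST is the mean over
non-missing days; missing days are excluded, never imputed.

Validation is strict by default; a permissive flag clamps awakening/nap
totals that exceed their containing period and warns, for field data with
entry errors.

## Sleep Regularity Index

The SRI compares sleep/wake state at epoch pairs 24 h apart (same epoch on
consecutive days): SRI = −100 + 200·(mean agreement), 100 for identical
days. Pairs with either epoch missing are removed from numerator and
denominator alike; a participant with no valid pair is an error, not a 0.

Diaries lack within-period event timing, so a binary state per epoch is not
available. The probabilistic variant sets each night epoch to
1 − awake_min/sleep_period_min, each wake epoch to nap_min/wake_period_min
(boundary epochs get the duration-weighted blend), and scores agreement as
p₁p₂ + (1−p₁)(1−p₂) — the probability that two independent epochs with
those sleep probabilities are in the same state. On {0,1} grids this equals
the binary SRI exactly (verified exhaustively against a brute-force pair
enumerator). A perfectly repeated schedule with fractional epochs scores
below 100 (e.g. constant night p = 0.9, wake p = 0.1 gives 64): the index
cannot distinguish true irregularity from uncertainty about event timing,
which is the price of the diary format.

An alternative word-for-word reading of "index values multiplied by the
proportion of the period spent in the opposing state" would assign the
night epochs the *opposing* proportion itself; under it an unbroken,
perfectly regular sleeper scores near −100, contradicting the defining
property that 100 means perfect alignment. Both conventions are
implemented (`diary_to_grid(..., convention=)`); the probabilistic reading
is the default and is used everywhere else. The bundled cohort's SRI values
cannot discriminate the two because the underlying raw diaries are not
distributed.

Epoch length defaults to 1 minute and is configurable (any divisor of
1440); coarser epochs trade boundary resolution for speed.

## Clock chain

The pipeline deliberately starts at beta matrices; IDAT decoding and
raw-intensity quantile normalisation are platform plumbing outside scope.

**Beta-mixture EM.** Beta values are clamped to [1e−6, 1−1e−6] and fitted
with a 3-state (unmethylated/hemi/methylated) beta mixture. Initialisation
is deterministic: quantile slices with method-of-moments shapes. The M-step
maximises the weighted beta log-likelihood per component (L-BFGS-B in
log-shape space with analytic digamma gradients, shapes bounded in
[0.1, 1e4]), so the EM log-likelihood is monotone to optimiser tolerance.
Convergence: relative log-likelihood change ≤ 1e−6, max 500 iterations;
non-convergence warns and returns the best fit. States are relabelled by
increasing mean.

**BMIQ.** Per sample, mixtures are fitted separately to type-I and type-II
probes; type-II probes are assigned to the state of maximal responsibility;
U-state probes map through CDF₂→quantile→CDF₁⁻¹, M-state probes through the
same map on the reflected scale (anchored at β = 1); H-state probes are
rescaled by a monotone affine map from their observed range onto the gap
between the transformed U maximum and M minimum. Type-I probes are
bitwise-unchanged and within-state type-II rank order is preserved. When
the middle state is empty or the gap degenerates, H probes pass through
unchanged rather than being extrapolated.

**Cell composition.** Each sample is projected onto reference mean-beta
profiles: minimise ‖x − Rw‖² s.t. w ≥ 0, Σw ≤ 1 (inequality, tolerating
references that do not span every circulating cell type), then renormalise
to proportions. NNLS solves the common case; an SLSQP quadratic programme
takes over when the simplex bound binds. A rank-deficient reference errors
and names the collinear cell-type pairs.

**Cell-type correction.** The exact correction operator used alongside
published clocks is rarely stated; this package uses per-probe OLS of beta
on the estimated proportions (intercept included) across samples, replacing
each value with its residual plus the fitted value at the cohort-mean
composition, clamped to [0,1]. This removes composition-attributable
between-sample variance while preserving the beta scale. It needs at least
n_cell_types + 2 samples; tiny cohorts should disable the step rather than
fit an unstable regression. Note the bundled cohort's ages are taken as
published, so the downstream inference does not depend on this choice.

**Age transform.** F(age) = log(age+1) − log(A+1) for age ≤ A, else
(age−A)/(A+1), with A = adult_age (default 20 y, the point where
developmental methylation change flattens); the inverse is exact and the
round trip holds to 1e−9 over (−0.9, 120). Clock coefficients are runtime
data (`clock.csv` with reserved `(Intercept)`/`(AdultAge)` rows) so any
published coefficient table can be dropped in; all tests use synthetic
clocks with known truth.

## Grouping and inference

Age-difference = epigenetic − chronological age; positive means
epigenetically older. Duration groups split the cohort in half by mean TST,
regularity groups at the median SRI (midpoint of central order statistics;
strictly above → More Regulated). A tie straddling either boundary is an
explicit error — a silent tie-break would manufacture groups the data do
not support. Crossing gives Good (Longer ∧ More), Poor (Shorter ∧ Less),
Mixed (exactly one).

The ANCOVA is a common-slope model (no group×covariate interaction, which a
cohort of 12 cannot estimate) fitted from first principles by within-group
least squares: slope b = Sxy_within/Sxx_within, adjusted mean of group g at
covariate value x₀ is ȳ_g + b(x₀ − x̄_g) with
SE = √(MSE(1/n_g + (x̄_g − x₀)²/Sxx_within)), t-based CIs on n − k − 1 df,
and the group effect as the partial F against the covariate-only model.
Contrasts (ȳ₁−ȳ₂) − b(x̄₁−x̄₂) are independent of x₀ (asserted over random
evaluation points). The implementation is cross-checked against a
normal-equations solver and statsmodels OLS to 1e−8.

Two presentation choices deserve note:

- **Evaluation point.** Adjusted means default to covariate 0 — the
  predicted change for a participant whose epigenetic age matched
  chronology at baseline — rather than the covariate grand mean.
  Recomputing the bundled cohort's published adjusted means and all six CI
  bounds succeeds (≤ 0.06, the slack induced by 2-dp rounding of the
  inputs) only under this convention, which pins down what the original
  analysis reported. `fit(eval_at=...)` overrides it.
- **Outcome parametrisation.** Fitting the Time-2 age-difference instead of
  the change, with the same covariate, shifts the slope by exactly +1 and
  leaves SSE, F, adjusted-mean differences and contrasts unchanged; the
  equivalence is tested.

The published inferential F statistics for these models (and one baseline
two-group F) are *not* reproducible from the published 2-dp tables under
the model that reproduces every adjusted mean and CI bound; the package
asserts its own recomputed values against an independently computed, frozen
statsmodels oracle instead of the printed ones, and reports p-values
two-sided from the F distribution with no multiplicity correction.

## Synthetic data

The diary generator emulates a 9-week (63-night) college-semester log:
nightly bedtime N(00:45, 1 h²) jitter, time in bed N(8, 0.75²) h, naps with
probability 0.3 and N(45, 20²) min duration, Poisson(1) awakenings of ~10
min each, 5% missing days. One child RNG stream per participant
(SeedSequence([seed, index])) keeps streams stable when the cohort grows.
Truth records exact per-day sleep minutes and the nap placement the diary
format discards, so tests can quantify what the probabilistic SRI loses.
It does not emulate weekday/weekend structure, circadian drift across the
semester, or reporting bias — regularity differences enter only through the
jitter SD.

The methylation generator builds clock probes as base + c_s·w so the
generating clock is exact by construction at zero noise, cell-reference
probes as R·π with Dirichlet(5) mixing over 3 toy cell types (a 6-type
blood-like preset is a config change), i.i.d. Gaussian beta noise (default
SD 0.02), and a second timepoint whose true ages advance by the 63-day
interval plus a per-group drift (default Good −1.5, Mixed 0, Poor +3 y —
the direction pattern the analysis is designed to detect). Probe-type
compression (type-II betas shrunk toward 0.5) is generated by a dedicated
batch helper for the BMIQ tests. The generator does not emulate probe-wise
heteroscedastic noise, batch/chip effects, SNP-affected probes, or
age-correlated composition shifts, so passing tests show the chain is
correct under its own assumptions, not that it is robust to those
artefacts.

Problem sizes used by the test suite and acceptance script (30 clock
probes, ~100–200 background probes, 12 samples, 50–200 replicates for the
drift-recovery study) were chosen as the smallest sizes at which the
targeted effects are comfortably identified; all scale up by config.

## Known limitations

- The probabilistic SRI conflates timing uncertainty with irregularity
  (see above); comparisons are only meaningful within one diary format and
  epoch length.
- BMIQ's H-state affine rescaling is anchored at observed sample extremes
  and is therefore sensitive to outliers in sparse middle states.
- The cell-type correction operator is one of several in field use;
  corrected betas (not the bundled-cohort inference) depend on it.
- With n = 12 the ANCOVA rests on normality and common-slope assumptions
  it cannot itself check; the package reports estimates and intervals, not
  robustness.
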