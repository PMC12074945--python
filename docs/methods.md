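# Methods

## Problem and data model

The package models the mapping from an older adult's basic profile — age,
sex, BMI, baseline VO₂max, and a targeted relative VO₂max improvement — to
the four elements of an aerobic exercise prescription: frequency
(sessions/week), intensity (%HRR), time (minutes/session) and volume
(weeks). Ground truth at the individual level does not exist in the
literature; what exists are study-level summaries (group means ± SDs and the
prescription each study applied). The pipeline therefore treats each study
as a distribution over subjects and trains on samples from it.

### Encoding

Intensity is coded as `pct/100 − 0.5`, placing the 50 %HRR reference at 0;
when a study reports a range, the midpoint is coded. Age, BMI and baseline
VO₂max carry one decimal place; improvement (a fraction, 0.10 = 10 %), time
and volume carry two. Sex is a 0/1 indicator. Frequency has no published
transform and is carried raw, with model output rounded to the nearest
positive integer at decode time. All rounding is round-half-up (ties away
from zero), applied once at encoding; this dialect is canonical throughout,
including in whole-percent rates. Decoding attaches an intensity range of
midpoint ±5 %HRR by default (configurable to ±10), reflecting the practical
tolerance with which intensity targets are administered.

No further input scaling is applied by default — the coding above is taken
as the data standardization. A min–max switch (`input_scaling`) maps inputs
to [−1, 1] using training-set extrema; it is part of the model state (saved
in checkpoints) so inference stays consistent. It matters in practice:
raw physiological scales (age ≈ 70) saturate tanh units at typical
initialization, and several convergence-sensitive tests enable it.

### Gaussian augmentation

`augment_study` expands a study row into `n_subjects` synthetic subjects:
age, BMI and baseline VO₂max drawn independently from Normal(mean, SD)
(a 1×3 draw per subject), sex and improvement held fixed, and the study's
encoded prescription attached as the target of every subject. Draws below
0.05 are rejected and redrawn so the 1-decimal rounding can never produce a
non-positive value; at realistic summary statistics rejection is
vanishingly rare, leaving moments effectively unbiased. Mixed-sex rows
carry a proportion-male field and assign sex per subject by a seeded
Bernoulli draw. Each study uses a child RNG stream keyed by (global seed,
CRC-32 of the study id), so reordering the table never changes per-study
content.

What this emulates — and does not: the generator reproduces the first two
moments of each study's covariates and the deterministic study→prescription
link. It does not model covariate correlations within studies, secular or
protocol heterogeneity beyond what the summaries carry, or any within-study
variation of the prescription itself. Consequently, tests passing on
augmented corpora demonstrate that the pipeline behaves correctly under its
own data model, not that the learned mapping is clinically valid.

### Synthetic ground truth

Two generators provide labelled data with known truth for recovery tests:

- `synth_response_surface` — a smooth hand-designed map on realistic subject
  ranges (intensity decreasing in BMI and age, session time increasing in
  the improvement target) plus optional iid Gaussian noise; the generating
  function is returned so tests can measure recovery and monotone-structure
  transmission.
- `synth_teacher_corpus` — a random network of the same 5–12–10–8–4
  architecture evaluated on uniform [−1, 1]⁵ inputs, so the target is
  exactly realizable by the model class. Teacher weights are scaled by 1.5:
  large enough that outputs have O(0.1–0.5) spread (a trivial target would
  make recovery meaningless), small enough that full-batch LM reaches the
  deep-convergence regime (≈10⁻⁸ MSE) within a few hundred epochs on a
  240-sample training set.

## Network and optimizer

The regressor is fully connected, default widths 5–12–10–8–4, tanh hidden
activations and identity output — the standard configuration for
least-squares training; the activation is configurable. Weights initialize
uniformly in ±1/√fan_in (seeded); biases start at zero. The candidate
hidden-width rule `n₁ = round(√(n+m)) + a`, a ∈ [1, 10], gives 4–13 for
5 inputs / 4 outputs.

Training minimizes `L = MSE + α Σ wⱼ²`, with the MSE pooled over all
(sample, output) residuals and the penalty over weights only (biases are
excluded by default — penalizing output offsets harms calibration — with a
switch to include them). The LM step works on the stacked residual vector
`e = [r/√(Nm); √α·w]`, whose squared norm is exactly `L`, so the penalty
enters the damped normal equations `(JᵀJ + λI)Δw = Jᵀe` as extra
Gauss–Newton rows rather than as an ad-hoc gradient correction. Damping
starts at λ = 0.01, shrinks ×0.1 on an accepted step and grows ×10 on a
rejected one (classic Marquardt factors), bounded to [10⁻¹², 10¹²] with at
most 20 retries per epoch; a Cholesky failure is treated as a rejection.
Accepted steps therefore never increase `L`, and an epoch is one accepted
(or exhausted-retry) full-batch update.

The Jacobian of residuals is computed analytically by per-sample reverse
accumulation (vectorized over samples, one backward sweep per output unit),
or by forward finite differences with step Δ = 10⁻⁵; the two agree to 10⁻⁴
relative error on random full-architecture networks, which the suite
asserts. The finite-difference mode exists because it is the conventional
reference for this optimizer; the analytic mode is the default and is
~300× faster at this parameter count (326 weights and biases).

Early stopping monitors validation MSE with patience 10 (default); training
also stops at the error-precision goal (10⁻⁷ MSE) or the epoch cap (1,000).
The best-validation snapshot is returned alongside the final state and a
per-epoch history (train MSE, validation MSE, λ, accepted flag), logged
every `display_interval` (25) epochs.

A plain gradient-descent-with-momentum trainer (`algorithm="gd"`) is
included as the conventional back-propagation baseline; the learning rate η
and momentum β govern only this path — a pure LM update has no use for
either, although both appear in the hyperparameter grid for completeness.

## Model selection

`paper_split_sizes` reproduces the floor(80/10/10) arithmetic
(1,594 → 1,275/159/159; the floors drop one sample). The operational
splitter instead shuffles once (seeded), cuts ten near-equal contiguous
segments, and assigns any remainder to training, so no sample is silently
lost; the two conventions intentionally differ and both are tested.

Grid search is exhaustive over η ∈ {0.001, 0.01, 0.1}, β ∈ {0.5, 0.7, 0.9},
α ∈ {0, 0.001, 0.01} (27 cells), minimizing mean inner-validation RMSE;
exact ties prefer smaller α, then smaller η, then smaller β, for
reproducibility. A single-cell grid short-circuits without training.

Nested cross-validation runs a 10-fold outer loop; within each outer
training pool, the inner grid search (10 folds by default, reducible) sees
only pool indices — the structural no-leakage property is asserted on every
run and re-checked by the suite. Weights are reinitialized per outer fold
from an independent child seed. The inner loop may run with a reduced epoch
cap (`inner_cfg`) to keep the grid tractable; the winning hyperparameters
are then refit at full caps. Round metrics (RMSE, MAE, R²) are pooled over
the encoded 4-vector residuals, giving one number per round, with Mean and
Best (minimum-RMSE round) summary rows. Note that under this standard
definition MAE ≤ RMSE always holds for a common residual set.

## Validation statistics

- `metric_set`: pooled MAE, RMSE, MSE, R² (= 1 − SSres/SStot) and Pearson R;
  a zero-variance target flags R² as undefined rather than raising.
- `error_ratios`: signed relative deviations `100·(pred − target)/target`
  per element (intensity, time, volume) — negative means under-prescription
  — with mean ± SD and the fraction inside a ±20 % band (configurable);
  zero-target pairs are excluded with a warning.
- `hit_rate`: the share of observed improvements inside M ± k·SD of their
  own sample (k = 1 or 1.96), inclusive bounds, whole-percent round-half-up.
- `bland_altman`: bias, 95 % limits of agreement (bias ± 1.96·SD of
  differences) and coverage; differences default to expected − observed,
  switchable.
- `expected_vs_observed_regression`: OLS (via statsmodels) with slope CI and
  the non-zero-slope p-value.

Sample SDs use the n−1 denominator everywhere.

## Numerical and design choices

- Damped normal equations are solved by Cholesky factorization of
  `JᵀJ + λI`; λ > 0 guarantees positive definiteness except at extreme
  ill-conditioning, which the damping escalation absorbs.
- Divergence (non-finite loss) aborts with a diagnostic rather than
  returning garbage; reachable with the gradient-descent baseline at large
  η, not with LM's acceptance test.
- Frequency decoding never emits a value below 1; time/volume are never
  clipped — implausible values are flagged by the prescription screen
  (intensity 40–90 %HRR, time 10–90 min, volume 4–52 wk, deliberately wider
  than guideline ranges so the screen warns without blocking).
- All randomness flows from one root seed through named child streams
  (corpus / splits / init), and stochastic artifacts embed the seed and a
  configuration hash.

## Problem sizes used in the checks

The recovery and cross-validation tests run on a 300-sample teacher corpus
(240/60 splits, epoch caps 30–600) and a 400-sample response surface —
sizes at which full-batch LM on 326 parameters converges in seconds while
exercising every code path, chosen as the package's standard verification
scale. The corpus-scale checks build the full 68-study, 1,594-sample
synthetic table.

## Known limitations

- The model interpolates the intervention literature's summary statistics;
  it cannot outperform the resolution of those summaries, and augmented
  subjects inherit each study's prescription wholesale, so within-study
  dose–response is invisible to it.
- Intensity scales (%HRR vs %HRmax vs %VO₂max) are assumed harmonized
  upstream; no conversion is provided.
- Full-batch LM stores the complete Jacobian; memory grows as
  (samples × outputs) × parameters, which is trivial here but rules out
  very large corpora without mini-batching (out of scope).
- LM on tanh networks has local minima; with some initializations training
  plateaus at a poor fit. The trainer is deterministic given a seed and
  reports its history, so such runs are visible; multi-restart is left to
  the caller.
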