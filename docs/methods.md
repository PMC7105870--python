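# Methods

`sleepvar` implements a complete analysis chain for studying the relationship
between objectively measured sleep — especially its *night-to-night
variability* — and caregiver-reported behavior in autism spectrum disorder
(ASD), driven by a synthetic cohort generator with a known ground truth.
This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic experiments do and do not show.

## Minute-level sleep/wake scoring

Each minute of wrist-actigraphy activity (zero-crossing counts) receives the
linear score

```
S = 0.0033 · (1.06·a₋₄ + 0.54·a₋₃ + 0.58·a₋₂ + 0.76·a₋₁ + 2.3·a₀ + 0.74·a₊₁ + 0.67·a₊₂)
```

and is labelled sleep when `S < 1`. This is the Cole–Kripke-family filter
used by zero-crossing-mode wrist devices. Minutes without a full 7-minute
window (the first four and last two of a series) and off-wrist minutes are
*undefined*. Epochs must be 1-minute; other resolutions are rejected rather
than resampled.

**Rescoring.** Raw labels are cleaned with the Webster rescoring rules:
after ≥4 minutes of wake the next 1 sleep minute is rescored wake, after ≥10
the next 3, after ≥15 the next 4; sleep bouts ≤6 minutes flanked by ≥10
minutes of wake on both sides (or ≤10 minutes flanked by ≥20) are rescored
entirely. All rules are evaluated against the run structure of the *input*
labels and applied in one pass. The pass is deliberately not iterated to a
fixed point: a pre-sleep wake run always exceeds 15 minutes, so a fixed-point
operator would erode four additional minutes of sleep per iteration and
eventually consume the whole night. Consequently the operation is a
post-processing pass, not an idempotent projection; applying it twice can
rescore a few additional boundary minutes. Rescoring can be disabled in
configuration.

**Sleep-period detection.** The study this design follows used automatic
detection plus expert manual adjustment. The repository replaces the expert
with a stated heuristic plus an override hook: the period spans from the
first run of ≥K consecutive sleep minutes to the end of the last such run
(default K = 20, configurable), runs containing off-wrist minutes are
disqualified, and an optional ambient-light threshold disqualifies runs whose
median light is too high. Nights without a qualifying run are marked invalid
and discarded from aggregation. Externally supplied (start, end) pairs — the
manual-override channel — bypass detection entirely.

**Night measures.** Within the detected period: sleep start and end in
minutes relative to the midnight that begins the calendar date the night is
assigned to (an episode starting before midnight has negative start; the end
index is exclusive so duration = end − start); awakenings = maximal non-sleep
runs strictly inside the period followed by sleep; efficiency = percentage of
in-period minutes labelled sleep. Undefined minutes inside the period are
counted as wake — a conservative choice, since the alternative (excluding
them from the denominator) would inflate efficiency on noisy nights. Sleep
duration (and optionally sleep start) is age-adjusted by subtracting the
National Sleep Foundation recommendation for the participant's age band
(6–13: 600 min / −210 min; 14–17: 540 / −150; 18+: 480 / −90).

## Intra-individual variability windows

For each participant-visit, valid nights in the half-open week
`[visit − 7 d, visit)` are summarized per measure by mean, sample SD (n−1
denominator — material at 2–7 nights per window) and CV = SD/|mean|. Windows
with fewer than 2 nights are excluded. Duration is age-adjusted per night
*before* summarizing (the constant within-age-band offset shifts the mean
and leaves the SD unchanged); sleep start is left unadjusted by default with
a configuration switch, because the reference cohort summaries report
raw-looking start times alongside the adjustment recipe. Because sleep start
is signed, the CV uses |mean| and is flagged undefined when |mean| < 1e−9.

## Association models

The repeated-measures association between a caregiver scale and an
actigraphy statistic is

```
scale ~ (1 | participant) + actigraphy + age + sex + IQ
```

with all variables standardized on the analysis sample (complete cases per
model; sex coded 0/1 before standardization), fit by REML via
`statsmodels.MixedLM`. Inference on the actigraphy coefficient is a Wald
test with a normal approximation — the backend does not provide
Satterthwaite degrees of freedom, and with ~50–100 participants the
difference is small. When every participant contributes a single visit (or
the fit is singular), the model degrades to OLS and the result is flagged
`degenerate`. P-values from one scale×statistic grid form one
Benjamini–Hochberg family at FDR 0.05; the family structure is explicit in
the API because it is a genuine analysis choice.

Covariate-adjusted Spearman correlations rank-transform *all* variables
(including covariates — residualizing ranks on raw covariates would leave
any shared monotone component behind), residualize the x/y ranks on the
covariate ranks by least squares, and report the Pearson correlation of the
residuals with a t-based p-value on n − 2 − k degrees of freedom. With no
covariates this reproduces classical Spearman exactly.

Group prevalence of "more than mild" caregiver-reported sleep problems
(ordinal sleep item ≥ 3) is compared by Pearson chi-squared without
continuity correction (configurable); group mean differences by OLS
controlling for sex and age.

## Anxiety prediction protocol

The feature table has 17 columns — mean/SD/CV of the four sleep measures
(12), the caregiver sleep item, age, sex (0/1), IQ, and ADOS CSS — over
participant-visits passing the 2-night filter; the response is the caregiver
anxiety total (CASI-Anx).

Preprocessing: (1) near-zero-variance flagging — unique fraction < 10% AND
most/second-most frequency ratio > 19 (strict inequality; a constant column
is always flagged); (2) iterative decorrelation — repeatedly find the pair
with the largest |r| ≥ 0.7 and drop the member with the larger mean absolute
correlation to the remaining features (ties: the later column); (3) VIF
check — each retained feature regressed on the others with intercept,
VIF = 1/(1−R²); any feature at VIF ≥ 10 is dropped worst-first (in practice
none is after step 2).

The elastic net minimizes

```
(1/2N) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ Σⱼ ((1−α)/2 βⱼ² + α|βⱼ|)
```

on standardized predictors and centered response. The solver is
scikit-learn's coordinate descent, whose penalty parameterization matches
this objective exactly (`alpha=λ, l1_ratio=α`); λ = 0 falls back to OLS and
α = 0 to a closed-form SVD ridge path (coordinate descent is unreliable at
`l1_ratio=0`). The λ path per α is 100 log-spaced values from
λ_max = max|Xᵀy|/(N·max(α, 10⁻³)) — the smallest λ with an all-zero solution
— down four decades.

Protocol (defaults = the published settings):

1. Split 70/30. The split unit is the *participant* (all visits of one
   person on the same side) to prevent within-person leakage; a row-level
   option reproduces the per-observation variant. Splits leaving a constant
   training column are redrawn.
2. On the training side, for each α ∈ {0, 0.05, …, 1}: 100 repetitions of
   10-fold CV along the λ path; each repetition records its minimum
   cross-validated MSE; repetitions are averaged. Fold assignments are
   shared across the α grid so mixing values compete on identical
   resamples.
3. α\* minimizes the averaged minimum MSE (ties toward smaller α — more
   ridge-like, more stable); λ\* is the minimizer of the pooled MSE curve at
   α\* (`min_mse`), or the largest λ within one standard error of it
   (`min_mse_plus_1se`), with the SE taken across fold-level MSEs at the
   minimizing λ.
4. Refit once at (α\*, λ\*) on the full training side — the protocol refits
   rather than averaging across inner repetitions, which is the simplest
   reading consistent with a single reported model per split — and score
   the test side: MSE; R² = 1 − SSE/SST about the *test* mean (can be
   negative); and the regression F-statistic against an intercept-only
   model with df₁ = number of selected features (min 1) and
   df₂ = n_test − df₁ − 1 (non-positive df₂ ⇒ not significant).
5. Repeat 100×. Feature importance: raw_j = Σ_s c_sj · (r_s · f_s) / S with
   c_sj the selection indicator, r_s the test R², f_s = 1 iff the F-test
   p < 0.05; the denominator is the number of test sets S (100 at the
   published scale), and the raw vector is normalized by its maximum to
   [0, 1] (an all-zero vector stays zero and is flagged).

## Synthetic cohort generator

The generator defines the study conditions and supplies ground truth for
every downstream stage.

*Profiles.* ASD ages follow a shifted gamma on [6, ∞) with mean 14.5 and SD
7.91 years — matching the reference cohort's mean/SD while reproducing its
right skew (median ≈ 12) that a truncated normal cannot; sex is Bernoulli
(77.7% male ASD, 74% TD); IQ ~ N(99.0, 19.55²) clipped to [40, 160]; ADOS
CSS ~ N(7.59, 1.74²) rounded into 1–10 (ASD only).

*Architecture.* Per participant: mean bedtime ~ N(−81, 60²) minutes vs.
midnight with within-person SD 40; mean duration ~ N(481, 55²) with
within-person SD 45; awakening rate ~ N(17.5, 6.2²) clipped to [0.5, 45],
loading −0.6 of its SD on a latent sleep-quality scalar q ~ N(0,1) so poorer
sleepers have more fragmented nights. Each night draws a true interval;
awakenings are a Poisson count of geometric-length (mean 2.5 min) wake
bouts placed uniformly in the gap-reduced space (so the realized count
equals the Poisson draw exactly and bouts never overlap), keeping a 25-min
episode-free consolidation margin after onset and before final waking —
emulating consolidated sleep at the period edges, without which a 20-minute
run detector cannot pin onset to ±15 minutes at realistic fragmentation.

*Activity/light.* Wake minutes draw negative-binomial counts (mean 180,
shape 5); sleep minutes zero-inflated Poisson (65% zeros, mean 12
otherwise): overdispersed non-negative integers with cleanly separable
regimes, which is all the linear scorer requires. Ambient light is
exponential with scale 120 outside the sleep interval and 1 inside.

*Compliance.* The number of nights worn per 7-day window follows the
observed wear pattern (midpoint: 21/12/10/9/2/4 participants at 2–7 nights);
at the cohort level a Bernoulli first decides whether a participant falls
below the 2-night bar (defaults 81/139 at midpoint, 101/139 at endpoint,
from the observed attrition), so a default cohort yields a feature table
near the reference N = 96.

*Scales.* The caregiver sleep item is ordinal 0–7 (the instrument's range is
not published; the bound is configurable). Its ASD distribution (mean 3.8,
SD ≈ 1.9 before rounding) balances two incompatible published summaries of
the same item and reproduces the ≈69% vs ≈12% ASD/TD prevalence of scores
≥ 3. The anxiety score is linearly coupled to *observable* quantities —
the sleep item, the realized window SD of true efficiency, and the realized
CV of true awakening counts (defaults: intercept 8, β = 2.5 / 3.0 / 8.0,
noise SD 2.5, clipped to 0–63) — realized meaning computed from the
generated nights, not the latent architecture, so the pipeline can in
principle recover the coupling through its own scoring. Other scales load
on the latent quality only.

**What the generator does not emulate:** circadian phase drift,
weekday/weekend structure, naps and daytime wear, device-specific noise
spectra, non-random missingness, and any true biomechanics of
accelerometry. Passing recovery tests therefore shows the *pipeline* is
correct and sensitive under separable regimes and the stated coupling — not
that the same effect sizes would be estimable from real recordings.

## Problem sizes and numerics

Unit and acceptance tests run the protocol at a scaled size — 20 outer
splits × 10 inner repetitions with a 40-point λ path — which preserves every
structural property of the full 100×100×100 protocol while keeping a
desk-scale runtime; the full scale remains the default configuration. The
scaled null-calibration check accordingly uses a wide tolerance on mean test
R² (|mean| ≤ 0.25), since at 20 splits the mean of a slightly-negative-mean
statistic is noisy. Coordinate descent uses tolerance 1e−10 for single fits
and the library default along CV paths; CV fold standardization is computed
on each training fold and applied to its validation fold. Ties in α
selection break toward smaller α; ties in decorrelation drop the
later column. Degenerate inputs (constant scales, rank-deficient feature
matrices, empty groups, sub-2-night windows) raise or flag rather than
silently produce numbers.

## Known limitations

- The mixed-model p-values use a normal approximation; at very small
  cohorts they are mildly anti-conservative compared to Satterthwaite or
  Kenward–Roger corrections.
- The rescoring pass is not idempotent (see above); its effect on night
  measures is a few boundary minutes.
- Scored efficiency runs ~5–8 points below true efficiency because
  awakening-adjacent windows spill wake evidence into neighboring minutes;
  rank order across nights and participants is preserved (r ≈ 0.96), which
  is what the variability statistics consume.
- The TD arm carries caregiver scales only (the reference design collected
  no TD actigraphy), so group comparisons are restricted to reported sleep.
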