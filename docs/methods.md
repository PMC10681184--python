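# Methods

`pcstroop` re-implements, as a reusable and fully testable pipeline, the
computational machinery of a dual proportion-congruency (PC) emotional-priming
spatial Stroop experiment: the trial-list design and its selection, the
ideal-observer belief predictors, a generative model of the behavior, the
mixed-effects analysis, and power analysis for crossed participant × stimulus
designs. This note documents the models, the defaults and why they were
chosen, and what the synthetic data can and cannot show.

## Task and design

Each trial shows an arrow at one of four corner locations (upper-left,
upper-right, lower-right, lower-left), pointing toward one of the same four
corners; participants respond to the *direction* with a spatially compatible
key (E/O/K/D). A trial is congruent when direction equals location. The
proportion of congruent trials is manipulated at two levels simultaneously:

- **LWPC** (list-wide PC): the fraction of congruent trials per block,
  driving anticipatory (proactive) control;
- **ISPC** (item-specific PC): the fraction of congruent trials at each
  location, driving stimulus-triggered (reactive) control;
- **PRS** (response-given-stimulus contingency): the probability of each
  direction given the location — an associative-learning confound that the
  design decorrelates from the PC manipulations rather than holding constant.

The default design has six blocks of 96 trials (24 per location, locations
equiprobable), with LWPC levels .25/.50/.75 mirrored across block pairs
1&5, 2&4, 3&6 (blocks 4–6 reuse the block 1–3 count matrices with corners
relabeled by the reversing permutation, which preserves congruent cells and
row sums while moving the ISPC profile across locations). Within each block
the per-location ISPC values are spread widely around the block LWPC
(e.g. .042/.125/.375/.458 in the low block) and the incongruent trials of
each location are allocated unevenly over directions (relative weights
4:2:1, rotated per location). The spread and the allocation were fixed by
running the same search the design procedure itself prescribes — minimize
the shared variance between the trial-wise ISPC and PRS predictor series
over candidate lists while keeping the LWPC–ISPC overlap low — and are
frozen in `design.default_design()`. Any other 6×4×4 count configuration
can be supplied as YAML.

**Trial ordering.** Within the concatenated list (constraints bind across
block boundaries) a sequential sampler enforces: at most five consecutive
trials of the same congruency, no immediate repetition of target location,
and no immediate repetition of target direction (direction determines the
response, so this also removes response repetitions). "No repetition" is
read per attribute — the stricter of the two plausible readings — because
that is the standard first-order priming control. Trials are drawn
uniformly over the remaining admissible (location, direction) cells; dead
ends restart the block, with a bounded restart budget. The break position
is the midpoint of the list (`floor(total/2)`).

**List selection.** 1000 candidate lists are generated from seeds derived
from one master seed; trial-wise LWPC/ISPC/PRS beliefs are computed for
each (below); the list minimizing the squared Pearson correlation between
the ISPC and PRS series is selected (ties broken toward the lowest
candidate index). With the default design and filter the winning list
shares ≈ 1% ISPC–PRS, ≈ 20–25% LWPC–ISPC and < 1% LWPC–PRS variance —
the same profile the design aims for by construction.

## Trial-wise beliefs: the binary Hierarchical Gaussian Filter

Participants cannot know a block's PC on its first trials, so block-wise
constants are replaced by the beliefs of an ideal observer. The 3-level
binary HGF places a Gaussian random walk on the log-odds of the tracked
event (level 2) and another on its log-volatility (level 3); under a
mean-field variational approximation each trial yields closed-form
precision-weighted prediction-error updates — a Bayesian analogue of
Rescorla–Wagner learning with a dynamic learning rate. The implementation
follows the standard update equations exactly (tested to 1e-12 against an
independent transcription).

Predictor families, all reported on the natural-log-odds (logit) scale:

| family | trackers | input stream | read out |
|---|---|---|---|
| LWPC | 1 | congruency of every trial | prediction |
| ISPC | 4 (per location) | congruency at that location | current trial's location |
| PRS | 16 (per location × direction, one-vs-rest) | direction identity at that location | actual direction |
| PR | 4 (one-vs-rest) | direction identity, all trials | actual direction |
| PL | 4 (one-vs-rest) | location identity, all trials | actual location |

Categorical streams use four one-vs-rest binary filters (renormalization to
a proper distribution is available but not applied to the predictors, which
enter the model one cell at a time). By default the predictor for trial *k*
is the **one-step-ahead prediction** — the belief held *before* observing
trial *k* — since an expectation about a trial cannot use that trial's
outcome; the posterior alternative sits behind a flag.

**Default perceptual parameters** (free choices; nothing in the data pins
them): κ = 1, ω = −6, ϑ = 0.05, μ₂⁰ = 0, σ₂⁰ = 1, μ₃⁰ = 0, σ₃⁰ = 1. The
binary HGF is numerically unstable for large ϑ or high tonic volatility
(the level-3 posterior precision can go negative — the update then raises);
the chosen regime is stable across all probed lists, converges to within
0.1 of the truth on stationary Bernoulli(.75) input, and tracks the
block-wise LWPC with the expected lag (correlation ≈ .7–.8 between
trial-wise and block-wise LWPC). All parameters are exposed in the config
and recorded in output metadata.

## Generative model of behavior

Analyses run on inverse-transformed reaction times, iRT = −1000/RT (ms),
which tames the right skew of RT distributions; iRT is negative and
increasing in RT. The generator simulates each participant trial by trial:

iRT = Σ βⱼ·xⱼ + b₀ᵖ + Σ bⱼᵖ·xⱼ + b₀ⁱᵐᵍ + β_prec·z(iRT_prev) + ε

with effect-coded factors (congruent = −1 / incongruent = +1; neutral = −1
/ sad = +1; left/lower = −1, right/upper = +1 for the position and
direction codes), standardized continuous covariates, participant random
effects bᵖ (intercept + slopes for congruency, LWPC, ISPC and the
congruency × PC interactions), a by-image random intercept shared across
participants, and Gaussian residual ε. The fixed-effect defaults are the
final-model estimates of the study the package emulates (intercept −2.329,
congruency 0.225, congruency × LWPC 0.054, …), making parameter recovery a
direct end-to-end check of the analysis chain.

Details worth knowing:

- **Variance components.** Random-effect magnitudes are not published;
  defaults target the variance partitioning the power analysis assumes —
  participant intercept ≈ .1, image intercept ≈ .1, participant congruency
  slope ≈ .2, residual ≈ .6 of the (random + residual) iRT variance:
  SDs 0.141 / 0.141 / 0.2 on an iRT scale with residual SD 0.346; the
  remaining slopes default to SD 0.02 with an identity correlation matrix.
  All configurable.
- **Temporal dependence** comes from the preceding-iRT term itself
  (β_prec = 0.086 on the standardized previous simulated iRT; the first
  trial uses a marginal draw). The standardization scale is the
  self-consistent marginal SD, `s² = V₀ + β_prec²`, where V₀ sums the
  fixed-predictor, random-effect, image and residual variances — with the
  regressor standardized by s the effective AR(1) coefficient is β_prec/s.
  The constant is exported in the dataset metadata so the analysis side can
  reproduce the generator's design matrix exactly.
- **Errors and timeouts.** Accuracy is Bernoulli with congruency-specific
  error rates (defaults .01 congruent / .03 incongruent, keeping congruent
  accuracy at ceiling); error trials still receive a model-drawn RT (they
  are excluded downstream). RTs are clipped at a 150 ms floor; responses
  beyond the 2000 ms timeout are recorded as missing. Residual draws that
  would produce non-negative iRT (undefined RT) are resampled and counted.
- **Primes.** Images 1–20 are sad, 21–40 neutral (same actors). Emotion is
  balanced 50/50 within each block × congruency cell (odd cells round
  alternately); the image is drawn uniformly within emotion with no
  immediate repetition. The design engine itself is emotion-agnostic: the
  PC structure never depends on the prime.
- Every participant sees the same selected list, as in the emulated study.

**What the synthetic data do not emulate:** practice trials, the
manipulation-check ratings, non-Gaussian residuals, slow drifts beyond the
linear trial-rank trend, and any dependence of the emotion effect on the
stimulus set. Passing recovery tests therefore shows the *pipeline* is
consistent (the estimator recovers the generating process pushed through
the real exclusion/transform/fit chain), not that the model is true of real
participants.

## Preprocessing

Per participant, the analysis drops: the first trial of the task, the first
trial after the mid-task break, error trials (incorrect *or* missing —
timeouts count as missing responses, hence as errors), and the trial
immediately following each error. The preceding-iRT covariate of a retained
trial comes from the immediately *presented* previous trial whether or not
that trial was itself retained; rows whose predecessor has no measurable RT
are dropped and counted. Exclusion is idempotent. Continuous covariates
(belief logits, trial rank, preceding iRT) are standardized on the analysis
sample by default; the generator's constants can be injected for exact
round-trip comparisons.

## Mixed model

The analysis model is a Gaussian LMM with crossed random effects:

iRT ~ Trial + PrecedingRT + PRS + PR + PL + hPOS + vPOS + hDIR + vDIR
      + Congruency × LWPC × Emotion + Congruency × ISPC × Emotion
      + (Congruency × LWPC + Congruency × ISPC | participant) + (1 | image)

The estimator is a self-contained profiled-REML engine in the lme4
formulation: the random-effect covariance is σ²Λ(θ)Λ(θ)′ with Λ a
block-diagonal relative Cholesky factor (one lower-triangular block per
grouping factor, fully correlated within block); for any θ a single
penalized least-squares solve profiles out β and σ², and the optimizer
(L-BFGS-B with a derivative-free fallback, diagonal θ bounded at zero)
searches only the covariance parameters. On shared fixtures the engine
agrees with lme4 to ~1e-4 in estimates and ~1e-3 in the REML criterion, and
matches the closed-form one-way ANOVA estimators on balanced data.

Inference uses Wald z statistics with a normal approximation (labeled
`df_method="normal"` in every output; with ~40,000 rows the Satterthwaite
correction is negligible). Boundary fits (a variance at zero) are flagged,
not errors. Further operations:

- **Backward elimination** (thresholds α_random = .1, α_fixed = .05, the
  conventional defaults of the stepwise procedure; configurable): random
  terms first, one at a time by REML likelihood-ratio tests against the
  model without the term, respecting marginality and keeping a group's
  intercept until last; then fixed terms by Wald tests, never removing a
  term contained in a retained interaction or one that still carries a
  random slope. The full-versus-final random structure LRT is reported
  (the full default structure has 78 covariance parameters, the final 21,
  hence 57 degrees of freedom).
- **Outlier refit**: after model selection, rows with |conditional
  residual|/σ̂ > 2.5 are removed and the model refit once (~1.2% of rows
  under Gaussian residuals).
- **Variance explained**: Nakagawa-style decomposition; marginal R² =
  var(Xβ̂) over the total, conditional R² adds the random-effect variances,
  each random term contributing the row-average of zᵢ′Σ̂zᵢ.

## Post-hoc contrasts

Cell slopes (∂iRT/∂LWPC within each congruency × emotion cell) and
marginal means at chosen LWPC values are exact linear functions c′β̂ of the
fixed effects, with delta-method (here exact) standard errors from the
fixed-effect covariance. Families of simultaneous pairwise comparisons are
Tukey-adjusted via the studentized-range distribution: k pairwise
comparisons are mapped back to m means through m(m−1)/2 = k (non-triangular
k rounds m up, which is conservative); k = 1 returns the unadjusted
two-sided p. The adjustment was verified against a 10⁶-draw multivariate
normal Monte Carlo at k = 28. Two slope families are supported: all 6
pairwise contrasts of the 2×2 cells, or the 4 simple-effect contrasts
(emotion within congruency plus congruency within emotion) — the family
size k is always an explicit argument because reported family sizes in this
literature are ambiguous between the two conventions.

## Power analysis

For a fully-crossed design with p participants and q stimuli, all variance
components expressed as proportions of total outcome variance (VPCs), the
condition-difference estimate has variance (in VPC units)

Var(d̂) = 2·V_pslope/p + 2·V_sslope/q + 4·(V_ps + V_e)/(p·q)

under counterbalancing (each stimulus appears in both conditions, so both
intercept variances cancel from the contrast; with stimuli nested in
conditions the term 4·V_sint/q is added). Power is the two-tailed
noncentral-t tail beyond t_crit at Satterthwaite-style effective degrees of
freedom df = Var² / Σ(termᵢ²/dfᵢ) with df terms p−1, q−1 and (p−1)(q−1).
The minimal detectable effect inverts this in d by bisection. As q → ∞ the
computation converges to the paired-t power with variance 2·V_pslope/p.

Conversions for a two-level contrast: f = d/2, η²_p = f²/(1+f²), inverses
accordingly. The repeated-measures ANOVA sensitivity solve uses the
noncentral F with λ = f²·n·m/(1−ρ), df₁ = m−1, df₂ = (m−1)(n−1) (the
conventional G*Power parameterization); the number of within-subject levels
m is an explicit argument because a detectable-d figure is meaningless
without it — for n = 74, ρ = .75 the detectable d at 80% power is ≈ .23
(m = 2) to ≈ .19 (m = 4).

## Problem sizes and numerical choices

The default study scale is 74 participants × 576 trials (≈ 40,000 analysis
rows after exclusions); a full REML fit of the final model (22 covariance
parameters) takes on the order of a minute on one core, and the
1000-candidate selection a similar time, so the end-to-end reproduction
script runs in minutes. Tests use scaled-down versions of the same
machinery (4–6 participants, 8–20 candidates) except where the full scale
is the point. Degenerate inputs fail loudly: infeasible count targets name
the violated constraint, unsatisfiable ordering constraints report the
block, non-positive HGF precisions raise rather than silently clamp,
constant series make shared variance an error, and singular fixed-effect
designs raise instead of returning pseudo-inverse estimates.

## Known limitations

- The HGF defaults are a documented convention, not fitted values; any
  quantity that depends on the belief series (e.g. shared-variance
  percentages) moves with them.
- Satterthwaite degrees of freedom are not implemented; at the package's
  intended scale the normal approximation is accurate, but p-values on very
  small fixtures are approximate.
- The elimination procedure tests one covariance-parameter block at a time
  and does not explore uncorrelated ("diagonal") random structures.
- One-vs-rest categorical tracking ignores the sum-to-one coupling between
  cells; the renormalized distribution is exposed for diagnostics.
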