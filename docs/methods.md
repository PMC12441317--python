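# Methods

`aalearn` implements a complete simulate–fit–compare–validate chain for a
continuous intergroup approach–avoidance learning task. This note documents
the model space, the estimation and comparison machinery, the synthetic-data
generator and the numerical choices, including the places where the design
was genuinely open and what the package chose.

## The task

On each trial a participant moves a manikin along a horizontal line toward
(approach) or away from (avoid) an abstract symbol shown at the right end of
the line; in the two social arms the symbols stand for an in-group and an
out-group individual. The response is the signed distance moved,
`raw_distance = final_pos − start_pos`, with the start position jittered
uniformly on [0.40, 0.60] of the line. Three study arms differ only in the
reward schedule:

- **social_conflict** and **nonsocial_control**: approaching symbol 2
  (out-group) is rewarded (+0.05 €) on 80% of trials and punished (−0.05 €)
  otherwise; approaching symbol 1 (in-group) is rewarded on 20% of trials;
  avoidance probabilities are complementary.
- **social_control**: 50% reward regardless of symbol and direction.

Each participant runs 3 blocks × 40 trials (20 per symbol, no more than two
consecutive same-symbol trials), 120 decision trials in total. Trials with
no movement are invalid: no outcome is delivered and no learning occurs.
Participants with more than one invalid trial in any block × symbol cell
(>5% of the 20 trials in that cell) are excluded.

For modelling, the signed distance is mapped affinely onto [0, 1]
(`(raw + D) / 2D` with D = 0.6, so 0.5 means no movement) and in-group-symbol
trials are reflected (`1 − u`) so that larger oriented values point in the
rewarded direction for both symbols. The oriented, normalised response y is
what the models predict.

## The model space

All six models are Rescorla–Wagner learners over y with a binary outcome
r ∈ {0, 1} (punishment/reward) and prediction error δ(t) = r(t) − V(t−1):

| model | learning rate(s)            | response weight(s) | K |
|-------|-----------------------------|--------------------|---|
| 1     | α                           | —                  | 3 |
| 2     | α                           | β                  | 4 |
| 3     | α                           | β_in, β_out        | 5 |
| 4     | α_in, α_out                 | β                  | 5 |
| 5     | α⁺ (δ ≥ 0), α⁻ (δ < 0)      | β                  | 5 |
| 6     | α⁺/α⁻ × in/out              | β                  | 7 |

plus, in every model, two free initial values V1_in and V1_out — the
prediction for the first encounter with each symbol, encoding the initial
intergroup approach bias. The update is

    V(t) = [V(t−1) + α* · δ(t)] · β*,

with α* chosen by symbol (model 4), by the sign of δ (model 5, δ = 0 on the
positive branch), or by both (model 6), and β* = 1 (model 1), shared β
(models 2/4/5/6) or per-symbol β (model 3).

Resolution of the within-trial timing: the value updated with trial t's
outcome becomes the prediction for the *next* same-symbol encounter (the
outcome cannot precede the choice it rewards). Invalid trials are skipped
entirely — no update, no residual, and they do not advance the per-symbol
encounter counter.

**Teacher-forced vs latent propagation.** The value carried into each update
is, per symbol, either the participant's previous *observed* response
(teacher-forced) or the model's own previous prediction (latent). Because
the model identifies the expected value with the choice itself,
teacher-forced is the fitting default; latent mode is implemented for
robustness checks and verified against an independent step-by-step oracle.

**First encounters.** The first-encounter prediction is V1 itself, without β
scaling, and its residual counts in the SSE. Under teacher forcing every
later prediction depends only on observed data, so without a first-encounter
residual V1 would be nearly unidentifiable.

**Bounds.** All parameters live in [0, 1]. Start values are drawn there, V
and r live there, and the convex-combination structure then keeps every
prediction (and δ ∈ [−1, 1]) in range, which is property-tested.

## Estimation and comparison

Per participant and model, parameters minimise the sum of squared errors
between observed and predicted oriented responses, using L-BFGS-B inside the
unit box from `n_starts = 10` uniform random start vectors (the restart
count is a package default; more starts can only lower the returned SSE,
which is tested). Ties within 1e−10 go to the lowest start index for
determinism; a Powell polish is applied (and flagged) if the winning
quasi-Newton run reports failure, which happens occasionally at bound
corners. In teacher-forced mode the objective is fully vectorised, since
every prediction is an explicit function of the data and parameters.

Models are compared with

    BIC = n · ln(SSE/n) + k · ln(n),

summed over participants (lower is better; ties broken by smaller K), with
participants lacking a fit for any model dropped listwise and counted.
A perfect fit (SSE = 0) makes the criterion diverge; `bic()` rejects it and
the fitter records a perfect-fit sentinel (−∞) instead. Goodness of fit is
reported as R² = 1 − SSE/SST per participant (SST about the participant's
mean oriented response), then averaged — the per-participant-then-average
convention is a package decision, isolated in one function, since the
summary convention is ambiguous in general. Parameter contrasts use Welch
two-sample t-tests with Welch–Satterthwaite degrees of freedom (checked
against the pooled t in the equal-variance, equal-n limit).

The design's a-priori sample size uses the exact noncentral-t power of a
two-sided paired t-test (df = n−1, noncentrality d·√n), scanning n upward;
d = 0.444 at α = 0.05 and power 0.80 yields n = 42, with the two-sided,
dependent-means (d_z) interpretation.

## The synthetic cohort generator

Agents respond with the generating model's own teacher-forced policy: on
each valid trial the emitted response is the model's prediction — carried
value equal to the agent's previous emitted response — plus Gaussian noise
(σ = 0.10 on the oriented scale, clamped to [0, 1]). The oriented response
is mapped back through the orientation and the affine normalisation to a
signed distance; the outcome is then drawn from the arm's schedule given the
movement direction. Invalid trials are injected with probability 0.01 per
trial. With σ = 0 and no invalid trials, the emitted series satisfies the
fitted model's defining recursion exactly, so refitting recovers the truth
with SSE ≈ 0 — the pipeline's core self-consistency check.

Populations are truncated normals on [0, 1]. Defaults per arm:

- **social_conflict**: valence-split model (5) with α⁺ ~ (0.38, 0.39),
  α⁻ ~ (0.01, 0.02), β ~ (0.67, 0.18), V1_in ~ (0.70, 0.24),
  V1_out ~ (0.80, 0.21) — the fitted conflict-cohort means and s.d.s.
- **nonsocial_control**: single-rate baseline (1) with α ~ (0.01, 0.02) and
  V1 ~ (0.53, 0.14) for both symbols — that arm's winning-model means.
- **social_control**: single-rate baseline with α ~ (0.01, 0.02) and equal
  midpoint initial values V1 ~ (0.50, 0.14) for both symbols (see below).

Impression ratings (1–7 Likert, rounded by default) carry a stable group
main effect — in-group mean 4.2, out-group 3.7, s.d. 1.1 — with post-task
means equal to pre-task means by construction, so any pre/post change in a
simulated cohort is pure sampling noise. In-group identification scores are
drawn at 4.3 ± 1.1.

### What the generator does and does not emulate

The generator reproduces the statistical structure the analysis chain
assumes: biased initial values, reinforcement-driven updating under the
arm's schedule, Gaussian response noise of roughly the magnitude implied by
the fitted goodness of fit, occasional invalid trials, and null pre/post
impression dynamics. Passing tests therefore demonstrate that the
estimation, comparison and recovery machinery works on data obeying the
models' own assumptions; they say nothing about response kinematics, timing,
sequential strategies or any behaviour outside the model family.

Two generative limitations are worth stating plainly:

- **The teacher-forced policy is a clamped random walk.** Because each
  prediction anchors on the previous *emitted* response, response noise
  accumulates, and clamping at [0, 1] biases the walk toward 0.5 whenever
  values sit off-centre. A biased-V1 population under the uninformative
  50/50 schedule therefore drifts systematically on the raw-distance scale
  even with α near 0. This is why the social-control population uses equal
  midpoint initial values: with V1 centred at 0.5 the policy is symmetric
  under clamping and the per-symbol slope contrast is null, matching the
  flat control-arm behaviour the generator is meant to emulate. The price is
  that the control arm's *trial* data carry no initial in-group bias (its
  impression ratings still do).
- **Forward simulation of fitted means compounds β.** A response weight
  β < 1 inside the value recursion multiplies the carried value on every
  encounter when the model generates its own data, pulling both symbols'
  oriented values toward a low fixed point. Cohorts forward-simulated at the
  fitted conflict means consequently do not reproduce the direction of the
  empirical per-symbol drift (their raw-scale slope ordering inverts), even
  though they are exactly the right substrate for parameter and model
  recovery, where the fitted model's own assumptions are the point.

Simulated final positions may overshoot the nominal [0, 1] guide line by up
to 0.2 when a large emitted distance combines with an off-centre start. The
response variable is the distance and its oriented transform, not the
position; clamping positions would break the σ = 0 self-consistency
guarantee, so positions are treated as derived metadata.

## Recovery studies

Parameter recovery simulates agents from a known population, refits, and
tabulates bias, RMSE and truth–estimate Pearson correlation per parameter.
At the conflict-arm population with σ = 0.1 and 120 trials, α⁺, β and both
V1s recover with correlations around 0.9; α⁻ recovers weakly *by
construction* — its truth is ≈ 0.01 against the lower bound, so there is
almost no variance to recover — and is reported rather than thresholded.

Model recovery simulates cohorts per generating model, fits all six models
to each cohort, and records the summed-BIC winner in a confusion matrix.
Cohort size 16 and 6 restarts per fit keep the study desk-scale; the
valence-split generator uses a tight α⁺ spread (0.40 ± 0.10) so the
generating structure is clearly expressed in every cohort. Under these
conditions selection is essentially perfect: valence-split cohorts are won
by model 5 and single-rate cohorts by the baseline model.

## Numerical and degenerate-input conventions

- Zero displacement after movement counts as avoidance (approach is
  strictly distance > 0) and outcomes are undefined for invalid trials.
- Symbol sequences are drawn position by position, uniformly over admissible
  next symbols under a feasibility look-ahead. Plain rejection sampling of
  balanced permutations is hopeless here — arrangements of 40 trials with a
  maximum run of 2 are far too rare — while the look-ahead sampler never
  stalls on a satisfiable constraint and raises explicitly on an infeasible
  one.
- All randomness fans out from one master seed through NumPy seed
  sequences: per-agent, per-fit-cell and per-stage streams are spawned
  deterministically, so every table is bit-reproducible from
  (config, seed).
- Constant observations (zero variance) make R² undefined; the fitter
  records NaN and `r_squared` raises.
- Welch's test requires n ≥ 2 per sample and positive variance in at least
  one sample.

## Known limitations

- Only the family's own response model (Gaussian noise on the oriented
  scale) is simulated; there is no lapse, perseveration or timeout process.
- The affine distance normalisation with a global half-width D = 0.6 is one
  reasonable convention (documented, configurable); per-trial reachable
  ranges would give a different mapping.
- Latent-mode fitting is provided but not the default; mixed or hierarchical
  estimation is out of scope.
- The per-participant OLS slope descriptive is a deliberate lightweight
  stand-in for mixed-effects regression of trial-level data.
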