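# Methods

This note documents the models the package implements, the choices made
where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.  Nothing here reports an empirical
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## The task and its statistics

Participants estimate an angular location on a circle, report
confidence on a 1–6 scale, see a partner's estimate of the same target,
and on alternating trials either revise their own estimate (revision
trials) or watch the partner revise (observation trials).  A session is
4 blocks of 30 trials, one partner per block, the partners realising
the 2×2 design of cover story (human / computer) × susceptibility
(susceptible / insusceptible).

All geometry is wrap-aware and in degrees.  Angles live in [0, 360)
(half-open); arc distances in [0, 180].  The central statistic is the
**shift fraction**: for a reviser with initial estimate *x*, revised
estimate *y*, and counterpart initial estimate *z*,

    shift = arc(x, y) / arc(x, z)  ∈ [0, 1].

Computed for the participant it is the **revision** r_t; computed for
the partner it is the **influence** inf_t.  When the two initial
estimates coincide the statistic is undefined; such trials are dropped
with a logged count (with continuous angles this is a measure-zero
event).  Revised estimates are constrained by the task to the shorter
arc between the two initial estimates; antipodal ties (exactly 180°
apart) resolve counter-clockwise, a fixed deterministic rule chosen for
testability.

## Partner construction

Partner first estimates are von Mises around the target with
concentration κ = 7.4, except when the participant reported confidence
5 or 6: then the partner's estimate is uniform within ±20° (behavioural
setting) or ±50° (fMRI setting) of the participant's own estimate,
applied wrap-aware on the circle.  Influence draws are U[0, 0.2] for
insusceptible partners and the mixture 0.5·U[0.7, 1] + 0.2·U[0.3, 0.7]
+ 0.3·U[0, 0.3] (analytic mean 0.57) for susceptible ones.

The drawn influence value is turned into a revised partner estimate by
shorter-arc linear interpolation towards the participant's initial
estimate.  This mapping is chosen so that the *recorded* influence
statistic equals the drawn value by construction, which the tests
verify as a round-trip property.

## The synthetic participant cohort

The behavioural generator exists so that the analysis models can be
validated by parameter recovery.  Each agent:

* perceives the target with von Mises noise, κ_subject = 1.0 by
  default — calibrated once so the mean absolute error (≈ 57°) sits in
  the band the task's difficulty produces in practice; this is a
  calibration, not ground truth;
* reports confidence by thresholding a noisy read-out of its own error
  (−|error| + N(0, 10°)) against 5 fixed cutpoints (−127.1, −84.3,
  −53.0, −26.3, −7.1), calibrated once to give level shares of roughly
  (.10, .15, .20, .25, .20, .10).  Any monotone error→ordinal map would
  do; the constraint that matters is that levels 5–6 occur with
  substantial probability, because they trigger the partner's
  high-confidence branch.  The confidence model is a modelling
  invention: the task paradigm itself specifies no perceptual model;
* on revision trials draws its revision fraction from a linear mixed
  model and truncates to [0, 1] (the task rule: the revised estimate
  must lie between the two initial estimates).

Two generative modes mirror the two analysis models:

* **per-condition** (default): r = β₁ + β₂·c + β₃·inf + β₄·c·inf + ε
  with normalised confidence c = confidence/6 and inf the influence
  exerted on the immediately preceding observation trial; random
  intercept and random c and inf slopes per participant (independent
  Gaussians); separate coefficient sets per partner type.  Reference
  slopes: human (−0.3, 0.17, −0.21), computer (−0.37, 0.01, −0.03).
* **pooled**: one 8-coefficient set over both conditions with a
  condition dummy (1 = human, 2 = computer) and all interactions;
  random intercept and confidence slope only.  Reference coefficients
  (intercept, c, inf, cond, c·inf, c·cond, inf·cond, c·inf·cond) =
  (0.65, −0.33, 0.11, 0.07, −0.4, −0.1, −0.09, 0.21).

Intercepts are not part of the reference slope sets and were chosen
(0.5 human, 0.55 computer, 0.65 pooled) so the linear predictor stays
well inside [0, 1] across the design.  Likewise the noise defaults —
random-effect SDs 0.03 (intercept), 0.03 (confidence), 0.025
(influence) and residual SD 0.035 — are deliberately moderate: the
[0, 1] truncation the task forces is a censoring nonlinearity, and at
larger noise scales it attenuates the recovered influence-related
coefficients by up to tens of percent (the pooled model is most
vulnerable because the condition dummy of 1/2 doubles effective
slopes).  At the shipped scales the linear predictor sits ≳ 3.8 SD from
both bounds, truncation is essentially never active, and recovery is
unbiased to within Monte-Carlo error.  The cost is mild: between-person
heterogeneity is smaller than a real cohort's, which the recovery
claims should be read against.

`reciprocity_ramp` (default 0) optionally grows the influence slope
within a block, emulating reciprocity that builds up over time.  The
default generator is stationary: trial-order effects in the real
phenomenon (revision drifting up for susceptible and down for
insusceptible partners) are not in the default data, so sliding-window
*trends* are flat in expectation and only the susceptibility *level*
contrast is present.  Tests that need the trend switch the ramp on.

In per-condition mode, random effects are drawn independently per
condition (each condition's model is fitted separately, so nothing
links them); in pooled mode a single intercept and confidence-slope
deviation are shared, matching that model's random structure.

## Mixed-model estimation and inference

Both revision models are estimated by REML through statsmodels'
`MixedLM` with the random structure expressed as a random intercept
plus independent variance components (diagonal random-effect
covariance).  On top of the REML variance estimates the package
computes its own generalised-least-squares fixed-effect covariance and
**Satterthwaite denominator degrees of freedom**: df_j = 2·Var(β̂_j)² /
Var̂(Var(β̂_j)), with the delta-method variance obtained from the
numerical gradient of Var(β̂_j) in the variance parameters and the
inverse observed information of the restricted log-likelihood (central
finite differences; one-sided at the boundary of the parameter space).
The test suite pins this layer against `lmerTest` on identical data
(estimates to 2·10⁻⁴, df to 5%).  Wald F statistics use numerator df 1;
confidence intervals use the t quantile at the Satterthwaite df.  Bulk
simulation loops may request `dof="residual"` (df = n − p), which
changes nothing about the estimates.

A non-converged or non-positive-definite fit triggers one refit with
the random slopes dropped, flagged `simplified` in the output.  BIC is
computed from the REML log-likelihood, as the model-comparison the
analysis mirrors did.  Holm–Bonferroni adjustment is applied within one
model fit, family = the non-intercept fixed effects; raw p-values are
always reported alongside.

The Wilcoxon signed-rank helper reports W⁺ (sum of positive ranks),
with exact p for n ≤ 25 without ties and the continuity-corrected
normal approximation otherwise.  Exactly-zero differences are
discarded; if none remain the test is degenerate and raises rather
than fabricating p = 1.

## Synthetic BOLD

The event schedule lays out each trial as: partner photo (2 s),
stimulus stream (1.38 s), initial estimate (lognormal RT), confidence
report (RT), jitter, partner estimate (1.5 s), jitter, revision /
observation phase (RT), outcome display (3 s), jitter — jitters
uniform on [1.5, 4.5] s, TR = 3.74 s, runs padded to whole TRs
(≈ 11–13 min per run with the default RT parameters).

ROI signals are impulse responses: each event contributes
amplitude × HRF(t − onset), where the HRF is a fixed double-gamma
(gamma-density difference, peak ≈ 5 s, undershoot ≈ 15 s at 1/6 depth,
unit peak) and the amplitude is a baseline plus a linear function of
standardised trial modulators (the injected encoding weights are the
recovery ground truth).  No basis-set or derivative terms: the analysis
operates on raw time courses, so a single canonical shape suffices.
Noise is AR(1) (ρ = 0.3, SD 0.3) plus white measurement noise (SD 0.1)
plus a small admixture of 6 smooth random-walk motion regressors, so
the residualisation step does real work.  Event durations are metadata:
response amplitude does not scale with duration.

One scope rule matters: the analysis standardises modulators per
participant and condition (pooling that condition's two runs), so the
generator standardises the encoded modulators over the same scope.
Injecting with per-run z-scores leaves run-mean offsets that leak into
correlated regressors — the block regressor especially — and turns
nominally null coefficients systematically non-zero.  The test suite
checks the null terms stay at chance.

The coupled-pair generator for PPI ground truth builds
target(t) = gain(t)·seed(t) + noise with gain = α + Σ γ_m·z-modulator
during a window (default 8 s) from each coupling event's onset.  The
confidence × influence product modulator is constructed as the product
of the two z-scored factors — matching how the PPI regression builds
its interaction regressors; z-scoring the raw product instead makes the
injected coupling load on the seed × confidence term.

## ROI pipeline

Per run: OLS residualisation on the 6 motion regressors plus intercept
(rank-deficient nuisance columns are dropped with a warning); cubic
spline upsampling from TR to 0.2 s (pinned by fixture tests — any
smooth interpolant would serve, the choice is stabilised, endpoints are
never extrapolated); epoch extraction of exactly 75 samples starting
1.0 s before each onset, aligned to the nearest 0.2 s grid sample
(alignment error ≤ 0.1 s), edge epochs dropped with a warning.

The per-timepoint GLM regresses the epoch matrix column-wise on an
intercept plus z-scored modulators — for revision-locked analyses:
confidence, previous-trial influence, their product, log revision RT,
and block number (1–4, entered numerically then standardised like the
rest).  Modulators are not orthogonalised; constant modulators yield
NaN coefficient rows with a warning.  Trials are pooled across the two
same-condition runs by default (a per-run fit then averaging is
possible through the API by calling per run).

### Leave-one-out peak inference and its calibration

For each participant, the group-mean beta curve *excluding* them is
computed; the peak is the time of maximal absolute mean over the full
75-point window (earliest sample on ties); the left-out participant's
beta at that time is collected, and the collected values are summarised
by the signed-rank statistic W⁺ against zero, two-sided.

The leave-one-out read-out makes each collected value *individually*
unbiased, but the collected values are not independent: every peak is
selected on (nearly) the same group curve, so under a no-signal null
the values share a selection-conditioned shift.  Referring W⁺ to the
ordinary Wilcoxon table is therefore badly anticonservative when the
curves are pure noise — measured here at ≈ 32% rejections at nominal
α = 0.05 for 20 participants × 75 iid-normal time points (≈ 17% for
HRF-smooth noise).  The package therefore calibrates the p-value
against the **exact sign-flip null of the entire procedure**: each
participant's whole curve is multiplied by a Rademacher sign (valid
because, under the null, participant curves are independent and
symmetric about zero), the LOO read-out and W⁺ are recomputed for each
of 1,000 internally-seeded flips, and the two-sided tail probability is
reported with add-one smoothing (p resolution 0.002).  The
independence-assuming table p is retained in the result (`table_p`)
for comparison with conventional reports.  With the calibrated p, the
iid null rejects at ≈ α, and detection of the injected encodings at
n = 20 remains essentially certain at the shipped signal-to-noise
defaults.

### PPI and the connectivity surface

At each epoch time point, the target region is regressed on the seed
region's activity at the same time point, confidence, influence, their
product, and all seed × modulator interactions including the triple
term (a flag drops it).  Seed activity and modulators are z-scored
across trials; a consequence is that rescaling the seed signal leaves
all coefficients unchanged (scale invariance replaces the 1/c scaling a
raw-units design would show).  Group inference per term uses the same
calibrated LOO procedure.  The connectivity surface evaluates the
modulator-dependent seed slope b_seed + b_(s×c)·c + b_(s×i)·i +
b_(s×c×i)·c·i — coefficients averaged over epoch times 2–3 s
post-onset (6 samples) — on the z-score grid [−2, 2] × [−2, 2], step
0.25.

## Problem sizes

The recovery experiments run at the full cohort scale where that is cheap
(cohorts of 60 participants; 100 replicate cohorts for the recovery
averages) and at 20 synthetic participants for the fMRI-side
experiments, matching the scanner cohort.  The null calibration of the
LOO test uses 500 replicate draws.  The end-to-end pipeline demo
defaults to 12 behavioural + 8 fMRI participants so a full run stays
interactive.

## Known limitations

* The revision noise model is truncated-Gaussian; at noise scales well
  above the defaults, truncation attenuates recovered coefficients (by
  design acknowledged, not corrected).
* Real BOLD physiology — nonlinear HRF summation, per-region HRF
  variability, physiological noise spectra, scanner drift beyond
  AR(1) — is out of scope; recovery results certify the pipeline's
  statistics, not real-data effect sizes.
* Partner photographs, payoff presentation, and end-of-block
  performance ratings are not modelled; the stimulus stream appears
  only as timing metadata.
* The sliding-window trend analysis will show flat trends on default
  cohorts (see `reciprocity_ramp` above).
* Satterthwaite df use finite differences on the variance scale; at
  boundary estimates (a variance component at zero) the df fall back
  conservatively to the residual df.
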