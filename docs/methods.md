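# Methods

## The generative observer model

Each trial of the 2AFC task is modelled with equal-variance Gaussian
signal detection theory.  The stimulus class s ∈ {0, 1} places the
type-1 decision variable at x₁ ~ N(±d′/2, 1); the choice is x₁ > c.
Stimulus difficulty enters through a psychometric link: expected
accuracy is a logistic function of the stimulus level spanning
55–95 % over the legal range (brightness 128–256 for perception,
encoding set size for memory), converted to d′ by inverting the
unbiased 2AFC accuracy formula acc = Φ(d′/2).  The midpoint of the
span is exactly 75 %, so the psychometric midpoint is the titration
target.  Accuracy increases with brightness and decreases with set
size.

Confidence comes from a second, metacognitively noisy decision
variable.  The meta-d′ measurement model asks what sensitivity an
SDT-ideal rater would need to produce the observed response-conditional
confidence distributions, holding the type-1 criterion at its
d′-relative position (c′ = c/d′).  The generator samples the exact
generative counterpart of that model: given the true class and the
realised response, x₂ is drawn from N(±m·d′/2, 1) truncated to the
response's side of the scaled criterion c·m, and binned by three
ordered type-2 criterion offsets per side.  Consequently the fitted
meta-d′/d′ converges to the generating efficiency m as n grows, with
no free calibration constant.  With `meta_ratio=None` the criteria are
applied directly to x₁ itself — the ideal metacognitive observer,
whose fitted ratio is 1.

This is a measurement-matched stand-in, not a mechanistic claim about
how feedback changes confidence; no generative account of learning is
implied.

## Staircase titration

Perceptual difficulty is controlled by two interleaved weighted
staircases acting on integer brightness (one step = one unit on the
128–256 scale, matching the difficulty formula's integer range).  The
rules alternate strictly trial by trial and each keeps its own streak
of consecutive correct responses on its own trials.  Rule 1 decreases
brightness by 2 once its streak reaches 2; rule 2 decreases by 3 once
its streak reaches 3; either rule increases brightness by 4 after an
error, which also breaks the streak.  The streak counter is *not*
reset after a decrease fires: past the quota, every further correct
response fires another decrease.  This is what distinguishes the
procedure from a traditional n-down/1-up.  Setting the expected level
drift to zero gives the equilibrium accuracy: for rule 1,
−2p² + 4(1 − p) = 0 (p ≈ 0.732); for rule 2, −3p³ + 4(1 − p) = 0
(p ≈ 0.716); interleaved, the procedure settles near 72.5–73.5 %
correct, i.e. within the ±3-point band around the 75 % target.  (A
multiples-of-the-quota reading of the counter would instead equilibrate
at 80 %, and a never-resetting streak at 62 % — both incompatible with
the stated convergence target, which is why the streak reading was
adopted.)

The memory set-size staircase adjusts once per 27-trial block using the
mean accuracy of the previous two blocks: +1 item above 75 %, −1 below
70 %, no change in the dead band (and no change at exactly 75 %).  The
displayed set size is floored at two items while the underlying
staircase value is unbounded below; both are tracked.  The memory-words
task uses a fixed set size of 54.

## Feedback scoring

Experimental-group feedback scores calibration with the quadratic
scoring rule.  Ratings 1–4 map linearly to subjective probability
p = −1/3 + confidence/3 ∈ {0, ⅓, ⅔, 1} and each trial scores
1 − (accuracy − p)², i.e. one minus the Brier score: maximal for
confident-correct and unconfident-wrong trials, and a proper scoring
rule on the discrete scale (verified exhaustively in the tests).
Control-group feedback scores achieved difficulty,
128 − (brightness − 128) ∈ [0, 128].  Block scores (27-trial means)
convert to points through Φ((s − μ)/σ) scaled to a configurable
maximum (default 100, rounded to integers; the points scale and
rounding are package choices), where (μ, σ) are ML Gaussian fits to a
feedback-free pilot distribution of block scores — here produced by a
drift-free simulated cohort — which equates expected points across the
two feedback types.

## Meta-d′ estimation

Fits operate on the 2 (class) × 2 (response) × 4 (confidence) count
table.  A uniform padding of 1/8 (one over twice the number of rating
levels) is added to every cell before fitting to avoid zero-cell
degeneracies; it is applied identically to all groups and conditions.
Type-1 d′ and c come from the padded marginal hit/false-alarm rates.
The meta-level likelihood is multinomial over the response-conditional
confidence distributions implied by meta-d′ and six type-2 criteria,
parameterised as cumulative positive increments (log-scale) away from
the scaled type-1 criterion so ordering is guaranteed throughout
optimisation.  L-BFGS-B runs from three deterministic starts
(meta-d′ ∈ {0.5, 1, 1.5} × d′) with an objective tolerance of 1e-8;
the best likelihood wins.  meta-d′ may come out negative (confidence
anticorrelated with accuracy); the ratio is still reported but its log
is NaN, and such cells drop out of log-scale analyses.  Equal-variance
SDT is assumed throughout; no unequal-variance or response-specific
extension is provided.

The test suite checks the optimiser against an exhaustive two-stage
grid search over (meta-d′, six criteria).  On very small tables
(N ≤ 40) the profile likelihood in meta-d′ is flat to within ~0.05
nats over ±0.15, which bounds how precisely *any* grid can localise
the optimum; the sharp check is that the MLE's likelihood is never
worse than the best grid point.

## Latent change score models

With the pre→post loading fixed at 1, the latent change equals the
observed difference and the model is a structured mean/covariance
model for (P_pre, P_post, M_pre, M_post):

    ΔP = α_P + β_P·P_pre + γ_P·M_pre + e_P
    ΔM = α_M + β_M·M_pre + γ_M·P_pre + e_M

with free pre means, variances and covariance, change-residual
variances and their covariance ("correlated change").  β is
self-feedback (regression to the mean, baseline dependence, ceiling),
γ cross-domain coupling.  Both groups are fitted simultaneously by
Gaussian ML on per-group sufficient statistics (N-divisor
covariances); any parameter can be constrained equal across groups or
fixed.  The default bivariate constraint set equates pre means, the
pre covariance and the memory pre variance across groups while leaving
the perception pre variance group-specific; the fully free model is
saturated (28 parameters, 28 moments, df = 0), and the default set
gives df = 4.

Variances are optimised on the log scale, covariances directly, with a
positive-definiteness guard on the implied covariance (a Cholesky
parameterisation was rejected because the natural-parameter equality
constraints — e.g. equal covariance with group-specific variance — do
not correspond to shared Cholesky entries).  Starting values come from
per-group OLS of the observed changes on the pre scores; a Nelder-Mead
polish follows the quasi-Newton run.  Standard errors are square roots
of the inverse observed information (central-difference Hessian of the
log-likelihood in the natural parameters).

Fit statistics: T = −2(LL_model − LL_saturated) with df = moments −
free parameters; RMSEA = √(G · max(T − df, 0)/(df (N − 1))) for G = 2
groups, with a 90 % CI from inverting the noncentral χ² distribution;
CFI against the per-group independence baseline (free means and
variances, zero covariances, computed analytically); SRMR as the
N-weighted average of per-group root-mean-square standardised
residuals of covariances and means.  Nested models are compared by the
likelihood-ratio difference test.  Estimation is plain (non-robust)
ML; sandwich standard errors are not implemented because the
complete-case synthetic data do not require robustness.

## Mediation of training dynamics

Per participant: X = group (0 control, 1 experimental), M = change in
mean confidence from pretraining to the first training session (the
bias step is immediate, so this window captures it), Y = change in
log(meta-d′/d′) from mid-training (session 5) to posttraining (the
efficiency gain is gradual, so this window isolates its later half).
Both windows are configurable.  Pre/post endpoints average the two
perception stimulus-type cells — the trained-stimulus restriction
belongs to the LCS analysis — which halves endpoint estimation
variance.  Paths are closed-form OLS (so c = c′ + ab holds to
machine precision); inference is a participant-level nonparametric
percentile bootstrap (default 2000 resamples, seeded and
bit-reproducible), with a normal-approximation z-test from the
bootstrap spread reported alongside.  BCa intervals are not
implemented.  At the complete null the percentile interval for the
product ab is conservative (coverage near 1), as expected for
product-of-coefficients tests.

`peak_change_session` returns the 1-based transition index of the
largest session-to-session increase, ties breaking to the earliest
transition; constant series return the first transition with a flag.

## The synthetic cohort

Defaults mirror the study design: 30 observers per group; session 1 =
four tasks (perception/memory × shapes/words) of 108 trials;
sessions 2–9 = 270 perceptual trials on the trained stimulus type
(alternately assigned shapes/words); session 10 mirrors session 1.
Feedback blocks are 27 trials.  A 60-trial titration block per
perception stimulus type precedes the pretraining session (not part of
the log) and brightness carries over between sessions.  Observer
heterogeneity: criterion ~ N(0, 0.1²), baseline efficiency
m ~ N(0.8, 0.12²) clipped to [0.3, 1.5], confidence criterion offsets
(0.4, 0.9, 1.5) with a shared jitter of SD 0.12.  Response times are
shifted lognormal (150 + logN(6.1, 0.55²) ms, clipped to 3000 ms) with
a 0.4 % admixture of fast guesses, so the RT exclusion filter removes
roughly 1 % of trials.

Experimental-group drifts: a confidence-bias step
b_i ~ N(0.45, 0.35²) truncated at 0, applied to the type-2 criteria
from session 2 onward (mean confidence rises by roughly +0.7 scale
points), and a linear efficiency gain of 0.20·b_i + N(0, 0.015²)
ratio-units per training session, retained at posttraining.  Coupling
the efficiency slope to the individual bias step is what produces a
positive indirect (bias → efficiency) pathway at the population level;
the magnitudes were fixed once, by simulation, so that the cohort
reproduces the qualitative training phenomena — an immediate bias
step, a gradual efficiency gain of ~0.3–0.5 log-units, calibration
improving in the experimental group only, and a mediation effect
detectable at n = 30/group in most replicates — given that a 108-trial
meta-d′ fit carries ~0.45 log-units of estimation noise.  Control
observers are drift-free.

What the generator does *not* emulate: learning within sessions,
feedback-driven trial-to-trial adaptation, lapses and attention
fluctuations, unequal-variance evidence, domain-specific metacognitive
resources (drifts apply across tasks, so cross-domain transfer is
built in rather than emergent), and any mechanism linking feedback to
confidence.  Passing tests therefore demonstrate that the estimators
recover known structure of this model, not that real training data
satisfy it.

## Exclusions

Trials with RT < 200 ms or > 2000 ms are dropped (retention is
boundary-inclusive at exactly 200 and 2000).  Participants are then
flagged, in order: accuracy outside 55–95 % in any
condition × session cell (applied to all sessions); mean difficulty
across all sessions more than 2.5 SD below the feedback-group mean;
the same rating on ≥ 95 % of a session's trials in three or more
sessions (not necessarily consecutive).  A participant is reported
under the first rule they trigger; all flagged participants are
removed.  Flags are computed once from the RT-filtered input, so the
procedure is deterministic and idempotent on its own output.

## Problem sizes and tolerances in the test suite

The suite exercises staircase convergence over 2000–4000 trials,
ideal-observer efficiency at 20 000 trials (tolerance ±0.1), recovery
medians over 100 observers × 1000 trials per generating ratio
(±0.1), grid-search cross-checks on 20 tables of 40 trials, LCS
recovery at 500–1000 per group (2 SE), null-mediation coverage over
200 replicates and the positive control over 5 simulated studies at
the default cohort size.  These sizes make every estimator's sampling
error small relative to its tolerance while keeping a full run of the
suite to a few minutes.
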