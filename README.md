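# metacog

Simulation and analysis tools for **adaptive metacognitive training**
studies: experiments that ask whether feedback on the *calibration* of
confidence judgments — rather than on task performance itself — can
improve people's ability to introspect about their own decisions, and
whether such improvements transfer to untrained stimuli and tasks.

The package is aimed at researchers in psychophysics and computational
cognitive modelling who need a tested, reproducible implementation of
the full analysis chain for trial-level confidence-rating data from
two-group, multi-session training designs (perception and recognition
memory, 2AFC, 4-point confidence scale), together with a generative
observer model for power analysis and method validation.

## What it computes

**Signal-detection observers** (`metacog.observers`).  Equal-variance
Gaussian SDT with a 4-point confidence rating derived from a second,
metacognitively noisy decision variable of sensitivity
meta-*d*′ = *m*·*d*′.  A full synthetic cohort reproduces the study
design: 10 sessions (pretraining, 8 training sessions of 270 trials,
posttraining), a 2×2 perception/memory × shapes/words task design,
staircase-titrated ~75 % accuracy, and group-specific training drifts
(an immediate confidence-bias step and a gradual efficiency gain in the
experimental group only).

**Adaptive staircases** (`metacog.staircase`).  Two interleaved
weighted staircases on stimulus brightness (2-down-by-2 / 3-down-by-3,
up-by-4, with non-resetting correct counters) and a block-wise
set-size staircase for recognition memory.

**Calibration scoring** (`metacog.calibration`).  The quadratic scoring
rule QSR = 1 − (accuracy − p)², with p = −1/3 + confidence/3 — one
minus the Brier score — plus the difficulty-based control feedback
(difficulty = 128 − (brightness − 128)) and the Gaussian-CDF transform
that converts block scores into reward points.

**Metacognitive efficiency** (`metacog.metad`).  Maximum-likelihood
meta-*d*′: the first-order sensitivity an SDT-optimal confidence rater
would need to produce the observed response-conditional confidence
counts, fitted jointly with six ordered type-2 criteria under the
c′ = c/d′ criterion convention.  Efficiency is meta-*d*′/*d*′ (1 =
confidence uses all choice-relevant evidence); analyses use
log(meta-*d*′/*d*′).

**Latent change score models** (`metacog.lcs`).  Two-group univariate
and bivariate LCS models of pre/post calibration:
ΔY = α + β·Y_pre (+ γ·X_pre) + e with the pre→post loading fixed at 1,
fitted by Gaussian maximum likelihood on group mean/covariance
structures with per-parameter equality constraints, standard errors
from the observed information, and χ², RMSEA (90 % CI by noncentrality
inversion), CFI and SRMR fit statistics.

**Bootstrap mediation** (`metacog.mediation`).  Nonparametric
percentile-bootstrap mediation of feedback type → early confidence
shift → late efficiency gain (paths a, b, c, c′, indirect effect ab).

**Pipeline** (`metacog.pipeline`).  Response-time filtering (< 200 ms or
> 2000 ms), the four participant exclusion rules, per-session summary
tables, group contrast tables, the artificial confidence-bias-shift
simulation, and `run_study` for a fully seeded end-to-end run.

## Worked example

```python
import numpy as np
from metacog import (ObserverParams, simulate_sdt_trials, counts_from_trials,
                     fit_meta_d, run_titration)

# an observer whose confidence uses only 70% of the decision evidence
rng = np.random.default_rng(7)
trials = simulate_sdt_trials(20000, d_prime=1.5, criterion=0.0,
                             conf_criteria=(0.4, 0.9, 1.5),
                             meta_ratio=0.7, rng=rng)
fit = fit_meta_d(counts_from_trials(trials))
print(f"d' = {fit.d_prime:.3f}   meta-d' = {fit.meta_d_prime:.3f}")
print(f"meta-d'/d' = {fit.ratio:.3f}   log ratio = {fit.log_ratio:.3f}")

# closed-loop titration of task difficulty
res = run_titration(ObserverParams(), 2000, rng=np.random.default_rng(1))
print(f"final brightness = {res.final_level}, "
      f"percent correct = {100*res.percent_correct:.1f}%")
```

Output:

```
d' = 1.530   meta-d' = 1.056
meta-d'/d' = 0.690   log ratio = -0.371
final brightness = 189, percent correct = 73.2%
```

The fitted *d*′ recovers the generating sensitivity (1.5); meta-*d*′ is
the lower sensitivity (≈ 0.7 × *d*′) implied by the noisier confidence
ratings, so the efficiency ratio recovers the generating 0.7.  The
staircase holds accuracy near the ~75 % target, converging on the
brightness where the two interleaved update rules balance.

A complete simulated study (cohort → exclusions → summaries → LCS →
mediation → bias-shift simulation) runs from the command line:

```bash
metacog run-study --seed 5 --out study_out/
# LCS chi2(4) = 2.32; mediation ab = 0.4740 CI [0.1805, 0.7482]
```

writing `trials.csv`, `exclusions.csv`, `session_summary.csv`,
`group_contrasts.csv`, `lcs_params.csv`, `mediation.json` and
`bias_shift.csv` into `study_out/`.  Subcommands `simulate`, `titrate`,
`score`, `fit-metad`, `fit-lcs` and `mediate` expose the individual
stages.

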