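"""Generative signal-detection observers for metacognitive-training cohorts.

This module simulates trial-level behaviour of observers performing
two-alternative forced-choice (2AFC) perception and recognition-memory
tasks with 4-point confidence ratings.  The first-order decision follows
an equal-variance Gaussian SDT model; confidence is produced by a second,
metacognitively noisy decision variable whose effective sensitivity is
``meta_ratio * d'``, so that the meta-d' measurement model (see
:mod:`metacog.metad`) recovers the generating efficiency at large n.

A full study cohort is two groups (experimental / control) observed over
10 sessions: one pretraining session (4 tasks x 108 trials), eight
training sessions of 270 perceptual trials on the trained stimulus type,
and one posttraining session mirroring pretraining.  Experimental-group
observers carry training-induced drifts: a step increase in confidence
(a downward shift of the type-2 criteria) from the first training
session onward, and a gradual, session-linear gain in metacognitive
efficiency.  Control observers are drift-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .staircase import BrightnessStaircase, SetSizeStaircase

__all__ = [
    "ObserverParams",
    "TrialRecord",
    "CohortConfig",
    "psychometric",
    "psychometric_accuracy",
    "simulate_trial",
    "simulate_sdt_trials",
    "simulate_cohort",
]

# Accuracy span of the psychometric link over the legal stimulus range.
# The midpoint of the span is exactly the 75%-correct titration target.
ACC_FLOOR = 0.55
ACC_CEIL = 0.95

BRIGHTNESS_MIN = 128
BRIGHTNESS_MAX = 256

#: number of confidence levels on the rating scale
N_CONF = 4

_TINY = 1e-12


@dataclass(frozen=True)
class ObserverParams:
    """Generative description of one simulated participant.

    Parameters
    ----------
    d_prime
        Nominal first-order sensitivity (unitless, equal-variance SDT);
        used when trials are simulated at a fixed sensitivity rather
        than through the psychometric link.
    criterion
        Type-1 decision criterion c.
    meta_ratio
        Target metacognitive efficiency meta-d'/d' (> 0); 1 means
        confidence uses all choice-relevant evidence.
    conf_criteria
        Three strictly increasing type-2 criterion offsets (distances
        from the type-1 criterion, per response side) binning the
        metacognitive evidence into the four confidence levels.
    conf_bias_drift
        Step shift of the type-2 criteria toward the criterion applied
        from the first training session onward (higher values = more
        confident ratings).  Zero for control observers.
    efficiency_drift
        Per-session additive change of ``meta_ratio`` accrued over the
        eight training sessions.  Zero for control observers.
    psychometric_slope, psychometric_midpoint
        Logistic link from brightness to accuracy for the perception
        task (midpoint = the 75%-correct brightness).
    memory_slope, memory_midpoint_shapes, memory_midpoint_words
        Logistic link from encoding set size to accuracy for the
        memory task (accuracy decreasing in set size).
    group
        ``"experimental"`` or ``"control"``.
    seed
        Per-observer RNG seed.
    """

    d_prime: float = 1.35
    criterion: float = 0.0
    meta_ratio: float = 0.8
    conf_criteria: tuple[float, float, float] = (0.4, 0.9, 1.5)
    conf_bias_drift: float = 0.0
    efficiency_drift: float = 0.0
    psychometric_slope: float = 0.1
    psychometric_midpoint: float = 192.0
    memory_slope: float = 0.4
    memory_midpoint_shapes: float = 6.0
    memory_midpoint_words: float = 54.0
    group: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.d_prime):
            raise ValueError("d_prime must be finite")
        if self.meta_ratio <= 0:
            raise ValueError("meta_ratio must be positive")
        cc = tuple(self.conf_criteria)
        if len(cc) != N_CONF - 1 or any(
            b <= a for a, b in zip(cc, cc[1:])
        ) or cc[0] <= 0:
            raise ValueError("conf_criteria must be strictly increasing and positive")


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial of the 2AFC task with a confidence rating."""

    participant_id: str
    session: int
    phase: str  # pre | train | post
    domain: str  # perception | memory
    stimulus_type: str  # shapes | words
    block: int
    trial: int
    stimulus_level: float
    true_class: int
    response: int
    accuracy: int
    confidence: int
    rt_ms: float

    def __post_init__(self) -> None:
        if self.confidence not in (1, 2, 3, 4):
            raise ValueError("confidence must be in 1..4")
        if self.accuracy != int(self.response == self.true_class):
            raise ValueError("accuracy inconsistent with response/true_class")


# ---------------------------------------------------------------------------
# Session-dependent effective parameters
# ---------------------------------------------------------------------------

def _session_meta_ratio(params: ObserverParams, session: int) -> float:
    """Effective meta-d'/d' at a given session (1..10).

    Efficiency accrues linearly over the eight training sessions
    (sessions 2-9) and is retained at posttraining.
    """
    accrued = min(max(session - 1, 0), 8)
    return max(params.meta_ratio + params.efficiency_drift * accrued, 0.05)


def _session_conf_offsets(params: ObserverParams, session: int) -> np.ndarray:
    """Effective type-2 criterion offsets at a given session.

    The confidence-bias drift is a step change: from the first training
    session (session 2) onward the offsets move toward the criterion by
    ``conf_bias_drift``, clipped to remain positive and ordered.
    """
    offs = np.asarray(params.conf_criteria, dtype=float)
    if session >= 2 and params.conf_bias_drift:
        shifted = offs - params.conf_bias_drift
        # keep strictly ordered and positive after a large shift
        floor = np.array([0.05, 0.10, 0.15])
        offs = np.maximum(shifted, floor)
    return offs


# ---------------------------------------------------------------------------
# Psychometric link
# ---------------------------------------------------------------------------

def psychometric_accuracy(
    params: ObserverParams,
    stimulus_level: float,
    domain: str = "perception",
    stimulus_type: str = "shapes",
) -> float:
    """Expected 2AFC accuracy at a stimulus level.

    A logistic function of the level spanning [ACC_FLOOR, ACC_CEIL]:
    accuracy increases with brightness (brighter lines are easier to
    discriminate) and decreases with memory set size (more encoded
    items are harder to recognise).  At the midpoint the expected
    accuracy is exactly the midpoint of the span, i.e. 75% correct.
    """
    if not math.isfinite(stimulus_level):
        raise ValueError("stimulus_level must be finite")
    if domain == "perception":
        x = params.psychometric_slope * (stimulus_level - params.psychometric_midpoint)
    elif domain == "memory":
        mid = (
            params.memory_midpoint_words
            if stimulus_type == "words"
            else params.memory_midpoint_shapes
        )
        x = -params.memory_slope * (stimulus_level - mid)
    else:
        raise ValueError(f"unknown domain {domain!r}")
    return ACC_FLOOR + (ACC_CEIL - ACC_FLOOR) / (1.0 + math.exp(-x))


def psychometric(
    params: ObserverParams,
    stimulus_level: float,
    domain: str = "perception",
    stimulus_type: str = "shapes",
) -> float:
    """Effective first-order sensitivity d' at a stimulus level.

    Inverts the unbiased 2AFC accuracy formula acc = Phi(d'/2) applied
    to :func:`psychometric_accuracy`, so d' is monotone increasing in
    brightness and decreasing in set size.
    """
    p = psychometric_accuracy(params, stimulus_level, domain, stimulus_type)
    return 2.0 * float(ndtri(p))


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

def _truncnorm_side(
    rng: np.random.Generator,
    mu: np.ndarray,
    threshold: np.ndarray | float,
    upper_side: np.ndarray,
) -> np.ndarray:
    """Draw from N(mu, 1) truncated to one side of ``threshold``.

    ``upper_side`` selects, elementwise, the side above (True) or below
    (False) the threshold.  Inverse-CDF sampling.
    """
    a = ndtr(np.asarray(threshold) - mu)  # P(x < threshold)
    u = rng.random(np.shape(mu))
    q = np.where(upper_side, a + u * (1.0 - a), u * a)
    return mu + ndtri(np.clip(q, _TINY, 1.0 - _TINY))


def simulate_sdt_trials(
    n: int,
    d_prime: float,
    criterion: float = 0.0,
    conf_criteria: tuple[float, ...] = (0.4, 0.9, 1.5),
    meta_ratio: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` 2AFC trials from the equal-variance SDT model.

    Parameters
    ----------
    meta_ratio
        If ``None`` the confidence criteria are applied directly to the
        type-1 decision variable (the metacognitively ideal observer,
        whose fitted meta-d'/d' is 1).  Otherwise confidence is derived
        from a second decision variable of sensitivity
        ``meta_ratio * d_prime`` drawn on the chosen-response side of
        the scaled criterion, which matches the meta-d' measurement
        model exactly, so the fitted ratio converges to ``meta_ratio``.

    Returns
    -------
    DataFrame with columns true_class, response, accuracy, confidence.
    """
    if rng is None:
        rng = np.random.default_rng()
    tc = rng.integers(0, 2, size=n)
    mu1 = np.where(tc == 1, d_prime / 2.0, -d_prime / 2.0)
    x1 = rng.normal(mu1, 1.0)
    resp = (x1 > criterion).astype(int)
    offs = np.asarray(conf_criteria, dtype=float)
    if meta_ratio is None:
        x2 = x1
        c2 = criterion
    else:
        meta_d = meta_ratio * d_prime
        mu2 = np.where(tc == 1, meta_d / 2.0, -meta_d / 2.0)
        # the c' = c/d' convention: the meta-level criterion sits at the
        # same d'-relative position as the type-1 criterion
        c2 = criterion * meta_ratio
        x2 = _truncnorm_side(rng, mu2, c2, resp == 1)
    dist = np.abs(x2 - c2)
    conf = 1 + (dist[:, None] > offs[None, :]).sum(axis=1)
    return pd.DataFrame(
        {
            "true_class": tc,
            "response": resp,
            "accuracy": (resp == tc).astype(int),
            "confidence": conf,
        }
    )


def _draw_rt(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Shifted-lognormal response times in ms, clipped to (0, 3000].

    A small fraction of fast guesses (< 200 ms) and slow tail responses
    (> 2000 ms) is produced so the RT exclusion filter has work to do;
    the parameters are arbitrary but give ~1% filtered trials.
    """
    rt = 150.0 + rng.lognormal(mean=6.1, sigma=0.55, size=n)
    guess = rng.random(n) < 0.004
    rt[guess] = rng.uniform(80.0, 195.0, size=int(guess.sum()))
    return np.clip(rt, 1.0, 3000.0)


def simulate_trial(
    params: ObserverParams,
    stimulus_level: float,
    domain: str = "perception",
    session: int = 1,
    *,
    stimulus_type: str = "shapes",
    rng: np.random.Generator | None = None,
    participant_id: str = "obs",
    phase: str = "pre",
    block: int = 1,
    trial: int = 1,
) -> TrialRecord:
    """Simulate one trial of the 2AFC task at a given stimulus level.

    Sensitivity comes from the psychometric link; confidence from the
    session-drifted metacognitive model (see module docstring).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    d = psychometric(params, stimulus_level, domain, stimulus_type)
    m = _session_meta_ratio(params, session)
    offs = _session_conf_offsets(params, session)
    df = simulate_sdt_trials(
        1, d, params.criterion, tuple(offs), meta_ratio=m, rng=rng
    )
    row = df.iloc[0]
    return TrialRecord(
        participant_id=participant_id,
        session=session,
        phase=phase,
        domain=domain,
        stimulus_type=stimulus_type,
        block=block,
        trial=trial,
        stimulus_level=float(stimulus_level),
        true_class=int(row.true_class),
        response=int(row.response),
        accuracy=int(row.accuracy),
        confidence=int(row.confidence),
        rt_ms=float(_draw_rt(rng)[0]),
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design configuration for a simulated two-group cohort.

    Defaults reproduce the training-study design: 30 observers per
    group, 10 sessions (pre + 8 training + post), a 2x2 task design
    (perception/memory x shapes/words) with 108 trials per task at pre
    and post (432 trials each) and 270 perceptual trials per training
    session, feedback blocks of 27 trials, ~75% staircase-titrated
    accuracy.  Experimental-group drifts: an immediate confidence-bias
    step at the first training session whose size varies across
    observers, and a gradual efficiency gain proportional to each
    observer's bias shift (plus noise), which yields both the early
    bias / late efficiency dissociation and a positive indirect
    (bias -> efficiency) pathway at the population level.
    """

    n_per_group: int = 30
    trials_per_task: int = 108
    train_trials: int = 270
    block_length: int = 27
    n_sessions: int = 10
    # population distributions of observer parameters
    meta_ratio_mean: float = 0.8
    meta_ratio_sd: float = 0.12
    criterion_sd: float = 0.1
    conf_offset_jitter_sd: float = 0.12
    # experimental-group drifts
    conf_bias_drift_mean: float = 0.45
    conf_bias_drift_sd: float = 0.35
    efficiency_per_bias: float = 0.20
    efficiency_drift_sd: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_task % self.block_length:
            raise ValueError("trials_per_task must be a multiple of block_length")
        if self.train_trials % self.block_length:
            raise ValueError("train_trials must be a multiple of block_length")
        if self.n_sessions != 10:
            raise ValueError("the study design has 10 sessions (1 pre + 8 train + 1 post)")


def _spawn_observer(
    cfg: CohortConfig, group: str, idx: int, rng: np.random.Generator
) -> ObserverParams:
    base = np.array([0.4, 0.9, 1.5])
    jitter = rng.normal(0.0, cfg.conf_offset_jitter_sd)
    offs = np.maximum(base + jitter, [0.08, 0.2, 0.35])
    offs = tuple(np.sort(offs) + np.array([0.0, 1e-3, 2e-3]))
    meta = float(np.clip(rng.normal(cfg.meta_ratio_mean, cfg.meta_ratio_sd), 0.3, 1.5))
    if group == "experimental":
        bias = float(max(rng.normal(cfg.conf_bias_drift_mean, cfg.conf_bias_drift_sd), 0.0))
        eff = float(cfg.efficiency_per_bias * bias + rng.normal(0.0, cfg.efficiency_drift_sd))
    else:
        bias = 0.0
        eff = 0.0
    return ObserverParams(
        criterion=float(rng.normal(0.0, cfg.criterion_sd)),
        meta_ratio=meta,
        conf_criteria=offs,
        conf_bias_drift=bias,
        efficiency_drift=eff,
        group=group,
        seed=idx,
    )


def _perception_block_loop(
    params: ObserverParams,
    stair: BrightnessStaircase,
    n_trials: int,
    session: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Run ``n_trials`` perceptual trials through the brightness staircase."""
    m = _session_meta_ratio(params, session)
    offs = _session_conf_offsets(params, session)
    c = params.criterion
    levels = np.empty(n_trials)
    tcs = np.empty(n_trials, dtype=int)
    resps = np.empty(n_trials, dtype=int)
    confs = np.empty(n_trials, dtype=int)
    u_class = rng.random(n_trials)
    z1 = rng.standard_normal(n_trials)
    u_meta = rng.random(n_trials)
    for i in range(n_trials):
        level = stair.level
        d = psychometric(params, level, "perception")
        tc = int(u_class[i] < 0.5)
        mu1 = d / 2.0 if tc else -d / 2.0
        x1 = mu1 + z1[i]
        resp = int(x1 > c)
        acc = int(resp == tc)
        meta_d = m * d
        mu2 = meta_d / 2.0 if tc else -meta_d / 2.0
        c2 = c * m
        a = ndtr(c2 - mu2)
        q = a + u_meta[i] * (1.0 - a) if resp else u_meta[i] * a
        x2 = mu2 + ndtri(min(max(q, _TINY), 1.0 - _TINY))
        conf = 1 + int(np.sum(abs(x2 - c2) > offs))
        stair.update(acc)
        levels[i] = level
        tcs[i] = tc
        resps[i] = resp
        confs[i] = conf
    accs = (resps == tcs).astype(int)
    return {
        "stimulus_level": levels,
        "true_class": tcs,
        "response": resps,
        "accuracy": accs,
        "confidence": confs,
        "rt_ms": _draw_rt(rng, n_trials),
    }


def _memory_task(
    params: ObserverParams,
    stair: SetSizeStaircase | None,
    stimulus_type: str,
    n_trials: int,
    block_length: int,
    session: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Run a memory task; set size adapts per block (shapes) or is fixed (words)."""
    m = _session_meta_ratio(params, session)
    offs = _session_conf_offsets(params, session)
    out: list[pd.DataFrame] = []
    levels = []
    for _ in range(n_trials // block_length):
        size = stair.displayed if stair is not None else params.memory_midpoint_words
        d = psychometric(params, size, "memory", stimulus_type)
        df = simulate_sdt_trials(
            block_length, d, params.criterion, tuple(offs), meta_ratio=m, rng=rng
        )
        if stair is not None:
            stair.record_block(float(df.accuracy.mean()))
        out.append(df)
        levels.append(np.full(block_length, size, dtype=float))
    df = pd.concat(out, ignore_index=True)
    return {
        "stimulus_level": np.concatenate(levels),
        "true_class": df.true_class.to_numpy(),
        "response": df.response.to_numpy(),
        "accuracy": df.accuracy.to_numpy(),
        "confidence": df.confidence.to_numpy(),
        "rt_ms": _draw_rt(rng, n_trials),
    }


def _emit(
    rows: list[dict],
    arrays: dict[str, np.ndarray],
    *,
    participant: str,
    group: str,
    trained_stimulus: str,
    session: int,
    phase: str,
    domain: str,
    stimulus_type: str,
    block_length: int,
) -> None:
    n = len(arrays["accuracy"])
    rows.append(
        {
            "participant": np.repeat(participant, n),
            "group": np.repeat(group, n),
            "trained_stimulus": np.repeat(trained_stimulus, n),
            "session": np.full(n, session, dtype=int),
            "phase": np.repeat(phase, n),
            "domain": np.repeat(domain, n),
            "stimulus_type": np.repeat(stimulus_type, n),
            "block": 1 + np.arange(n) // block_length,
            "trial": 1 + np.arange(n) % block_length,
            **arrays,
        }
    )


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate a full two-group, 10-session cohort trial log.

    Brightness staircases persist across sessions per stimulus type
    (each session starts at the previous session's final level), after
    a 60-trial initial titration block that is not part of the log.
    Returns a tidy DataFrame, one row per trial.
    """
    cfg = config or CohortConfig()
    if seed is None:
        seed = cfg.seed
    master = np.random.SeedSequence(seed)
    n = cfg.n_per_group
    obs_seeds = master.spawn(2 * n)
    rows: list[dict] = []
    for g_idx, group in enumerate(("control", "experimental")):
        for j in range(n):
            ss = obs_seeds[g_idx * n + j]
            rng = np.random.default_rng(ss)
            params = _spawn_observer(cfg, group, j, rng)
            pid = f"{'ctl' if group == 'control' else 'exp'}{j + 1:02d}"
            trained = "shapes" if j % 2 == 0 else "words"
            # persistent titration state
            stairs = {
                "shapes": BrightnessStaircase(level=BRIGHTNESS_MAX),
                "words": BrightnessStaircase(level=BRIGHTNESS_MAX),
            }
            for st in ("shapes", "words"):
                _perception_block_loop(params, stairs[st], 60, 1, rng)
            mem_stair = SetSizeStaircase(value=4.0)

            def run_session(session: int, phase: str) -> None:
                if phase == "train":
                    arr = _perception_block_loop(
                        params, stairs[trained], cfg.train_trials, session, rng
                    )
                    _emit(
                        rows, arr, participant=pid, group=group,
                        trained_stimulus=trained, session=session, phase=phase,
                        domain="perception", stimulus_type=trained,
                        block_length=cfg.block_length,
                    )
                    return
                for st in ("shapes", "words"):
                    arr = _perception_block_loop(
                        params, stairs[st], cfg.trials_per_task, session, rng
                    )
                    _emit(
                        rows, arr, participant=pid, group=group,
                        trained_stimulus=trained, session=session, phase=phase,
                        domain="perception", stimulus_type=st,
                        block_length=cfg.block_length,
                    )
                for st in ("shapes", "words"):
                    arr = _memory_task(
                        params,
                        mem_stair if st == "shapes" else None,
                        st, cfg.trials_per_task, cfg.block_length, session, rng,
                    )
                    _emit(
                        rows, arr, participant=pid, group=group,
                        trained_stimulus=trained, session=session, phase=phase,
                        domain="memory", stimulus_type=st,
                        block_length=cfg.block_length,
                    )

            run_session(1, "pre")
            for s in range(2, 10):
                run_session(s, "train")
            run_session(10, "post")

    frames = [pd.DataFrame(r) for r in rows]
    df = pd.concat(frames, ignore_index=True)
    df["accuracy"] = df["accuracy"].astype(int)
    return df
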