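"""Nonparametric bootstrap mediation of training effects.

Tests whether the effect of feedback type (X: 0 = control,
1 = experimental) on later gains in metacognitive efficiency
(Y: change in log(meta-d'/d') over the late training window) runs
through the early shift in confidence (M: change in mean confidence
from pretraining to the first training session).  Paths are ordinary
least squares:

    M = i1 + a X
    Y = i2 + c' X + b M
    Y = i3 + c X

with the indirect effect ab and the OLS identity c = c' + ab.
Inference is by participant-level nonparametric bootstrap with
percentile confidence intervals (robust to non-normal path products,
unlike the Sobel test); a normal-approximation z from the bootstrap
spread is reported alongside the percentile p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["MediationData", "PathEstimate", "MediationFit", "fit_mediation", "peak_change_session"]


@dataclass(frozen=True)
class MediationData:
    """Per-participant mediation variables (X binary, M and Y continuous)."""

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "MediationData":
        return MediationData(
            x=np.asarray(df["X"], dtype=float),
            m=np.asarray(df["M"], dtype=float),
            y=np.asarray(df["Y"], dtype=float),
        )

    def __post_init__(self) -> None:
        n = len(self.x)
        if len(self.m) != n or len(self.y) != n:
            raise ValueError("X, M, Y must have equal length")
        if not np.isin(self.x, (0.0, 1.0)).all():
            raise ValueError("X must be binary 0/1")
        if np.isnan(self.m).any() or np.isnan(self.y).any():
            raise ValueError("missing values in M or Y")
        for g in (0.0, 1.0):
            if (self.x == g).sum() < 10:
                raise ValueError("need at least 10 participants per group")
        if np.var(self.m) <= 0 or np.var(self.y) <= 0:
            raise ValueError("zero variance in M or Y")


@dataclass(frozen=True)
class PathEstimate:
    """One mediation path: point estimate, percentile CI and p values."""

    estimate: float
    ci: tuple[float, float]
    p_boot: float
    p_z: float


@dataclass(frozen=True)
class MediationFit:
    a: PathEstimate
    b: PathEstimate
    c: PathEstimate
    c_prime: PathEstimate
    ab: PathEstimate
    n_boot: int
    alpha: float


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS path coefficients (a, b, c, c') via closed-form moments.

    Vectorised over a leading bootstrap axis: inputs of shape (..., n).
    """
    def cov(u, v):
        return (u * v).mean(axis=-1) - u.mean(axis=-1) * v.mean(axis=-1)

    sxx = cov(x, x)
    a = cov(x, m) / sxx
    c = cov(x, y) / sxx
    smm = cov(m, m)
    sxm = cov(x, m)
    sxy = cov(x, y)
    smy = cov(m, y)
    det = sxx * smm - sxm**2
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    return np.stack([a, b, c, c_prime], axis=-1)


def _pct_p(samples: np.ndarray) -> float:
    """Two-sided bootstrap p: twice the smaller tail mass around zero."""
    lo = float(np.mean(samples < 0.0))
    hi = float(np.mean(samples > 0.0))
    return float(min(1.0, 2.0 * min(lo, hi) + np.mean(samples == 0.0)))


def fit_mediation(
    data: MediationData | pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MediationFit:
    """Fit the three-variable mediation model with a percentile bootstrap.

    Resamples participants with replacement ``n_boot`` times (>= 1000);
    bit-reproducible under a fixed ``seed``.
    """
    if isinstance(data, pd.DataFrame):
        data = MediationData.from_frame(data)
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    rng = np.random.default_rng(seed)
    n = len(data.x)
    est = _paths(data.x, data.m, data.y)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = _paths(data.x[idx], data.m[idx], data.y[idx])  # (n_boot, 4)
    ab_boot = boot[:, 0] * boot[:, 1]
    ab_est = est[0] * est[1]
    q = (100 * alpha / 2.0, 100 * (1 - alpha / 2.0))

    def make(point: float, samples: np.ndarray) -> PathEstimate:
        lo, hi = np.percentile(samples, q)
        sd = samples.std(ddof=1)
        pz = float(2.0 * norm.sf(abs(point) / sd)) if sd > 0 else float("nan")
        return PathEstimate(float(point), (float(lo), float(hi)), _pct_p(samples), pz)

    return MediationFit(
        a=make(est[0], boot[:, 0]),
        b=make(est[1], boot[:, 1]),
        c=make(est[2], boot[:, 2]),
        c_prime=make(est[3], boot[:, 3]),
        ab=make(ab_est, ab_boot),
        n_boot=n_boot,
        alpha=alpha,
    )


def peak_change_session(series: np.ndarray) -> tuple[int, bool]:
    """Transition index of the largest session-to-session increase.

    ``series`` is a per-session measure ordered by session.  Returns a
    1-based transition index (1 = change from the first to the second
    session) and a flag that is True when the series is constant (all
    changes tie at zero; the earliest transition is returned).  Ties
    break to the earliest transition.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two sessions")
    d = np.diff(s)
    flat = bool(np.allclose(d, d[0]) and np.allclose(d, 0.0))
    return int(np.argmax(d)) + 1, flat
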