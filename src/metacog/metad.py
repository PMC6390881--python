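"""Type-2 signal detection: d', meta-d' by maximum likelihood, and bias.

The meta-d' measurement model asks what first-order sensitivity would be
required, under equal-variance Gaussian SDT, for an optimal confidence
rater to produce the observed response-conditional confidence counts.
Fitting holds the type-1 criterion at its d'-relative position
(c' = c/d') and maximises the multinomial likelihood of the confidence
ratings over meta-d' and six ordered type-2 criteria (three per
response side).  The efficiency ratio meta-d'/d' equals 1 for an
observer whose confidence uses all choice-relevant evidence; analyses
are run on log(meta-d'/d'), which weights gains and losses relative to
1 symmetrically and is undefined for non-positive meta-d'.

All fits operate on a 2 (true class) x 2 (response) x 4 (confidence)
count array.  A uniform cell padding of 1/8 (one over twice the number
of rating levels) is added before fitting to avoid zero-cell
degeneracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

__all__ = [
    "MetaDFit",
    "counts_from_trials",
    "pad_counts",
    "fit_type1",
    "fit_meta_d",
    "mean_confidence",
]

N_CONF = 4
#: uniform cell padding: 1 / (2 * number of rating levels)
CELL_PAD = 1.0 / (2.0 * N_CONF)

_EPS = 1e-12


@dataclass(frozen=True)
class MetaDFit:
    """Fitted type-1 and type-2 SDT parameters for one data cell."""

    d_prime: float
    criterion: float
    meta_d_prime: float
    ratio: float
    log_ratio: float
    type2_criteria: tuple[float, ...]
    neg_log_likelihood: float
    converged: bool


def counts_from_trials(trials: pd.DataFrame) -> np.ndarray:
    """Tabulate a trial log into the 2 x 2 x 4 confidence count array.

    Axes are (true_class, response, confidence-1).  Order-invariant.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    tc = np.asarray(trials["true_class"], dtype=int)
    resp = np.asarray(trials["response"], dtype=int)
    conf = np.asarray(trials["confidence"], dtype=int)
    if not np.isin(conf, (1, 2, 3, 4)).all():
        raise ValueError("confidence ratings must be in 1..4")
    counts = np.zeros((2, 2, N_CONF), dtype=int)
    np.add.at(counts, (tc, resp, conf - 1), 1)
    return counts


def pad_counts(counts: np.ndarray, pad: float = CELL_PAD) -> np.ndarray:
    """Add a uniform padding constant to every count cell."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2, N_CONF):
        raise ValueError("counts must have shape (2, 2, 4)")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    return c + pad


def fit_type1(counts: np.ndarray) -> tuple[float, float]:
    """Equal-variance SDT estimates from a (padded) count array.

    Collapses over confidence and returns
    d' = z(H) - z(FA),  c = -(z(H) + z(FA)) / 2.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim == 3:
        c = c.sum(axis=2)
    n0, n1 = c[0].sum(), c[1].sum()
    if n0 <= 0 or n1 <= 0:
        raise ValueError("both stimulus classes must be present")
    hr = c[1, 1] / n1
    far = c[0, 1] / n0
    if not (0 < hr < 1 and 0 < far < 1):
        raise ValueError("degenerate hit/false-alarm rate; pad counts first")
    zh, zf = ndtri(hr), ndtri(far)
    return float(zh - zf), float(-0.5 * (zh + zf))


def _t2_distributions(
    meta_d: float, incs: np.ndarray, c_rel: float
) -> np.ndarray:
    """Response-conditional confidence probabilities under the meta model.

    ``c_rel`` is the d'-relative criterion c' = c/d'; the meta-level
    type-1 criterion sits at c' * meta_d.  ``incs`` are the six positive
    criterion increments (three below, three above).  Returns an array
    p[class, response, confidence] with each (class, response) slice a
    distribution over the four levels.
    """
    c2 = c_rel * meta_d
    lo = c2 - np.cumsum(incs[:3])  # descending criteria below c2
    hi = c2 + np.cumsum(incs[3:])  # ascending criteria above c2
    # bin edges on each side, ordered from the criterion outward
    edges_lo = np.concatenate(([c2], lo, [-np.inf]))
    edges_hi = np.concatenate(([c2], hi, [np.inf]))
    p = np.empty((2, 2, N_CONF))
    for s, mu in enumerate((-meta_d / 2.0, meta_d / 2.0)):
        below = ndtr(c2 - mu)
        cdf_lo = ndtr(edges_lo - mu)
        p[s, 0] = (cdf_lo[:-1] - cdf_lo[1:]) / max(below, _EPS)
        cdf_hi = ndtr(edges_hi - mu)
        p[s, 1] = (cdf_hi[1:] - cdf_hi[:-1]) / max(1.0 - below, _EPS)
    return p


def _nll(theta: np.ndarray, counts: np.ndarray, c_rel: float) -> float:
    meta_d = theta[0]
    incs = np.exp(np.clip(theta[1:], -10.0, 5.0))
    p = _t2_distributions(meta_d, incs, c_rel)
    return float(-(counts * np.log(np.clip(p, _EPS, None))).sum())


def fit_meta_d(
    counts: np.ndarray,
    pad: bool = True,
    tol: float = 1e-8,
) -> MetaDFit:
    """Maximum-likelihood meta-d' fit to a 2 x 2 x 4 count array.

    The type-1 parameters (d', c) are estimated first from the counts
    collapsed over confidence; the meta-level model then maximises the
    multinomial likelihood of the response-conditional confidence
    counts over meta-d' and six ordered type-2 criteria, parameterised
    as cumulative positive increments away from the scaled type-1
    criterion (so ordering is guaranteed throughout optimisation).
    Three deterministic starts (meta-d' at 0.5, 1 and 1.5 times d')
    guard against local optima.

    Notes
    -----
    meta-d' may legitimately come out negative (confidence anticorrelated
    with accuracy); in that case ``log_ratio`` is NaN.
    """
    c = pad_counts(counts) if pad else np.asarray(counts, dtype=float)
    d1, c1 = fit_type1(c)
    c_rel = c1 / d1 if abs(d1) > 1e-6 else 0.0

    start_incs = np.log(np.full(6, 0.4))
    best = None
    for f in (0.5, 1.0, 1.5):
        theta0 = np.concatenate(([f * d1], start_incs))
        res = minimize(
            _nll,
            theta0,
            args=(c, c_rel),
            method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    meta_d = float(best.x[0])
    incs = np.exp(best.x[1:])
    c2 = c_rel * meta_d
    t2c = tuple(
        np.concatenate(
            (np.sort(c2 - np.cumsum(incs[:3])), c2 + np.cumsum(incs[3:]))
        )
    )
    ratio = meta_d / d1
    log_ratio = float(np.log(ratio)) if ratio > 0 else float("nan")
    return MetaDFit(
        d_prime=d1,
        criterion=c1,
        meta_d_prime=meta_d,
        ratio=float(ratio),
        log_ratio=log_ratio,
        type2_criteria=t2c,
        neg_log_likelihood=float(best.fun),
        converged=bool(best.success),
    )


def mean_confidence(trials: pd.DataFrame | np.ndarray) -> float:
    """Metacognitive bias: mean 1–4 confidence irrespective of correctness."""
    conf = (
        np.asarray(trials["confidence"], dtype=float)
        if isinstance(trials, pd.DataFrame)
        else np.asarray(trials, dtype=float)
    )
    if conf.size == 0:
        raise ValueError("empty trial set")
    return float(conf.mean())
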