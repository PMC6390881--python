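"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimiser code paths: the
meta-d' oracle is an exhaustive grid search over the meta-level
sensitivity and the type-2 criterion increments, exploiting the fact
that the response-conditional likelihood separates into the two
response sides given meta-d'.
"""

import numpy as np
from scipy.special import ndtr

_EPS = 1e-12


def _side_nll(meta_d, c_rel, incs_grid, counts_side, side):
    """Negative log likelihood of one response side for all criteria combos.

    ``incs_grid``: (K, 3) positive increments; ``counts_side``: (2, 4)
    counts for this response over (true class, confidence).
    """
    c2 = c_rel * meta_d
    cum = np.cumsum(incs_grid, axis=1)  # (K, 3)
    if side == 0:
        edges = np.concatenate(
            [np.full((len(cum), 1), c2), c2 - cum, np.full((len(cum), 1), -np.inf)], axis=1
        )
    else:
        edges = np.concatenate(
            [np.full((len(cum), 1), c2), c2 + cum, np.full((len(cum), 1), np.inf)], axis=1
        )
    nll = np.zeros(len(cum))
    for s, mu in enumerate((-meta_d / 2.0, meta_d / 2.0)):
        below = ndtr(c2 - mu)
        denom = max(below, _EPS) if side == 0 else max(1.0 - below, _EPS)
        cdf = ndtr(edges - mu)
        p = (cdf[:, :-1] - cdf[:, 1:]) / denom if side == 0 else (cdf[:, 1:] - cdf[:, :-1]) / denom
        nll -= counts_side[s] @ np.log(np.clip(p, _EPS, None)).T
    return nll


def _combos(values):
    return np.array([(a, b, c) for a in values for b in values for c in values])


def _grid_pass(counts, c_rel, meta_grid, combos):
    best_nll, best_md, best_incs = np.inf, np.nan, (None, None)
    for md in meta_grid:
        n0 = _side_nll(md, c_rel, combos, counts[:, 0, :], side=0)
        n1 = _side_nll(md, c_rel, combos, counts[:, 1, :], side=1)
        i0, i1 = int(np.argmin(n0)), int(np.argmin(n1))
        tot = n0[i0] + n1[i1]
        if tot < best_nll:
            best_nll, best_md = tot, md
            best_incs = (combos[i0], combos[i1])
    return best_md, best_nll, best_incs


def grid_meta_d(counts, d_prime, criterion):
    """Exhaustive grid-search meta-d' MLE over (meta-d', 6 ordered criteria).

    Two-stage search: a coarse global grid over meta-d' in [-1, 3.5]
    (step 0.05) with 16 log-spaced criterion increments per slot
    (minimised per response side, which is exact because the
    response-conditional likelihood separates), then a dense local
    refinement of both meta-d' (step 0.01) and the increments around
    the coarse optimum.  Returns (meta_d, nll) at the refined optimum.
    """
    counts = np.asarray(counts, dtype=float)
    c_rel = criterion / d_prime
    coarse_md, _, (inc0, inc1) = _grid_pass(
        counts, c_rel, np.arange(-1.0, 3.5 + 1e-9, 0.05), _combos(np.geomspace(0.03, 2.2, 16))
    )
    # refine: meta-d' locally at 0.01, increments on a fine grid around
    # each side's coarse optimum (cartesian per side, 9 values per slot)
    local_md = np.arange(coarse_md - 0.15, coarse_md + 0.15 + 1e-9, 0.01)
    best_nll, best_md = np.inf, coarse_md
    fine0 = [np.unique(np.clip(np.linspace(v * 0.5, v * 1.8, 9), 0.01, 3.0)) for v in inc0]
    fine1 = [np.unique(np.clip(np.linspace(v * 0.5, v * 1.8, 9), 0.01, 3.0)) for v in inc1]
    combos0 = np.array([(a, b, c) for a in fine0[0] for b in fine0[1] for c in fine0[2]])
    combos1 = np.array([(a, b, c) for a in fine1[0] for b in fine1[1] for c in fine1[2]])
    for md in local_md:
        n0 = _side_nll(md, c_rel, combos0, counts[:, 0, :], side=0).min()
        n1 = _side_nll(md, c_rel, combos1, counts[:, 1, :], side=1).min()
        if n0 + n1 < best_nll:
            best_nll, best_md = n0 + n1, md
    return float(best_md), float(best_nll)
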