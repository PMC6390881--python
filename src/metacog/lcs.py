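"""Latent change score (LCS) models of pre/post calibration scores.

A latent change score model writes the posttraining score as the
pretraining score plus a latent change, Y_post = Y_pre + dY (the
pre -> post loading fixed at 1), and models the change itself as

    dY = alpha + beta * Y_pre + residual            (univariate)

    dP = alpha_P + beta_P * P_pre + gamma_P * M_pre + e_P
    dM = alpha_M + beta_M * M_pre + gamma_M * P_pre + e_M   (bivariate)

where beta is the self-feedback path (regression to the mean, baseline
dependence, ceiling effects) and gamma the cross-domain coupling.  The
bivariate model additionally estimates the covariance of the two change
residuals ("correlated change").  Models are fitted simultaneously to
two groups by Gaussian maximum likelihood on the group mean/covariance
structure, with per-parameter equality constraints across groups and
fixed values expressible through :class:`Constraints`.

Overall fit is summarised by the likelihood-ratio chi-square against
the saturated model, RMSEA (with a 90% CI from noncentrality
inversion), CFI against the independence baseline, and SRMR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.stats import chi2, ncx2

__all__ = [
    "Constraints",
    "LCSFit",
    "fit_univariate_lcs",
    "fit_bivariate_lcs",
    "fit_indices",
    "chisq_diff",
    "UNIVARIATE_PARAMS",
    "BIVARIATE_PARAMS",
]

GROUPS = ("control", "experimental")

# parameter names; the var_/cov_ prefixes drive the optimisation transform
UNIVARIATE_PARAMS = ("mu_pre", "var_pre", "alpha", "beta", "var_e")
BIVARIATE_PARAMS = (
    "mu_P_pre", "mu_M_pre",
    "var_P_pre", "var_M_pre", "cov_pre",
    "alpha_P", "alpha_M",
    "beta_P", "beta_M", "gamma_P", "gamma_M",
    "var_dP", "var_dM", "cov_d",
)


@dataclass(frozen=True)
class Constraints:
    """Cross-group equality and fixed-value constraints on model parameters.

    ``equal`` lists parameter names constrained to a single value shared
    by both groups; ``fixed`` maps a parameter name (fixed in both
    groups) or a ``(name, group)`` pair to a numeric value.
    """

    equal: frozenset[str] = frozenset()
    fixed: dict = field(default_factory=dict)

    @staticmethod
    def of(*equal: str, **fixed: float) -> "Constraints":
        return Constraints(equal=frozenset(equal), fixed=dict(fixed))


@dataclass
class LCSFit:
    """Two-group LCS fit: estimates, standard errors and fit statistics."""

    params: dict          # (name, group) -> estimate
    se: dict              # (name, group) -> standard error (NaN if constrained out)
    chi_square: float
    df: int
    n_obs: tuple[int, int]
    log_likelihood: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    srmr: float
    converged: bool
    model: str            # "univariate" | "bivariate"
    baseline_chi_square: float
    baseline_df: int
    n_free: int

    @property
    def z_values(self) -> dict:
        return {
            k: self.params[k] / self.se[k] if self.se.get(k, 0) else float("nan")
            for k in self.params
        }


# ---------------------------------------------------------------------------
# model-implied moments
# ---------------------------------------------------------------------------

def _implied_univariate(p: dict) -> tuple[np.ndarray, np.ndarray]:
    mu, v, a, b, ve = (p[k] for k in UNIVARIATE_PARAMS)
    lam = 1.0 + b
    mean = np.array([mu, a + lam * mu])
    cov = np.array([[v, lam * v], [lam * v, lam * lam * v + ve]])
    return mean, cov


def _implied_bivariate(p: dict) -> tuple[np.ndarray, np.ndarray]:
    muP, muM = p["mu_P_pre"], p["mu_M_pre"]
    vP, vM, cPM = p["var_P_pre"], p["var_M_pre"], p["cov_pre"]
    aP, aM = p["alpha_P"], p["alpha_M"]
    bP, bM, gP, gM = p["beta_P"], p["beta_M"], p["gamma_P"], p["gamma_M"]
    veP, veM, ce = p["var_dP"], p["var_dM"], p["cov_d"]
    # observed order: (P_pre, P_post, M_pre, M_post); latent (P_pre, M_pre)
    A = np.array(
        [
            [1.0, 0.0],
            [1.0 + bP, gP],
            [0.0, 1.0],
            [gM, 1.0 + bM],
        ]
    )
    S1 = np.array([[vP, cPM], [cPM, vM]])
    mean = A @ np.array([muP, muM]) + np.array([0.0, aP, 0.0, aM])
    R = np.zeros((4, 4))
    R[1, 1] = veP
    R[3, 3] = veM
    R[1, 3] = R[3, 1] = ce
    cov = A @ S1 @ A.T + R
    return mean, cov


_IMPLIED = {"univariate": _implied_univariate, "bivariate": _implied_bivariate}
_PARAM_NAMES = {"univariate": UNIVARIATE_PARAMS, "bivariate": BIVARIATE_PARAMS}
_OBS_COLS = {
    "univariate": None,  # filled per call
    "bivariate": ("P_pre", "P_post", "M_pre", "M_post"),
}


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _suff_stats(data: pd.DataFrame, cols: tuple[str, ...]):
    """Per-group sample size, mean and ML (N-divisor) covariance."""
    stats = []
    for g in GROUPS:
        y = data.loc[data["group"] == g, list(cols)].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("missing values; complete cases required")
        n = len(y)
        if n < 10:
            raise ValueError(f"need >= 10 complete cases per group (group {g!r}: {n})")
        ybar = y.mean(axis=0)
        S = (y - ybar).T @ (y - ybar) / n
        stats.append((n, ybar, S))
    return stats


def _m2ll_group(n: int, ybar: np.ndarray, S: np.ndarray, mu: np.ndarray, Sig: np.ndarray) -> float:
    p = len(ybar)
    sign, logdet = np.linalg.slogdet(Sig)
    if sign <= 0:
        return np.inf
    Sinv = np.linalg.inv(Sig)
    delta = ybar - mu
    return n * (
        p * np.log(2.0 * np.pi) + logdet + np.trace(S @ Sinv) + delta @ Sinv @ delta
    )


def _saturated_m2ll(stats) -> float:
    tot = 0.0
    for n, ybar, S in stats:
        p = len(ybar)
        sign, logdet = np.linalg.slogdet(S)
        tot += n * (p * np.log(2.0 * np.pi) + logdet + p)
    return tot


class _ParamMap:
    """Maps (name, group) parameters onto a free vector with constraints.

    Variance parameters (``var_*``) are optimised on the log scale; all
    others are unconstrained.  Equality constraints share one free slot
    across groups; fixed parameters occupy no slot.
    """

    def __init__(self, names: tuple[str, ...], constraints: Constraints):
        self.names = names
        self.constraints = constraints
        self.slots: dict[tuple[str, str], int | None] = {}
        self.fixed_vals: dict[tuple[str, str], float] = {}
        k = 0
        for name in names:
            if name in constraints.fixed:
                for g in GROUPS:
                    self.slots[(name, g)] = None
                    self.fixed_vals[(name, g)] = float(constraints.fixed[name])
                continue
            per_group_fixed = {
                g: constraints.fixed[(name, g)]
                for g in GROUPS
                if (name, g) in constraints.fixed
            }
            if name in constraints.equal:
                for g in GROUPS:
                    self.slots[(name, g)] = k
                k += 1
            else:
                for g in GROUPS:
                    if g in per_group_fixed:
                        self.slots[(name, g)] = None
                        self.fixed_vals[(name, g)] = float(per_group_fixed[g])
                    else:
                        self.slots[(name, g)] = k
                        k += 1
        self.n_free = k

    def _is_log(self, name: str) -> bool:
        return name.startswith("var_")

    def pack(self, natural: dict) -> np.ndarray:
        theta = np.zeros(self.n_free)
        for (name, g), slot in self.slots.items():
            if slot is None:
                continue
            v = natural[(name, g)]
            theta[slot] = np.log(v) if self._is_log(name) else v
        return theta

    def unpack(self, theta: np.ndarray) -> dict:
        out = dict(self.fixed_vals)
        for (name, g), slot in self.slots.items():
            if slot is None:
                continue
            v = theta[slot]
            out[(name, g)] = float(np.exp(v)) if self._is_log(name) else float(v)
        return out


def _fit_lcs(
    data: pd.DataFrame,
    model: str,
    cols: tuple[str, ...],
    constraints: Constraints,
    tol: float = 1e-10,
) -> LCSFit:
    names = _PARAM_NAMES[model]
    implied = _IMPLIED[model]
    stats = _suff_stats(data, cols)
    pmap = _ParamMap(names, constraints)

    def m2ll(theta: np.ndarray) -> float:
        nat = pmap.unpack(theta)
        tot = 0.0
        for g, (n, ybar, S) in zip(GROUPS, stats):
            p = {name: nat[(name, g)] for name in names}
            mu, Sig = implied(p)
            tot += _m2ll_group(n, ybar, S, mu, Sig)
            if not np.isfinite(tot):
                return 1e12
        return tot

    theta0 = pmap.pack(_start_values(model, cols, data, names))
    res = minimize(
        m2ll, theta0, method="L-BFGS-B",
        options={"ftol": tol, "gtol": 1e-9, "maxiter": 2000},
    )
    # polish with Nelder-Mead if the quasi-Newton step stalled
    res2 = minimize(
        m2ll, res.x, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 5000},
    )
    if res2.fun < res.fun:
        res = res2
    nat = pmap.unpack(res.x)

    sat = _saturated_m2ll(stats)
    T = max(res.fun - sat, 0.0)
    p_obs = len(cols)
    n_moments = 2 * (p_obs + p_obs * (p_obs + 1) // 2)
    df = n_moments - pmap.n_free
    N = sum(s[0] for s in stats)

    se = _standard_errors(pmap, m2ll_natural_factory(pmap, stats, names, implied), nat)
    base_T, base_df = _baseline(stats)
    rmsea, ci = _rmsea(T, df, N, n_groups=2)
    cfi = _cfi(T, df, base_T, base_df)
    srmr = _srmr(stats, nat, names, implied)
    return LCSFit(
        params=nat,
        se=se,
        chi_square=float(T),
        df=int(df),
        n_obs=tuple(s[0] for s in stats),
        log_likelihood=float(-0.5 * res.fun),
        rmsea=rmsea,
        rmsea_ci=ci,
        cfi=cfi,
        srmr=srmr,
        converged=bool(np.isfinite(res.fun)),
        model=model,
        baseline_chi_square=float(base_T),
        baseline_df=int(base_df),
        n_free=pmap.n_free,
    )


def _start_values(model, cols, data, names) -> dict:
    """Moment-based starting values (per group OLS of change on pre)."""
    out = {}
    for g in GROUPS:
        y = data.loc[data["group"] == g, list(cols)].to_numpy(dtype=float)
        if model == "univariate":
            pre, post = y[:, 0], y[:, 1]
            d = post - pre
            X = np.column_stack([np.ones_like(pre), pre])
            coef, *_ = np.linalg.lstsq(X, d, rcond=None)
            resid = d - X @ coef
            out.update(
                {
                    ("mu_pre", g): pre.mean(),
                    ("var_pre", g): max(pre.var(), 1e-6),
                    ("alpha", g): coef[0],
                    ("beta", g): coef[1],
                    ("var_e", g): max(resid.var(), 1e-6),
                }
            )
        else:
            P1, P2, M1, M2 = y.T
            dP, dM = P2 - P1, M2 - M1
            X = np.column_stack([np.ones_like(P1), P1, M1])
            cP, *_ = np.linalg.lstsq(X, dP, rcond=None)
            cM, *_ = np.linalg.lstsq(X, dM, rcond=None)
            rP = dP - X @ cP
            rM = dM - X @ cM
            out.update(
                {
                    ("mu_P_pre", g): P1.mean(),
                    ("mu_M_pre", g): M1.mean(),
                    ("var_P_pre", g): max(P1.var(), 1e-6),
                    ("var_M_pre", g): max(M1.var(), 1e-6),
                    ("cov_pre", g): float(np.cov(P1, M1, bias=True)[0, 1]),
                    ("alpha_P", g): cP[0],
                    ("alpha_M", g): cM[0],
                    ("beta_P", g): cP[1],
                    ("gamma_P", g): cP[2],
                    ("beta_M", g): cM[2],
                    ("gamma_M", g): cM[1],
                }
            )
            out[("var_dP", g)] = max(rP.var(), 1e-6)
            out[("var_dM", g)] = max(rM.var(), 1e-6)
            out[("cov_d", g)] = float(np.mean(rP * rM))
    # honour fixed values in starts
    return out


def m2ll_natural_factory(pmap, stats, names, implied):
    """-2 log likelihood as a function of the free natural parameters."""
    free_keys = sorted({k for k, s in pmap.slots.items() if s is not None}, key=lambda k: pmap.slots[k])
    # unique slots in order
    slot_to_key = {}
    for k in free_keys:
        slot_to_key.setdefault(pmap.slots[k], k)
    ordered = [slot_to_key[i] for i in range(pmap.n_free)]

    def fn(x: np.ndarray) -> float:
        nat = dict(pmap.fixed_vals)
        for (name, g), slot in pmap.slots.items():
            if slot is not None:
                nat[(name, g)] = x[slot]
        tot = 0.0
        for g, (n, ybar, S) in zip(GROUPS, stats):
            p = {name: nat[(name, g)] for name in names}
            mu, Sig = implied(p)
            v = _m2ll_group(n, ybar, S, mu, Sig)
            if not np.isfinite(v):
                return 1e12
            tot += v
        return tot

    fn.ordered_keys = ordered
    return fn


def _standard_errors(pmap, m2ll_nat, nat) -> dict:
    """SEs from the observed information (numerical Hessian, natural scale)."""
    keys = m2ll_nat.ordered_keys
    x0 = np.array([nat[k] for k in keys])
    k = len(x0)
    h = np.maximum(np.abs(x0), 0.1) * 1e-4
    H = np.zeros((k, k))
    f0 = m2ll_nat(x0)
    for i in range(k):
        for j in range(i, k):
            xi, xj = np.zeros(k), np.zeros(k)
            xi[i] = h[i]
            xj[j] = h[j]
            fpp = m2ll_nat(x0 + xi + xj)
            fpm = m2ll_nat(x0 + xi - xj)
            fmp = m2ll_nat(x0 - xi + xj)
            fmm = m2ll_nat(x0 - xi - xj)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    H *= 0.5  # information of the log-likelihood
    se = {kk: float("nan") for kk in nat}
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        for idx, key in enumerate(keys):
            if d[idx] > 0:
                name, g = key
                val = float(np.sqrt(d[idx]))
                for (n2, g2), slot in pmap.slots.items():
                    if slot == idx:
                        se[(n2, g2)] = val
    except np.linalg.LinAlgError:
        pass
    return se


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def _baseline(stats) -> tuple[float, int]:
    """Independence baseline: free means and variances, zero covariances."""
    T = 0.0
    p = len(stats[0][1])
    for n, ybar, S in stats:
        sign, logdet = np.linalg.slogdet(S)
        T += n * (np.log(np.diag(S)).sum() - logdet)
    df = 2 * (p * (p - 1) // 2)
    return float(T), df


def _rmsea(T: float, df: int, N: int, n_groups: int = 2):
    if df == 0:
        return 0.0, (0.0, 0.0)
    scale = df * (N - 1)
    rmsea = float(np.sqrt(n_groups * max(T - df, 0.0) / scale))

    def lo_fn(lam):
        return ncx2.cdf(T, df, lam) - 0.95

    def hi_fn(lam):
        return ncx2.cdf(T, df, lam) - 0.05

    lo = 0.0
    if lo_fn(0.0) > 0:  # T above the 95th central percentile
        lo = brentq(lo_fn, 0.0, max(10.0 * T, 10.0))
    hi = 0.0
    if hi_fn(0.0) > 0:
        hi = brentq(hi_fn, 0.0, max(10.0 * T, 100.0))
    ci = (
        float(np.sqrt(n_groups * lo / scale)),
        float(np.sqrt(n_groups * hi / scale)),
    )
    return rmsea, ci


def _cfi(T: float, df: int, Tb: float, dfb: int) -> float:
    num = max(T - df, 0.0)
    den = max(Tb - dfb, T - df, 0.0)
    if den == 0.0:
        return 1.0
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def _srmr(stats, nat, names, implied) -> float:
    tot, N = 0.0, sum(s[0] for s in stats)
    for g, (n, ybar, S) in zip(GROUPS, stats):
        p = {name: nat[(name, g)] for name in names}
        mu, Sig = implied(p)
        sd = np.sqrt(np.diag(S))
        res = []
        k = len(ybar)
        for i in range(k):
            for j in range(i + 1):
                res.append((S[i, j] - Sig[i, j]) / (sd[i] * sd[j]))
        for i in range(k):
            res.append((ybar[i] - mu[i]) / sd[i])
        tot += (n / N) * float(np.sqrt(np.mean(np.square(res))))
    return tot


def fit_indices(fit: LCSFit, baseline_fit: LCSFit | None = None):
    """(RMSEA, RMSEA 90% CI, CFI, SRMR) of a fitted model.

    If ``baseline_fit`` is given its chi-square/df replace the stored
    independence baseline in the CFI.
    """
    if baseline_fit is None:
        return fit.rmsea, fit.rmsea_ci, fit.cfi, fit.srmr
    cfi = _cfi(fit.chi_square, fit.df, baseline_fit.chi_square, baseline_fit.df)
    return fit.rmsea, fit.rmsea_ci, cfi, fit.srmr


def chisq_diff(fit_restricted: LCSFit, fit_free: LCSFit) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested two-group LCS fits."""
    ddf = fit_free.n_free - fit_restricted.n_free
    if ddf <= 0:
        raise ValueError("models are not nested (restricted model must have fewer free parameters)")
    dchi = fit_restricted.chi_square - fit_free.chi_square
    p = float(chi2.sf(max(dchi, 0.0), ddf))
    return float(dchi), int(ddf), p


# ---------------------------------------------------------------------------
# public fitting entry points
# ---------------------------------------------------------------------------

def fit_univariate_lcs(
    data: pd.DataFrame,
    domain: str = "P",
    constraints: Constraints | None = None,
) -> LCSFit:
    """Two-group univariate LCS fit for one domain ("P" or "M").

    ``data`` is wide per-participant with columns ``group`` and
    ``{domain}_pre`` / ``{domain}_post``.  Default constraints follow
    the usual baseline-equivalence specification (pretraining mean and
    variance equal across groups); pass ``Constraints()`` for a fully
    group-varying model.
    """
    if domain not in ("P", "M"):
        raise ValueError("domain must be 'P' or 'M'")
    if constraints is None:
        constraints = Constraints.of("mu_pre", "var_pre")
    cols = (f"{domain}_pre", f"{domain}_post")
    return _fit_lcs(data, "univariate", cols, constraints)


def fit_bivariate_lcs(
    data: pd.DataFrame,
    constraints: Constraints | None = None,
) -> LCSFit:
    """Two-group bivariate (coupled perception/memory) LCS fit.

    Default constraints equate the pretraining means, the pre
    covariance and the memory pre variance across groups while leaving
    the perception pre variance group-specific (the specification that
    restores acceptable fit when baseline perception variance differs
    between groups).
    """
    if constraints is None:
        constraints = Constraints.of("mu_P_pre", "mu_M_pre", "cov_pre", "var_M_pre")
    return _fit_lcs(data, "bivariate", _OBS_COLS["bivariate"], constraints)
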