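"""Binomial logit model with a single sire-level random intercept.

The phenotype is binary (a larva either settles, ``1``, or keeps swimming,
``0``).  Offspring of sire *i* settle independently with probability

    P(y_ij = 1) = logistic(alpha + beta_i),    beta_i ~ N(0, tau2),

so the only free parameters are the population log-odds ``alpha`` and the
among-sire variance ``tau2`` on the latent (logit) scale.  The marginal
likelihood integrates the sire effects out; each sire contributes a
one-dimensional integral which is evaluated by adaptive Gauss-Hermite
quadrature (nodes recentred and rescaled at the conditional mode of the
sire effect).  At ``tau2 = 0`` the model collapses to independent
Bernoulli sampling and the likelihood is closed form.

The null hypothesis ``tau2 = 0`` sits on the boundary of the parameter
space, so the alternative fit explicitly compares the interior optimum
against the boundary (null) fit rather than trusting asymptotics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import roots_hermite

logger = logging.getLogger("halfsib")

# -- configuration -----------------------------------------------------------

#: default number of Gauss-Hermite quadrature nodes per sire integral
DEFAULT_N_QUAD = 21
#: optimizer convergence tolerance on the negative log-likelihood
FIT_TOL = 1e-8
#: optimizer iteration cap
MAX_ITER = 500
#: tau2 below this is treated as exactly zero (boundary)
TAU2_FLOOR = 1e-12

OFFSPRING_COLUMNS = ("sire", "bin", "outcome")
COUNT_COLUMNS = ("sire", "bin", "settled", "swimming")


class InvalidParameterError(ValueError):
    """Non-finite or out-of-domain model parameter."""


class BoundaryDegenerateError(ValueError):
    """All-success or all-failure data: the intercept MLE diverges."""


class InsufficientGroupsError(ValueError):
    """Fewer than two sires with offspring; no among-sire variance is estimable."""


class DataMismatchError(ValueError):
    """Two model fits do not come from the same data."""


# -- containers ---------------------------------------------------------------


@dataclass
class ModelFit:
    """Result of a marginal maximum-likelihood fit.

    ``tau2`` is the among-sire variance on the latent logit scale;
    the null fit has ``tau2 == 0.0`` exactly.  Latent liabilities and
    per-sire effects are integrated out and deliberately not stored.
    """

    alpha: float
    tau2: float
    loglik: float
    converged: bool
    n_quad: int
    n_sires: int
    n_obs: int
    bin_effects: dict[str, float] | None = None


def as_offspring_table(data) -> pd.DataFrame:
    """Validate and return an offspring table (columns sire, bin, outcome).

    Each row is one genotyped larva: its assigned sire, its replicate
    bin, and the binary settlement outcome (1 = settled, 0 = swimming).
    """
    df = pd.DataFrame(data)
    missing = [c for c in OFFSPRING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"offspring table missing columns: {missing}")
    df = df.loc[:, list(OFFSPRING_COLUMNS)].copy()
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"offspring table has missing values at rows {bad}")
    out = pd.to_numeric(df["outcome"], errors="coerce")
    bad = df.index[~out.isin([0, 1])].tolist()
    if bad:
        raise ValueError(
            f"outcome must be 0 (swimming) or 1 (settled); offending rows: {bad}"
        )
    df["outcome"] = out.astype(np.int64)
    df["sire"] = df["sire"].astype(str)
    df["bin"] = df["bin"].astype(str)
    return df


def as_count_table(data) -> pd.DataFrame:
    """Validate and return a sire x bin count table (settled/swimming)."""
    df = pd.DataFrame(data)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    df = df.loc[:, list(COUNT_COLUMNS)].copy()
    for col in ("settled", "swimming"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals % 1 != 0).any():
            raise ValueError(f"column {col!r} must hold nonnegative integers")
        df[col] = vals.astype(np.int64)
    df["sire"] = df["sire"].astype(str)
    df["bin"] = df["bin"].astype(str)
    return df


def _collapse(counts: pd.DataFrame):
    """Per-sire successes and totals; sires without offspring are dropped."""
    grouped = counts.groupby("sire", sort=True)[["settled", "swimming"]].sum()
    n = (grouped["settled"] + grouped["swimming"]).to_numpy(dtype=np.float64)
    s = grouped["settled"].to_numpy(dtype=np.float64)
    keep = n > 0
    return s[keep], n[keep], grouped.index.to_numpy()[keep]


# -- quadrature kernel --------------------------------------------------------

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_rule(n_quad: int):
    """Hermite nodes x_k and log(w_k) + x_k^2 (the adaptive-GH weight term)."""
    rule = _GH_CACHE.get(n_quad)
    if rule is None:
        x, w = roots_hermite(n_quad)
        rule = (x, np.log(w) + x * x)
        _GH_CACHE[n_quad] = rule
    return rule


@njit(cache=True)
def _negll_arrays(alpha, tau2, s, n, x, logw_xx):  # pragma: no cover - jitted
    """Negative marginal log-likelihood from per-sire (successes, totals).

    Adaptive Gauss-Hermite: for each sire the integrand's mode is found
    by safeguarded Newton iteration and the nodes are recentred there and
    rescaled by the curvature.  Binomial coefficients are omitted (they
    cancel in every likelihood-ratio comparison and match the Bernoulli
    product over individually genotyped larvae).
    """
    n_sires = s.shape[0]
    if tau2 <= TAU2_FLOOR:
        tot = 0.0
        for i in range(n_sires):
            tot += s[i] * alpha - n[i] * (max(alpha, 0.0) + math.log1p(math.exp(-abs(alpha))))
        return -tot
    n_quad = x.shape[0]
    sq2 = math.sqrt(2.0)
    const = -0.5 * math.log(2.0 * math.pi * tau2) + 0.5 * math.log(2.0)
    tot = 0.0
    for i in range(n_sires):
        si = s[i]
        ni = n[i]
        m = 0.0
        for _ in range(100):
            p = 1.0 / (1.0 + math.exp(-(alpha + m)))
            grad = si - ni * p - m / tau2
            hess = -ni * p * (1.0 - p) - 1.0 / tau2
            step = grad / hess
            if step > 4.0:
                step = 4.0
            elif step < -4.0:
                step = -4.0
            m -= step
            if abs(step) < 1e-11:
                break
        p = 1.0 / (1.0 + math.exp(-(alpha + m)))
        sig = 1.0 / math.sqrt(ni * p * (1.0 - p) + 1.0 / tau2)
        peak = -1.0e308
        vals = np.empty(n_quad)
        for k in range(n_quad):
            b = m + sq2 * sig * x[k]
            eta = alpha + b
            v = (
                si * eta
                - ni * (max(eta, 0.0) + math.log1p(math.exp(-abs(eta))))
                - b * b / (2.0 * tau2)
                + logw_xx[k]
            )
            vals[k] = v
            if v > peak:
                peak = v
        acc = 0.0
        for k in range(n_quad):
            acc += math.exp(vals[k] - peak)
        tot += const + math.log(sig) + peak + math.log(acc)
    return -tot


@njit(cache=True)
def _negll_bins_arrays(alpha, gamma, tau2, S, N, x, logw_xx):  # pragma: no cover
    """As :func:`_negll_arrays` but with per-bin fixed offsets gamma."""
    n_sires, n_bins = S.shape
    n_quad = x.shape[0]
    sq2 = math.sqrt(2.0)
    if tau2 <= TAU2_FLOOR:
        tot = 0.0
        for i in range(n_sires):
            for b in range(n_bins):
                eta = alpha + gamma[b]
                tot += S[i, b] * eta - N[i, b] * (max(eta, 0.0) + math.log1p(math.exp(-abs(eta))))
        return -tot
    const = -0.5 * math.log(2.0 * math.pi * tau2) + 0.5 * math.log(2.0)
    tot = 0.0
    for i in range(n_sires):
        m = 0.0
        for _ in range(100):
            grad = -m / tau2
            hess = -1.0 / tau2
            for b in range(n_bins):
                p = 1.0 / (1.0 + math.exp(-(alpha + gamma[b] + m)))
                grad += S[i, b] - N[i, b] * p
                hess -= N[i, b] * p * (1.0 - p)
            step = grad / hess
            if step > 4.0:
                step = 4.0
            elif step < -4.0:
                step = -4.0
            m -= step
            if abs(step) < 1e-11:
                break
        curv = 1.0 / tau2
        for b in range(n_bins):
            p = 1.0 / (1.0 + math.exp(-(alpha + gamma[b] + m)))
            curv += N[i, b] * p * (1.0 - p)
        sig = 1.0 / math.sqrt(curv)
        peak = -1.0e308
        vals = np.empty(n_quad)
        for k in range(n_quad):
            bb = m + sq2 * sig * x[k]
            v = -bb * bb / (2.0 * tau2) + logw_xx[k]
            for b in range(n_bins):
                eta = alpha + gamma[b] + bb
                v += S[i, b] * eta - N[i, b] * (max(eta, 0.0) + math.log1p(math.exp(-abs(eta))))
            vals[k] = v
            if v > peak:
                peak = v
        acc = 0.0
        for k in range(n_quad):
            acc += math.exp(vals[k] - peak)
        tot += const + math.log(sig) + peak + math.log(acc)
    return -tot


# -- public likelihood / fitting ---------------------------------------------


def marginal_negloglik(alpha: float, tau2: float, data, n_quad: int = DEFAULT_N_QUAD) -> float:
    """Negative marginal log-likelihood of a count table at (alpha, tau2).

    The sire random effect is integrated out by adaptive Gauss-Hermite
    quadrature with ``n_quad`` nodes; at ``tau2 = 0`` the exact
    independent-Bernoulli log-likelihood at log-odds ``alpha`` is
    returned.
    """
    if not (np.isfinite(alpha) and np.isfinite(tau2)):
        raise InvalidParameterError("alpha and tau2 must be finite")
    if tau2 < 0:
        raise InvalidParameterError("tau2 must be nonnegative")
    if n_quad < 1:
        raise InvalidParameterError("n_quad must be a positive integer")
    counts = as_count_table(data)
    if len(counts) == 0 or (counts["settled"] + counts["swimming"]).sum() == 0:
        warnings.warn("empty count table: likelihood is trivially 1", stacklevel=2)
        return 0.0
    s, n, _ = _collapse(counts)
    x, logw_xx = _gh_rule(n_quad)
    return float(_negll_arrays(float(alpha), float(tau2), s, n, x, logw_xx))


def _fit_null_arrays(s: np.ndarray, n: np.ndarray):
    """Closed-form null fit (tau2 = 0): pooled logit and its log-likelihood."""
    total_s = s.sum()
    total_n = n.sum()
    if total_s <= 0 or total_s >= total_n:
        raise BoundaryDegenerateError(
            "pooled success proportion is 0 or 1: intercept MLE diverges"
        )
    alpha = math.log(total_s / (total_n - total_s))
    ll = total_s * alpha - total_n * math.log1p(math.exp(alpha)) if alpha <= 0 else (
        total_s * alpha - total_n * (alpha + math.log1p(math.exp(-alpha)))
    )
    return alpha, ll


def _moment_start(s: np.ndarray, n: np.ndarray) -> float:
    """Crude among-sire variance start from Haldane-corrected empirical logits."""
    p = (s + 0.5) / (n + 1.0)
    lg = np.log(p / (1.0 - p))
    return float(np.clip(np.var(lg), 0.05, 5.0))


def _fit_alt_arrays(s, n, n_quad=DEFAULT_N_QUAD, start=None):
    """Fast-path alternative fit on per-sire arrays.

    Returns (alpha, tau2, loglik_alt, loglik_null, converged).  The
    interior optimum over (alpha, log tau2) is compared against the
    closed-form boundary fit so that tau2 = 0 is exact when the data
    carry no among-sire signal.
    """
    alpha0, ll_null = _fit_null_arrays(s, n)
    if start is None:
        start = (alpha0, _moment_start(s, n))
    x, logw_xx = _gh_rule(n_quad)

    def objective(theta):
        return _negll_arrays(theta[0], math.exp(theta[1]), s, n, x, logw_xx)

    res = minimize(
        objective,
        np.array([start[0], math.log(max(start[1], 1e-6))]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": FIT_TOL, "maxiter": MAX_ITER, "maxfev": 2 * MAX_ITER},
    )
    ll_alt = -res.fun
    if ll_null >= ll_alt:
        # boundary check: the null dominates every interior point tried
        return alpha0, 0.0, ll_null, ll_null, True
    return float(res.x[0]), float(math.exp(res.x[1])), float(ll_alt), float(ll_null), bool(res.success)


def _prepare(data):
    counts = as_count_table(data)
    s, n, sires = _collapse(counts)
    return counts, s, n, sires


def fit_null(data, bin_effect: bool = False) -> ModelFit:
    """Fit the no-sire-effect model (tau2 constrained to zero), closed form."""
    counts, s, n, sires = _prepare(data)
    if n.sum() < 1:
        raise ValueError("need at least one observation")
    if not bin_effect:
        alpha, ll = _fit_null_arrays(s, n)
        return ModelFit(alpha, 0.0, ll, True, 1, len(sires), int(n.sum()))
    # saturated-in-bins logistic fit: each bin's pooled logit is the MLE
    gb = counts.groupby("bin", sort=True)[["settled", "swimming"]].sum()
    tot = gb.sum(axis=1).to_numpy(dtype=float)
    suc = gb["settled"].to_numpy(dtype=float)
    if ((suc <= 0) | (suc >= tot)).any():
        raise BoundaryDegenerateError("a bin has all successes or all failures")
    logits = np.log(suc / (tot - suc))
    ll = float(np.sum(suc * logits - tot * np.logaddexp(0.0, logits)))
    alpha = float(logits[0])
    effects = {b: float(l - alpha) for b, l in zip(gb.index, logits)}
    return ModelFit(alpha, 0.0, ll, True, 1, len(sires), int(tot.sum()), effects)


def fit_alternative(
    data,
    n_quad: int = DEFAULT_N_QUAD,
    start: tuple[float, float] | None = None,
    bin_effect: bool = False,
) -> ModelFit:
    """Maximize the marginal likelihood over (alpha, tau2) with tau2 >= 0.

    Optimizes over (alpha, log tau2) by Nelder-Mead and performs an
    explicit boundary comparison against the closed-form null fit, so
    data without among-sire signal come back with ``tau2 == 0`` exactly.
    """
    counts, s, n, sires = _prepare(data)
    if len(sires) < 2:
        raise InsufficientGroupsError("at least 2 sires with offspring are required")
    if s.sum() <= 0 or s.sum() >= n.sum():
        raise BoundaryDegenerateError("need at least one success and one failure overall")
    if not bin_effect:
        alpha, tau2, ll, _, conv = _fit_alt_arrays(s, n, n_quad=n_quad, start=start)
        return ModelFit(alpha, tau2, ll, conv, n_quad, len(sires), int(n.sum()))
    return _fit_alternative_bins(counts, n_quad, start)


def _fit_alternative_bins(counts: pd.DataFrame, n_quad: int, start):
    """Alternative fit with additive bin fixed effects (first bin is baseline)."""
    pivot_s = counts.pivot_table(index="sire", columns="bin", values="settled", aggfunc="sum", fill_value=0)
    pivot_n = pivot_s + counts.pivot_table(
        index="sire", columns="bin", values="swimming", aggfunc="sum", fill_value=0
    )
    keep = pivot_n.sum(axis=1) > 0
    S = pivot_s.loc[keep].to_numpy(dtype=np.float64)
    N = pivot_n.loc[keep].to_numpy(dtype=np.float64)
    bins = list(pivot_s.columns)
    null = fit_null(counts, bin_effect=True)
    x, logw_xx = _gh_rule(n_quad)
    n_bins = len(bins)
    if start is None:
        a0 = null.alpha
        t0 = _moment_start(S.sum(axis=1), N.sum(axis=1))
    else:
        a0, t0 = start

    def objective(theta):
        gamma = np.concatenate(([0.0], theta[1:n_bins]))
        return _negll_bins_arrays(theta[0], gamma, math.exp(theta[-1]), S, N, x, logw_xx)

    theta0 = np.concatenate(([a0], [null.bin_effects[b] for b in bins[1:]], [math.log(max(t0, 1e-6))]))
    res = minimize(objective, theta0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": FIT_TOL, "maxiter": 4 * MAX_ITER, "maxfev": 8 * MAX_ITER})
    ll_alt = -res.fun
    n_obs = int(N.sum())
    if null.loglik >= ll_alt:
        return ModelFit(null.alpha, 0.0, null.loglik, True, n_quad, int(keep.sum()), n_obs, null.bin_effects)
    effects = {bins[0]: 0.0}
    effects.update({b: float(g) for b, g in zip(bins[1:], res.x[1:n_bins])})
    return ModelFit(float(res.x[0]), float(math.exp(res.x[-1])), float(ll_alt), bool(res.success),
                    n_quad, int(keep.sum()), n_obs, effects)


def lrt_statistic(alt: ModelFit, null: ModelFit) -> float:
    """Likelihood-ratio statistic 2*(loglik_alt - loglik_null), clipped at 0.

    Equivalent to the deviance difference of the nested pair; tiny
    negative values from numerical noise are clipped to zero.
    """
    if alt.n_obs != null.n_obs:
        raise DataMismatchError(
            f"fits disagree on data size ({alt.n_obs} vs {null.n_obs} observations)"
        )
    stat = 2.0 * (alt.loglik - null.loglik)
    return stat if stat > 0.0 else 0.0
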