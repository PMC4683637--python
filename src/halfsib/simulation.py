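"""Synthetic half-sib settlement data, null-distribution and power machinery.

The generator mirrors the statistical structure of the coral settlement
study: a handful of sires whose offspring are spread over replicate
bins, with the number of genotyped offspring per sire per bin drawn
from a negative binomial (study values: mean 4.63, variance 12.63,
i.e. size = mu^2/(variance - mu)), and each larva settling with
probability logistic(logit(p_settle) + beta_i), p_settle = 0.285 being
the study's global settlement rate.  Under the null (tau2 = 0) the only
among-sire variability is sampling noise.

On top of the generator sit (a) a Monte Carlo approximation to the true
null distribution of the likelihood-ratio statistic, for comparison
with the asymptotic 50:50 point-mass/chi2(1) mixture, and (b) a power /
false-positive-rate calculator driven by the permutation test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import chi2

from . import model
from .heritability import h2_sire
from .permutation import _perm_lrts_arrays

logger = logging.getLogger("halfsib")

# study conditions (9 sires, 3 replicate bins, global settlement 0.285,
# negative binomial genotyped-offspring counts with mean 4.63, variance 12.63)
STUDY_N_SIRES = 9
STUDY_N_BINS = 3
STUDY_MU_OFFSPRING = 4.63
STUDY_VAR_OFFSPRING = 12.63
STUDY_P_SETTLE = 0.285


class InvalidOverdispersionError(ValueError):
    """Negative binomial requires variance strictly greater than the mean."""


@dataclass
class SimulationDesign:
    """Parameters of one simulated half-sib settlement experiment.

    Defaults are the study conditions.  ``tau2`` is the true among-sire
    variance on the logit scale (0 for null designs); ``marginal_p``
    chooses whether ``p_settle`` is the conditional (latent-scale
    intercept, default) or the marginal settlement probability.
    """

    n_sires: int = STUDY_N_SIRES
    n_bins: int = STUDY_N_BINS
    mu_offspring: float = STUDY_MU_OFFSPRING
    var_offspring: float = STUDY_VAR_OFFSPRING
    p_settle: float = STUDY_P_SETTLE
    tau2: float = 0.0
    n_datasets: int = 1000
    seed: int = 0
    marginal_p: bool = False

    def __post_init__(self):
        if self.n_sires < 1 or self.n_bins < 1 or self.n_datasets < 1:
            raise ValueError("n_sires, n_bins and n_datasets must be positive")
        if not 0 < self.p_settle < 1:
            raise ValueError("p_settle must lie in (0, 1)")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if self.var_offspring <= self.mu_offspring:
            raise InvalidOverdispersionError(
                "var_offspring must exceed mu_offspring (negative binomial)"
            )

    @property
    def size_offspring(self) -> float:
        return negbin_size(self.mu_offspring, self.var_offspring)


def study_design(**overrides) -> SimulationDesign:
    """The study-condition design, optionally with fields overridden."""
    return SimulationDesign(**overrides)


@dataclass
class NullDistribution:
    """Monte Carlo sample of the LRT statistic under tau2 = 0, with its ECDF."""

    lrt_values: np.ndarray
    ecdf: Callable[[float], float]
    n_resimulated: int = 0


def negbin_size(mu: float, variance: float) -> float:
    """Negative binomial size parameter giving the stated mean and variance."""
    if variance <= mu:
        raise InvalidOverdispersionError("variance must exceed the mean")
    return mu * mu / (variance - mu)


def offspring_size_for_mu(mu: float) -> float:
    """Size parameter when mu varies but the variance:mean ratio stays at the
    study value 12.63/4.63."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return mu * mu / (mu * (STUDY_VAR_OFFSPRING / STUDY_MU_OFFSPRING) - mu)


def _conditional_alpha(design: SimulationDesign) -> float:
    """Latent-scale intercept; optionally solved so the marginal mean is p_settle."""
    a0 = float(logit(design.p_settle))
    if not design.marginal_p or design.tau2 <= 0:
        return a0
    x, w = np.polynomial.hermite_e.hermegauss(61)
    w = w / w.sum()
    sd = math.sqrt(design.tau2)

    def marginal(a):
        return float(np.sum(w * expit(a + sd * x))) - design.p_settle

    return brentq(marginal, a0 - 10.0, a0 + 10.0)


def _draw_counts(design: SimulationDesign, rng: np.random.Generator):
    """Offspring totals and settled counts per sire x bin as integer matrices."""
    size = design.size_offspring
    p_nb = size / (size + design.mu_offspring)
    n = rng.negative_binomial(size, p_nb, size=(design.n_sires, design.n_bins))
    alpha = _conditional_alpha(design)
    if design.tau2 > 0:
        beta = rng.normal(0.0, math.sqrt(design.tau2), size=design.n_sires)
    else:
        beta = np.zeros(design.n_sires)
    p = expit(alpha + beta)
    s = rng.binomial(n, p[:, None])
    return s, n


def _counts_to_frame(s: np.ndarray, n: np.ndarray) -> pd.DataFrame:
    n_sires, n_bins = s.shape
    sires = [f"S{i+1}" for i in range(n_sires)]
    rows = {
        "sire": np.repeat(sires, n_bins),
        "bin": list(np.tile([str(b + 1) for b in range(n_bins)], n_sires)),
        "settled": s.ravel(),
        "swimming": (n - s).ravel(),
    }
    return pd.DataFrame(rows)


def simulate_null_dataset(design: SimulationDesign, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One count table under the null: equal settlement probability for all sires."""
    if design.tau2 != 0:
        raise ValueError("null simulation requires tau2 = 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    s, n = _draw_counts(design, rng)
    return _counts_to_frame(s, n)


def simulate_alt_dataset(design: SimulationDesign, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One count table with sire effects beta_i ~ N(0, tau2) on the logit scale."""
    if design.tau2 <= 0:
        raise ValueError("alternative simulation requires tau2 > 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    s, n = _draw_counts(design, rng)
    return _counts_to_frame(s, n)


def _draw_fittable(design: SimulationDesign, rng: np.random.Generator):
    """Draw per-sire (settled, total) arrays, resimulating degenerate tables.

    A table is degenerate when fewer than 2 sires have offspring or the
    pooled outcome is all-success/all-failure.  Returns (s, n, n_resim).
    """
    n_resim = 0
    while True:
        s, n = _draw_counts(design, rng)
        s_tot = s.sum(axis=1).astype(np.float64)
        n_tot = n.sum(axis=1).astype(np.float64)
        keep = n_tot > 0
        if keep.sum() >= 2 and 0 < s_tot.sum() < n_tot.sum():
            return s_tot[keep], n_tot[keep], n_resim
        n_resim += 1


def null_lrt_distribution(
    design: SimulationDesign, n_quad: int = model.DEFAULT_N_QUAD
) -> NullDistribution:
    """Monte Carlo sample of the LRT statistic under the null design.

    Simulates ``design.n_datasets`` count tables with tau2 = 0, fits the
    alternative and null models to each, and returns the statistics with
    their (right-continuous) empirical CDF.
    """
    if design.tau2 != 0:
        raise ValueError("null distribution requires a tau2 = 0 design")
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    values = np.empty(design.n_datasets)
    total_resim = 0
    for d in range(design.n_datasets):
        s, n, n_resim = _draw_fittable(design, rng)
        total_resim += n_resim
        _, _, ll_alt, ll_null, _ = model._fit_alt_arrays(s, n, n_quad=n_quad)
        values[d] = max(0.0, 2.0 * (ll_alt - ll_null))
    if total_resim:
        logger.info("resimulated %d degenerate null datasets", total_resim)
    return NullDistribution(values, ecdf_from_sample(values), total_resim)


def ecdf_from_sample(values: np.ndarray) -> Callable[[float], float]:
    """Right-continuous empirical CDF of a sample, usable on scalars or arrays."""
    srt = np.sort(np.asarray(values, dtype=float))
    m = len(srt)

    def ecdf(x):
        r = np.searchsorted(srt, np.asarray(x, dtype=float), side="right") / m
        return float(r) if r.ndim == 0 else r

    return ecdf


def theoretical_mixture_cdf(x):
    """Asymptotic boundary null: 50% point mass at 0 plus 50% chi2(1).

    CDF is 0 for x < 0 and 0.5 + 0.5 * Chi2CDF(x; 1) for x >= 0.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, 0.0, 0.5 + 0.5 * chi2.cdf(np.clip(x, 0.0, None), df=1))
    return float(out) if out.ndim == 0 else out


def ks_distance_samples(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov distance between ECDFs (handles ties)."""
    a, b = np.sort(np.asarray(a, float)), np.sort(np.asarray(b, float))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def ks_distance_cdf(sample: np.ndarray, cdf: Callable) -> float:
    """Sup distance between a sample's ECDF and a reference CDF.

    Evaluates both the right and left limits of the ECDF at each sample
    point, so point masses (the atom at 0) are handled exactly.
    """
    srt = np.sort(np.asarray(sample, dtype=float))
    m = len(srt)
    f = np.asarray(cdf(srt), dtype=float)
    upper = np.arange(1, m + 1) / m - f
    lower = f - np.arange(0, m) / m
    return float(max(upper.max(), lower.max()))


def power_analysis(
    designs: Sequence[SimulationDesign],
    alpha: float = 0.05,
    n_perm: int = 500,
    n_quad: int = model.DEFAULT_N_QUAD,
) -> pd.DataFrame:
    """Rejection rate of the permutation LRT across a grid of designs.

    For each design, ``design.n_datasets`` tables are simulated and the
    permutation test (``n_perm`` shuffles) is run on each; the returned
    ``rejection_rate`` is the fraction of datasets with p <= alpha.  For
    tau2 > 0 designs this is statistical power, for tau2 = 0 designs the
    false-positive rate.  ``mc_se`` is the binomial Monte Carlo standard
    error of the rate.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for design in designs:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed))
        n_reject = 0
        for _ in range(design.n_datasets):
            s, n, _ = _draw_fittable(design, rng)
            _, _, ll_alt, ll_null, _ = model._fit_alt_arrays(s, n, n_quad=n_quad)
            observed = max(0.0, 2.0 * (ll_alt - ll_null))
            # expand to offspring level for the sire-label shuffle
            n_int = n.astype(np.int64)
            sire_idx = np.repeat(np.arange(len(n_int)), n_int)
            outcome = np.zeros(int(n_int.sum()))
            pos = 0
            for i in range(len(n_int)):
                outcome[pos : pos + int(s[i])] = 1.0
                pos += n_int[i]
            perm = _perm_lrts_arrays(sire_idx, outcome, len(n_int), n_perm, rng, n_quad)
            p = (1.0 + np.sum(perm >= observed - 1e-9)) / (n_perm + 1.0)
            if p <= alpha:
                n_reject += 1
        rate = n_reject / design.n_datasets
        se = math.sqrt(rate * (1.0 - rate) / design.n_datasets)
        logger.info(
            "design(n_sires=%d, tau2=%.4g): rejection rate %.3f (MC SE %.3f)",
            design.n_sires, design.tau2, rate, se,
        )
        rows.append(
            {
                "n_sires": design.n_sires,
                "n_bins": design.n_bins,
                "mu": design.mu_offspring,
                "h2": h2_sire(design.tau2),
                "tau2": design.tau2,
                "n_datasets": design.n_datasets,
                "n_perm": n_perm,
                "rejection_rate": rate,
                "mc_se": se,
            }
        )
    return pd.DataFrame(rows)
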