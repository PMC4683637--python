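"""Latent-scale variance ratios and sire-model narrow-sense heritability.

Binary outcomes are viewed as thresholded liabilities with logistic
error, whose variance is pi^2/3.  The among-sire variance tau2 then
yields the latent-scale variance ratio (Bayesian R^2)

    R^2 = tau2 / (tau2 + pi^2/3),

and, because half-sibs share one quarter of their additive genetic
variance, the sire-model narrow-sense heritability is h^2 = 4 R^2.
The x4 step is an approximation and can exceed 1; estimates are kept
unclamped, with a clamped-to-[0, 1] companion for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from .io import aggregate_counts
from .model import InvalidParameterError

#: variance of the standard logistic distribution (the latent error term)
LOGISTIC_VARIANCE = math.pi**2 / 3.0


class UnstableBootstrapError(RuntimeError):
    """More than 20% of bootstrap replicates were degenerate."""


@dataclass
class HeritabilityEstimate:
    """Point estimate plus bootstrap uncertainty for tau2 and h^2.

    ``tau2``/``r2_latent``/``h2`` refer to the fit on the original data;
    ``boot_mean_tau2``/``boot_sd`` summarize the bootstrap replicates of
    tau2-hat, and the CI is the percentile interval of the clamped h^2.
    """

    tau2: float
    r2_latent: float
    h2: float
    h2_clamped: float
    ci_lower: float
    ci_upper: float
    boot_sd: float
    boot_mean_tau2: float
    n_boot: int
    n_dropped: int


def latent_r2(tau2: float) -> float:
    """Latent-scale variance ratio tau2 / (tau2 + pi^2/3)."""
    tau2 = np.asarray(tau2, dtype=float)
    if np.any(tau2 < 0) or not np.all(np.isfinite(tau2)):
        raise InvalidParameterError("tau2 must be finite and nonnegative")
    out = tau2 / (tau2 + LOGISTIC_VARIANCE)
    return float(out) if out.ndim == 0 else out


def h2_sire(tau2: float) -> float:
    """Sire-model narrow-sense heritability, 4x the latent variance ratio."""
    r2 = latent_r2(tau2)
    return 4.0 * r2


def tau2_from_h2(h2: float) -> float:
    """Invert the sire-model transform: tau2 such that h2_sire(tau2) == h2."""
    h2 = np.asarray(h2, dtype=float)
    if np.any(h2 < 0) or np.any(h2 >= 4) or not np.all(np.isfinite(h2)):
        raise InvalidParameterError("h2 must lie in [0, 4)")
    out = h2 * LOGISTIC_VARIANCE / (4.0 - h2)
    return float(out) if out.ndim == 0 else out


def _resample_offspring(sire, bins, outcome, rng):
    """Resample outcomes with replacement within each sire x bin stratum."""
    out = np.empty_like(outcome)
    order = np.lexsort((bins, sire))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    so, bo, yo = sire[order], bins[order], outcome[order]
    start = 0
    for stop in range(1, len(so) + 1):
        if stop == len(so) or so[stop] != so[start] or bo[stop] != bo[start]:
            k = stop - start
            pick = rng.integers(0, k, size=k)
            out[order[start:stop]] = yo[start + pick]
            start = stop
    return sire, bins, out


def _resample_sires(sire, bins, outcome, rng):
    """Resample whole sire clusters with replacement; copies get fresh labels."""
    labels = np.unique(sire)
    picks = rng.integers(0, len(labels), size=len(labels))
    parts_s, parts_b, parts_y = [], [], []
    for new_id, idx in enumerate(picks):
        mask = sire == labels[idx]
        parts_s.append(np.full(mask.sum(), new_id))
        parts_b.append(bins[mask])
        parts_y.append(outcome[mask])
    return np.concatenate(parts_s), np.concatenate(parts_b), np.concatenate(parts_y)


def bootstrap_heritability(
    data,
    n_boot: int = 1000,
    scheme: str = "offspring",
    seed: int = 0,
    n_quad: int = model.DEFAULT_N_QUAD,
) -> HeritabilityEstimate:
    """Bootstrap the heritability estimate from an offspring table.

    ``scheme="offspring"`` resamples larvae with replacement within each
    sire x bin stratum (keeping the design fixed); ``scheme="sire"``
    resamples whole sire clusters.  Replicates whose resample is
    all-success or all-failure (or has < 2 sires) cannot be fitted and
    are dropped; if more than 20% drop, the bootstrap is declared
    unstable.  The 95% CI is the percentile interval of h^2 clamped to
    [0, 1] for reporting.
    """
    if scheme not in ("offspring", "sire", "sire-cluster"):
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    off = model.as_offspring_table(data)
    sire = off["sire"].to_numpy()
    bins = off["bin"].to_numpy()
    outcome = off["outcome"].to_numpy(dtype=np.int64)

    def fit_tau2(s_lab, b_lab, y):
        df = pd.DataFrame({"sire": s_lab, "bin": b_lab, "outcome": y})
        counts = aggregate_counts(df)
        s, n, sires = model._collapse(counts)
        if len(sires) < 2 or s.sum() <= 0 or s.sum() >= n.sum():
            return None
        _, tau2, _, _, _ = model._fit_alt_arrays(s, n, n_quad=n_quad)
        return tau2

    point = fit_tau2(sire, bins, outcome)
    if point is None:
        raise model.BoundaryDegenerateError("original data cannot be fitted")

    resample = _resample_offspring if scheme == "offspring" else _resample_sires
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reps = []
    dropped = 0
    for _ in range(n_boot):
        t2 = fit_tau2(*resample(sire, bins, outcome, rng))
        if t2 is None:
            dropped += 1
        else:
            reps.append(t2)
    if dropped > 0.2 * n_boot:
        raise UnstableBootstrapError(
            f"{dropped}/{n_boot} bootstrap replicates were degenerate"
        )
    reps = np.asarray(reps)
    h2_reps = np.clip(4.0 * reps / (reps + LOGISTIC_VARIANCE), 0.0, 1.0)
    lo, hi = np.percentile(h2_reps, [2.5, 97.5])
    h2 = h2_sire(point)
    return HeritabilityEstimate(
        tau2=float(point),
        r2_latent=latent_r2(point),
        h2=float(h2),
        h2_clamped=float(min(max(h2, 0.0), 1.0)),
        ci_lower=float(lo),
        ci_upper=float(hi),
        boot_sd=float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0,
        boot_mean_tau2=float(np.mean(reps)),
        n_boot=n_boot,
        n_dropped=dropped,
    )
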