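"""Permutation likelihood-ratio test for the among-sire variance.

The null hypothesis tau2 = 0 lies on the boundary of the parameter
space, so the usual chi-square asymptotics (a 50:50 mixture of a point
mass at zero and chi2(1)) need not hold in finite samples.  The test
here sidesteps asymptotics entirely: it shuffles the sire labels of the
offspring (keeping each larva's bin and outcome attached), refits the
random-effects model to every shuffled table, and compares the observed
likelihood-ratio statistic against that permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model

logger = logging.getLogger("halfsib")

DEFAULT_N_PERM = 500
#: permuted statistics within this of the observed count as ties (>=)
TIE_TOL = 1e-9


@dataclass
class PermutationResult:
    """Observed LRT, the permutation null sample, and the empirical p-value.

    The p-value uses the add-one rule (1 + #{perm >= observed}) /
    (n_perm + 1), which counts the observed arrangement among the
    permutations and so can never be zero.
    """

    observed_lrt: float
    perm_lrts: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def permute_sire_labels(data, seed: int, within_bin: bool = False) -> pd.DataFrame:
    """Return a copy of the offspring table with sire labels shuffled.

    The multiset of sire labels is preserved (each label keeps its
    multiplicity); bins and outcomes stay attached to their larvae.
    With ``within_bin=True`` labels are only shuffled among larvae of
    the same replicate bin.
    """
    off = model.as_offspring_table(data)
    if off["sire"].nunique() < 2:
        raise model.InsufficientGroupsError("need at least 2 sires to permute")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = off.copy()
    sires = out["sire"].to_numpy()
    if within_bin:
        for _, idx in out.groupby("bin").indices.items():
            sires[idx] = sires[rng.permutation(idx)]
        out["sire"] = sires
    else:
        out["sire"] = sires[rng.permutation(len(sires))]
    return out


def _perm_lrts_arrays(
    sire_idx: np.ndarray,
    outcome: np.ndarray,
    n_sires: int,
    n_perm: int,
    rng: np.random.Generator,
    n_quad: int,
    bin_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Fast path: LRT statistics for ``n_perm`` sire-label shuffles.

    Works on integer-coded arrays; a shuffled replicate whose fit does
    not converge is refitted from a perturbed start, and recorded as 0
    with a warning if it still fails.
    """
    out = np.empty(n_perm)
    n_obs = len(sire_idx)
    for r in range(n_perm):
        if bin_idx is None:
            perm = rng.permutation(n_obs)
        else:
            perm = np.arange(n_obs)
            for b in np.unique(bin_idx):
                idx = np.flatnonzero(bin_idx == b)
                perm[idx] = idx[rng.permutation(len(idx))]
        lab = sire_idx[perm]
        n = np.bincount(lab, minlength=n_sires).astype(np.float64)
        s = np.bincount(lab, weights=outcome, minlength=n_sires)
        keep = n > 0
        s, n = s[keep], n[keep]
        alpha, tau2, ll_alt, ll_null, conv = model._fit_alt_arrays(s, n, n_quad=n_quad)
        if not conv:
            alpha2, tau22, ll2, _, conv2 = model._fit_alt_arrays(
                s, n, n_quad=n_quad, start=(alpha + 0.1, max(tau2, 0.1) * 2.0)
            )
            if conv2 and ll2 > ll_alt:
                ll_alt = ll2
            elif not conv2:
                logger.warning("permutation replicate %d failed to converge; recorded as 0", r)
                out[r] = 0.0
                continue
        out[r] = max(0.0, 2.0 * (ll_alt - ll_null))
    return out


def permutation_lrt_test(
    data,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    n_quad: int = model.DEFAULT_N_QUAD,
    within_bin: bool = False,
) -> PermutationResult:
    """Empirical p-value for the among-sire variance by sire-label shuffling.

    Fits the model to the observed offspring table, then to ``n_perm``
    tables with sire labels randomly reassigned, and reports the
    add-one Monte Carlo p-value.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    off = model.as_offspring_table(data)
    sire_codes, _ = pd.factorize(off["sire"], sort=True)
    if sire_codes.max() + 1 < 2:
        raise model.InsufficientGroupsError("need at least 2 sires")
    outcome = off["outcome"].to_numpy(dtype=np.float64)
    n_sires = int(sire_codes.max()) + 1
    n = np.bincount(sire_codes, minlength=n_sires).astype(np.float64)
    s = np.bincount(sire_codes, weights=outcome, minlength=n_sires)
    keep = n > 0
    _, _, ll_alt, ll_null, _ = model._fit_alt_arrays(s[keep], n[keep], n_quad=n_quad)
    observed = max(0.0, 2.0 * (ll_alt - ll_null))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bin_idx = pd.factorize(off["bin"])[0] if within_bin else None
    perm = _perm_lrts_arrays(sire_codes, outcome, n_sires, n_perm, rng, n_quad, bin_idx)
    p = (1.0 + np.sum(perm >= observed - TIE_TOL)) / (n_perm + 1.0)
    return PermutationResult(float(observed), perm, float(p), n_perm, seed)
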