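"""Marginal likelihood, fitting and the likelihood-ratio statistic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

import halfsib as hs
from halfsib import model

from conftest import make_offspring


def counts(rows):
    return pd.DataFrame(rows, columns=["sire", "bin", "settled", "swimming"])


def oracle_negloglik(alpha, tau2, s, n):
    """Independent adaptive-quadrature evaluation of the same marginal integral."""
    sd = math.sqrt(tau2)
    total = 0.0
    for si, ni in zip(s, n):
        def integrand(b):
            p = expit(alpha + b)
            return p**si * (1 - p) ** (ni - si) * norm.pdf(b, 0.0, sd)

        val, _ = quad(integrand, -12 * sd - 6, 12 * sd + 6, limit=400)
        total -= math.log(val)
    return total


class TestMarginalNegloglik:
    def test_two_fair_bernoullis(self):
        data = counts([("A", "1", 1, 1)])
        assert hs.marginal_negloglik(0.0, 0.0, data) == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_tau2_zero_is_closed_form_binomial(self):
        data = counts([("A", "1", 3, 2), ("B", "1", 1, 4), ("B", "2", 2, 0)])
        for alpha in (-1.3, 0.0, 0.7):
            expected = -(6 * alpha - 12 * np.logaddexp(0.0, alpha))
            assert hs.marginal_negloglik(alpha, 0.0, data) == pytest.approx(expected, abs=1e-10)

    def test_two_sire_example_matches_oracle(self):
        data = counts([("A", "1", 2, 1), ("B", "1", 0, 2)])
        got = hs.marginal_negloglik(-0.5, 1.0, data, n_quad=41)
        want = oracle_negloglik(-0.5, 1.0, [2, 0], [3, 2])
        assert got == pytest.approx(want, abs=1e-6)

    def test_oracle_agreement_random_small_datasets(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n_sires = rng.integers(1, 6)
            n = rng.integers(1, 9, n_sires)
            s = rng.binomial(n, 0.4)
            data = counts([(f"S{i}", "1", int(s[i]), int(n[i] - s[i])) for i in range(n_sires)])
            alpha = rng.uniform(-2, 2)
            tau2 = rng.uniform(0.0, 5.0)
            got = hs.marginal_negloglik(alpha, tau2, data)
            want = oracle_negloglik(alpha, tau2, s, n)
            assert got == pytest.approx(want, abs=1e-6)

    def test_monotone_node_refinement(self):
        data = counts([("A", "1", 5, 2), ("B", "1", 1, 6), ("C", "1", 3, 3)])
        ref = hs.marginal_negloglik(-0.3, 0.8, data, n_quad=81)
        errs = [abs(hs.marginal_negloglik(-0.3, 0.8, data, n_quad=k) - ref) for k in (11, 21, 41)]
        assert errs[0] >= errs[1] - 1e-12
        assert errs[1] >= errs[2] - 1e-12

    def test_invalid_parameters(self):
        data = counts([("A", "1", 1, 1)])
        with pytest.raises(hs.InvalidParameterError):
            hs.marginal_negloglik(np.nan, 0.5, data)
        with pytest.raises(hs.InvalidParameterError):
            hs.marginal_negloglik(0.0, -0.1, data)

    def test_empty_data_warns_and_returns_zero(self):
        empty = counts([])
        with pytest.warns(UserWarning):
            assert hs.marginal_negloglik(0.0, 1.0, empty) == 0.0


class TestFitNull:
    def test_pooled_logit_from_study_counts(self):
        # 37 assigned settlers and 81 assigned swimmers pooled
        data = counts([("A", "1", 37, 81)] )
        fit = hs.fit_null(data)
        assert fit.tau2 == 0.0
        assert fit.alpha == pytest.approx(math.log(37 / 81), abs=1e-12)
        assert fit.alpha == pytest.approx(-0.78353, abs=1e-5)

    def test_symmetric_counts_give_zero_logit(self):
        fit = hs.fit_null(counts([("A", "1", 5, 5)]))
        assert fit.alpha == 0.0

    def test_loglik_consistent_with_negloglik(self):
        data = counts([("A", "1", 3, 2), ("B", "1", 1, 4)])
        fit = hs.fit_null(data)
        assert fit.loglik == pytest.approx(-hs.marginal_negloglik(fit.alpha, 0.0, data), abs=1e-10)

    def test_degenerate_pooled_proportion(self):
        with pytest.raises(hs.BoundaryDegenerateError):
            hs.fit_null(counts([("A", "1", 4, 0), ("B", "1", 2, 0)]))


class TestFitAlternative:
    def test_identical_ratios_hit_boundary(self):
        data = counts([(s, b, 2, 3) for s in "ABCD" for b in "123"])
        fit = hs.fit_alternative(data)
        assert fit.tau2 < 1e-6
        null = hs.fit_null(data)
        assert hs.lrt_statistic(fit, null) < 1e-6

    def test_alternative_never_below_null(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n_sires = rng.integers(2, 6)
            n = rng.integers(1, 8, n_sires)
            s = rng.binomial(n, rng.uniform(0.2, 0.8))
            if s.sum() == 0 or s.sum() == n.sum():
                continue
            out = model._fit_alt_arrays(s.astype(float), n.astype(float))
            assert out[2] >= out[3] - 1e-10  # loglik_alt >= loglik_null
            assert 2 * (out[2] - out[3]) >= -1e-10

    def test_parameter_recovery_at_tau2_half(self):
        """Mean tau2-hat over 20 simulations at 100 sires x 200 offspring is
        within +-0.1 of the true 0.5."""
        rng = np.random.default_rng(7)
        alpha = math.log(0.285 / 0.715)
        estimates = []
        for _ in range(20):
            beta = rng.normal(0, math.sqrt(0.5), 100)
            n = np.full(100, 200.0)
            s = rng.binomial(200, expit(alpha + beta)).astype(float)
            estimates.append(model._fit_alt_arrays(s, n)[1])
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.1)

    def test_bias_shrinks_with_sample_size(self):
        rng = np.random.default_rng(123)
        alpha = math.log(0.285 / 0.715)

        def mean_bias(n_sires, n_off, tau2, reps):
            est = []
            for _ in range(reps):
                beta = rng.normal(0, math.sqrt(tau2), n_sires)
                n = np.full(n_sires, float(n_off))
                s = rng.binomial(n_off, expit(alpha + beta)).astype(float)
                est.append(model._fit_alt_arrays(s, n)[1])
            return np.mean(est) - tau2

        for tau2 in (0.25, 0.5, 1.0):
            small = mean_bias(15, 25, tau2, 12)
            large = mean_bias(100, 200, tau2, 12)
            assert abs(large) < abs(small) + 0.05

    def test_errors(self):
        with pytest.raises(hs.InsufficientGroupsError):
            hs.fit_alternative(counts([("A", "1", 2, 3)]))
        with pytest.raises(hs.BoundaryDegenerateError):
            hs.fit_alternative(counts([("A", "1", 2, 0), ("B", "1", 3, 0)]))

    def test_bin_effect_fit_runs_and_nests(self, study_counts):
        alt = hs.fit_alternative(study_counts, bin_effect=True)
        null = hs.fit_null(study_counts, bin_effect=True)
        assert alt.loglik >= null.loglik - 1e-8
        assert set(alt.bin_effects) == set(study_counts["bin"].unique())


class TestLrtStatistic:
    def test_arithmetic(self):
        a = hs.ModelFit(0.0, 0.5, -50.0, True, 21, 5, 60)
        b = hs.ModelFit(0.0, 0.0, -52.5, True, 1, 5, 60)
        assert hs.lrt_statistic(a, b) == pytest.approx(5.0)
        assert hs.lrt_statistic(b, b) == 0.0

    def test_mismatched_fits_rejected(self):
        a = hs.ModelFit(0.0, 0.5, -50.0, True, 21, 5, 60)
        b = hs.ModelFit(0.0, 0.0, -52.5, True, 1, 5, 61)
        with pytest.raises(hs.DataMismatchError):
            hs.lrt_statistic(a, b)


@pytest.mark.parametrize("tau2_true", [0.4])
def test_agrees_with_lme4(tmp_path, tau2_true):
    """Cross-check the fit against lme4's glmer (adaptive GH, nAGQ=25)."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rng = np.random.default_rng(5)
    n = rng.integers(8, 20, 12).astype(float)
    beta = rng.normal(0, math.sqrt(tau2_true), 12)
    s = rng.binomial(n.astype(int), expit(-0.9 + beta)).astype(float)
    off = make_offspring(
        np.repeat([f"S{i}" for i in range(12)], n.astype(int)),
        "1",
        np.concatenate([
            np.r_[np.ones(int(si)), np.zeros(int(ni - si))] for si, ni in zip(s, n)
        ]).astype(int),
    )
    csv = tmp_path / "off.csv"
    off.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(outcome ~ 1 + (1 | sire), data = d, family = binomial, nAGQ = 25)
        cat(fixef(m)[1], as.numeric(VarCorr(m)$sire[1]), sep = "\\n")
        """
    )
    res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    r_alpha, r_tau2 = map(float, res.stdout.split())
    fit = hs.fit_alternative(hs.aggregate_counts(off))
    assert fit.alpha == pytest.approx(r_alpha, abs=5e-3)
    assert fit.tau2 == pytest.approx(r_tau2, abs=1e-2)
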