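"""Unit and property tests for the two model features and feature handling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tremorlab import features as ft


def garch_series(n, omega, alpha, beta, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n + 200)
    e = np.empty(n + 200)
    s2 = omega / (1.0 - alpha - beta)
    for i in range(n + 200):
        e[i] = np.sqrt(s2) * z[i]
        s2 = omega + alpha * e[i] ** 2 + beta * s2
    return e[200:]


def ar2_series(n, a1, a2, seed=0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n + 200)
    eps = rng.standard_normal(n + 200)
    for i in range(2, n + 200):
        x[i] = a1 * x[i - 1] + a2 * x[i - 2] + eps[i]
    return x[200:]


class TestArResiduals:
    def test_ar2_coefficient_recovery(self):
        x = ar2_series(4000, 0.5, -0.3, seed=1)
        order, resid, coeffs = ft.fit_ar_residuals(x, max_order=4)
        assert order >= 2
        assert coeffs[0] == pytest.approx(0.5, abs=0.1)
        assert coeffs[1] == pytest.approx(-0.3, abs=0.1)
        assert resid.shape[0] == x.shape[0] - order

    def test_white_noise_residuals_uncorrelated(self):
        x = ar2_series(3000, 0.6, -0.2, seed=2)
        _, resid, _ = ft.fit_ar_residuals(x)
        r1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert abs(r1) < 0.05


class TestGarchFilter:
    def test_matches_direct_recursion(self):
        rng = np.random.default_rng(0)
        resid = rng.standard_normal(500)
        omega, alpha, beta = 0.05, 0.1, 0.8
        fast = ft._garch11_filter(resid, omega, alpha, beta)
        slow = np.empty_like(fast)
        slow[0] = np.var(resid)
        for i in range(1, resid.shape[0]):
            slow[i] = omega + alpha * resid[i - 1] ** 2 + beta * slow[i - 1]
        np.testing.assert_allclose(fast, slow, rtol=1e-10)


class TestGarchFit:
    def test_parameter_recovery_single_run(self):
        e = garch_series(6000, 0.1, 0.1, 0.8, seed=3)
        fit = ft.fit_garch11(e)
        assert fit.converged
        assert fit.alpha == pytest.approx(0.1, abs=0.08)
        assert fit.beta == pytest.approx(0.8, abs=0.12)

    def test_gaussian_residuals_pass_ks(self):
        e = garch_series(3000, 0.1, 0.1, 0.8, seed=4)
        fit = ft.fit_garch11(e)
        ks = stats.kstest(fit.standardized_residuals, "norm").statistic
        assert ks < 0.03

    def test_standardized_residuals_unit_scale(self):
        e = garch_series(2000, 0.2, 0.15, 0.7, seed=5)
        fit = ft.fit_garch11(e)
        assert np.std(fit.standardized_residuals) == pytest.approx(1.0, abs=0.1)

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            ft.fit_garch11(np.random.default_rng(0).standard_normal(100))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ft.fit_garch11(np.zeros(500))


class TestGarchKsFeature:
    def test_amplitude_invariance_exact(self):
        rng = np.random.default_rng(6)
        t = np.arange(1500) / 100.0
        x = np.sin(2 * np.pi * 5 * t) + 0.2 * rng.standard_normal(1500)
        a = ft.garch_ks_feature(x)
        b = ft.garch_ks_feature(123.456 * x)
        assert a == pytest.approx(b, abs=1e-9)

    def test_skewed_innovations_raise_ks(self):
        # one-sided shocks leave an asymmetric standardized-residual
        # distribution that no conditional-variance model can whiten
        rng = np.random.default_rng(7)
        t = np.arange(1500) / 100.0
        base = np.sin(2 * np.pi * 5 * t)
        sym = base + 0.15 * rng.standard_normal(1500)
        skew_noise = 0.15 * (rng.exponential(1.0, 1500) - 1.0)
        skewed = base + skew_noise + 0.6 * (rng.random(1500) < 0.02)
        assert ft.garch_ks_feature(skewed) > ft.garch_ks_feature(sym)


class TestHmm:
    def test_single_state_equals_closed_form(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(800)
        fit = ft.fit_gaussian_hmm(x, n_states=1, seed=0)
        closed = ft.gaussian_loglik_per_sample(x)
        assert abs(fit.train_log_likelihood_per_sample - closed) < 1e-6

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-2, 1, 400), rng.normal(2, 1, 400)])
        rng.shuffle(x)
        fit = ft.fit_gaussian_hmm(x, n_states=2, seed=1)
        trace = np.asarray(fit.log_likelihood_trace)
        assert trace.shape[0] >= 2
        assert np.all(np.diff(trace) >= -1e-8)

    def test_two_state_mean_recovery(self):
        rng = np.random.default_rng(10)
        state = (rng.random(2000) < 0.5).astype(int)
        # persistent regimes: flip with small probability
        for i in range(1, 2000):
            state[i] = state[i - 1] if rng.random() < 0.95 else 1 - state[i - 1]
        x = np.where(state == 1, 2.0, -2.0) + rng.standard_normal(2000)
        # best of a few EM restarts: single runs can hit local optima
        fits = [ft.fit_gaussian_hmm(x, n_states=2, seed=s) for s in range(3)]
        fit = max(fits, key=lambda f: f.log_likelihood_trace[-1])
        means = np.sort(fit.means)
        assert means[0] == pytest.approx(-2.0, abs=0.3)
        assert means[1] == pytest.approx(2.0, abs=0.3)

    def test_regime_structure_raises_feature(self):
        rng = np.random.default_rng(11)
        t = np.arange(1500) / 100.0
        flat = np.sin(2 * np.pi * 5 * t) + 0.1 * rng.standard_normal(1500)
        scale = np.where((t % 6) < 3, 1.0, 0.2)
        regimes = scale * np.sin(2 * np.pi * 5 * t) + 0.1 * rng.standard_normal(1500)
        f_flat = ft.hmm_compare_nstates_feature(flat / np.std(flat), seed=3)
        f_reg = ft.hmm_compare_nstates_feature(regimes / np.std(regimes), seed=3)
        assert np.isfinite(f_flat) and np.isfinite(f_reg)

    def test_feature_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(1000)
        a = ft.hmm_compare_nstates_feature(x, seed=7)
        b = ft.hmm_compare_nstates_feature(x, seed=7)
        assert a == b

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ft.hmm_compare_nstates_feature(np.random.default_rng(0).normal(size=40))


class TestFeatureMatrix:
    def _matrix(self):
        return ft.FeatureMatrix(pd.DataFrame(
            {"a": [0.1, 0.5, 0.9], "b": [1.0, np.nan, 3.0], "c": [2.0, 2.0, 2.0]},
            index=["r1", "r2", "r3"]))

    def test_filter_drops_nan_and_constant(self):
        filtered = ft.filter_invalid_features(self._matrix())
        assert filtered.feature_names == ["a"]
        assert set(filtered.removed) == {"b", "c"}

    def test_minmax_normalization_bounds_stored(self):
        m = ft.filter_invalid_features(self._matrix())
        norm = ft.minmax_normalize_features(m)
        vals = norm.values["a"].to_numpy()
        assert vals.min() == pytest.approx(0.0)
        assert vals.max() == pytest.approx(1.0)
        assert norm.bounds["a"] == pytest.approx((0.1, 0.9))

    def test_apply_normalization_does_not_clip(self):
        m = ft.filter_invalid_features(self._matrix())
        norm = ft.minmax_normalize_features(m)
        held_out = ft.FeatureMatrix(pd.DataFrame({"a": [1.3]}, index=["h1"]))
        out = ft.apply_normalization(held_out, norm.bounds)
        assert out.values["a"].iloc[0] == pytest.approx((1.3 - 0.1) / 0.8)
        assert any("out-of-bounds" in f for f in out.flags)

    def test_attach_external_rejects_collisions(self):
        m = self._matrix()
        with pytest.raises(ValueError):
            ft.attach_external_features(
                m, pd.DataFrame({"a": [1, 2, 3]}, index=["r1", "r2", "r3"]))

    def test_attach_external_rejects_unmatched_keys(self):
        m = self._matrix()
        with pytest.raises(KeyError):
            ft.attach_external_features(
                m, pd.DataFrame({"z": [1.0]}, index=["nope"]))
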