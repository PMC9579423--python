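"""Unit and property tests of the vARNN recurrence and its ARNN limit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vartime as vt
from vartime.varnn import (History, Prediction, VARNNParams, activation,
                           arnn_predict, generate_next, predict, sample_weights,
                           weight_variance)


def make_params(**kw):
    defaults = dict(p=1, w=np.array([0.5]), b=0.0,
                    sigma_plus_sq=0.01, sigma_minus_sq=0.04, sigma0_sq=0.01)
    defaults.update(kw)
    return VARNNParams(**defaults)


class TestWeightVariance:
    def test_reward_selects_variance(self):
        p = make_params()
        assert weight_variance(1, p) == 0.01
        assert weight_variance(0, p) == 0.04

    def test_reward_independence_limit(self):
        p = make_params(sigma_plus_sq=0.03, sigma_minus_sq=0.03)
        assert weight_variance(0, p) == weight_variance(1, p) == 0.03

    def test_non_binary_reward_rejected(self):
        with pytest.raises(ValueError):
            weight_variance(0.5, make_params())


class TestActivation:
    @pytest.mark.parametrize("x,expected", [(-1.5, -1.0), (0.2, 0.2), (-1.0, -1.0)])
    def test_shifted_hinge(self, x, expected):
        assert activation(x) == expected

    @given(st.floats(-100, 100))
    @settings(derandomize=True)
    def test_floor_at_minus_one(self, x):
        assert activation(x) >= -1.0


class TestSampleWeights:
    def test_zero_variance_returns_mean_weights(self, rng):
        p = make_params(sigma_plus_sq=0.0, sigma_minus_sq=0.0)
        assert np.array_equal(sample_weights(p, [1.0], rng), p.w)

    def test_moments_of_effective_weights(self, rng):
        p = make_params(p=2, w=np.array([0.5, -0.3]), sigma_minus_sq=0.09)
        draws = np.array([sample_weights(p, [0.0, 1.0], rng) for _ in range(100_000)])
        # means preserved (4 SE), variances w_i^2 * var(r_i) (5%)
        se = np.sqrt([0.25 * 0.09, 0.09 * 0.01]) / np.sqrt(1e5)
        assert np.all(np.abs(draws.mean(axis=0) - p.w) < 4 * se)
        expected_var = p.w**2 * np.array([0.09, 0.01])
        assert np.allclose(draws.var(axis=0), expected_var, rtol=0.05)


class TestGenerateNext:
    def test_zero_history_zero_noise(self, rng):
        p = make_params(sigma_plus_sq=0, sigma_minus_sq=0, sigma0_sq=0)
        assert generate_next(p, History([0.0], [0]), rng) == 0.0

    def test_deterministic_linear_step(self, rng):
        p = make_params(sigma_plus_sq=0, sigma_minus_sq=0, sigma0_sq=0)
        assert generate_next(p, History([0.2], [0]), rng) == pytest.approx(0.1)

    def test_monte_carlo_mean_in_linear_regime(self, rng):
        p = make_params()
        draws = [generate_next(p, History([0.2], [0]), rng) for _ in range(100_000)]
        # hinge inactive here, so the mean equals the pre-activation mean 0.1
        assert np.mean(draws) == pytest.approx(0.1, abs=4 * np.sqrt(0.0104 / 1e5))

    def test_non_finite_history_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_next(make_params(), History([np.nan], [0]), rng)


class TestPredict:
    def test_closed_form_example(self):
        pr = predict(make_params(), History([0.2], [0]))
        assert pr.mean == pytest.approx(0.1)
        assert pr.variance == pytest.approx(0.5**2 * 0.2**2 * 0.04 + 0.01)

    def test_arnn_reduction_variance_is_output_noise(self, rng):
        p = make_params(p=3, w=np.array([0.3, 0.2, 0.1]),
                        sigma_plus_sq=0, sigma_minus_sq=0, sigma0_sq=0.02)
        for _ in range(20):
            h = History(rng.normal(0, 0.2, 3), rng.integers(0, 2, 3))
            assert predict(p, h).variance == pytest.approx(0.02)

    def test_zero_history_variance_is_output_noise(self):
        p = make_params(sigma_minus_sq=0.5)
        assert predict(p, History([0.0], [0])).variance == pytest.approx(0.01)

    def test_variance_exceeds_output_noise(self, rng):
        p = make_params()
        for _ in range(20):
            h = History(rng.normal(0, 0.2, 1), rng.integers(0, 2, 1))
            assert predict(p, h).variance >= p.sigma0_sq

    def test_reward_gated_variance_ordering(self):
        p = make_params()  # sigma_minus > sigma_plus
        v0 = predict(p, History([0.2], [0])).variance
        v1 = predict(p, History([0.2], [1])).variance
        assert v0 > v1

    def test_variance_monotone_in_previous_error(self):
        p = make_params()
        vs = [predict(p, History([e], [0])).variance for e in (0.0, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(vs) > 0)


class TestArnnPredict:
    def test_requires_zero_weight_noise(self):
        with pytest.raises(ValueError):
            arnn_predict(make_params(), History([0.1], [0]))

    def test_matches_predict(self, rng):
        p = make_params(sigma_plus_sq=0, sigma_minus_sq=0)
        h = History([0.15], [1])
        assert arnn_predict(p, h) == predict(p, h)

    def test_noise_free_geometric_decay(self, rng):
        p = make_params(sigma_plus_sq=0, sigma_minus_sq=0, sigma0_sq=0)
        e = 1.0
        for n in range(1, 101):
            e = generate_next(p, History([e], [0]), rng)
            assert e == pytest.approx(0.5**n)


class TestMonteCarloVarianceOracle:
    def test_closed_form_matches_simulation(self, rng):
        """Spot-check of the linear-regime variance formula against the
        generator on a handful of random configurations (the full 100-config
        sweep runs in the acceptance suite)."""
        for _ in range(5):
            p_order = int(rng.integers(1, 4))
            params = make_params(
                p=p_order,
                w=rng.uniform(0.05, 0.5, p_order),
                sigma_plus_sq=rng.uniform(0.01, 0.2),
                sigma_minus_sq=rng.uniform(0.01, 0.4),
                sigma0_sq=rng.uniform(0.005, 0.02),
            )
            h = History(rng.uniform(-0.2, 0.2, p_order), rng.integers(0, 2, p_order))
            draws = np.array([generate_next(params, h, rng) for _ in range(50_000)])
            assert draws.var() == pytest.approx(predict(params, h).variance, rel=0.05)


class TestStationarity:
    def test_bounded_long_run(self):
        """Sub-unit total weight keeps 10,000-step closed-loop output bounded."""
        params = vt.presets.default_varnn_params()
        assert np.abs(params.w).sum() < 1
        s = vt.simulate_session(vt.VARNNSampler(params), 10_000, seed=9)
        assert np.isfinite(s.e).all()
        assert np.abs(s.e).max() < 2.0

    def test_means_floored_at_minus_one(self, rng):
        p = make_params(sigma0_sq=0.0)
        for _ in range(50):
            h = History(rng.normal(0, 1.0, 1), rng.integers(0, 2, 1))
            assert predict(p, h).mean >= -1.0
            assert generate_next(p, h, rng) >= -1.0


class TestParamsIO:
    def test_round_trip_bit_exact(self, tmp_path):
        p = make_params(p=3, w=np.array([0.1234567890123, -0.2, 1e-17]))
        path = tmp_path / "params.json"
        p.save(path)
        q = VARNNParams.load(path)
        assert q.p == p.p and np.array_equal(q.w, p.w)
        assert (q.b, q.sigma_plus_sq, q.sigma_minus_sq, q.sigma0_sq) == (
            p.b, p.sigma_plus_sq, p.sigma_minus_sq, p.sigma0_sq)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VARNNParams(p=0, w=np.array([]))
        with pytest.raises(ValueError):
            VARNNParams(p=1, w=np.array([0.1]), sigma0_sq=-1.0)
        with pytest.raises(ValueError):
            VARNNParams(p=2, w=np.array([0.1]))
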