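"""Tests of the training machinery: objectives, penalty, splits, early
stopping, reparameterized gradients, and small fitting controls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vartime as vt
from vartime.training import (Design, EarlyStopping, TrainingConfig,
                              build_design, penalty, reparam_loss_and_grads,
                              rwmse, rwmse_null, split_data, total_loss, wmse)
from vartime.varnn import VARNNParams


class TestWmse:
    def test_uniform_unit_variances_reduce_to_mse(self, rng):
        m = rng.normal(size=50)
        y = rng.normal(size=50)
        assert wmse(m, y, np.ones(50)) == pytest.approx(np.mean((m - y) ** 2))

    def test_direct_arithmetic(self):
        assert wmse([1, 1], [0, 0], [1, 4]) == pytest.approx(0.625)

    def test_perfect_forecasts(self):
        assert wmse([0.3, -0.1], [0.3, -0.1], [0.5, 0.2]) == 0.0

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            wmse([1.0], [0.0], [0.0])


class TestRwmse:
    def test_constant_residual_weights_cancel(self, rng):
        assert rwmse(np.full(30, 1.5), np.full(30, 0.5), rng) == pytest.approx(1.0)

    def test_expectation_matches_unweighted_mean(self, rng):
        m = rng.normal(size=40)
        y = rng.normal(size=40)
        draws = rwmse_null(m, y, n_replicates=10_000, rng=rng)
        target = np.mean((m - y) ** 2)
        # self-normalized random weighting is unbiased-ish for the plain mean
        assert draws.mean() == pytest.approx(target, rel=0.02)


class TestPenalty:
    def cfg(self, lam1=1.0, lam2=1.0):
        return TrainingConfig(lambda1=lam1, lambda2=lam2)

    def test_closed_form_minimum(self):
        p = VARNNParams(p=3, w=np.zeros(3), sigma_plus_sq=0.2, sigma_minus_sq=0.2)
        assert penalty(p, self.cfg()) == pytest.approx(2.0)

    def test_weight_term_saturates(self):
        p = VARNNParams(p=1, w=np.array([1e6]), sigma_plus_sq=0.1, sigma_minus_sq=0.1)
        assert penalty(p, self.cfg(lam2=0.0)) == pytest.approx(1.0, abs=1e-6)

    def test_ratio_term_arithmetic(self):
        p = VARNNParams(p=1, w=np.zeros(1), sigma_plus_sq=0.1, sigma_minus_sq=0.4)
        assert penalty(p, self.cfg(lam1=0.0)) == pytest.approx(4.25)

    def test_zero_variance_with_ratio_term_rejected(self):
        p = VARNNParams(p=1, w=np.zeros(1), sigma_plus_sq=0.0, sigma_minus_sq=0.1)
        with pytest.raises(ValueError):
            penalty(p, self.cfg())

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=8),
           st.floats(0.01, 5), st.floats(0.01, 5))
    @settings(derandomize=True, max_examples=50)
    def test_floor_two_lambda2(self, w, sp, sm):
        p = VARNNParams(p=len(w), w=np.array(w), sigma_plus_sq=sp, sigma_minus_sq=sm)
        assert penalty(p, self.cfg()) >= 2.0 - 1e-12


class TestTotalLoss:
    def test_zero_penalty_equals_residual(self, rng):
        p = VARNNParams(p=1, w=np.array([0.5]), sigma0_sq=1.0)
        X = rng.normal(size=(20, 1))
        R = rng.integers(0, 2, size=(20, 1)).astype(float)
        y = rng.normal(size=20)
        cfg = TrainingConfig(lambda1=0.0, lambda2=0.0)
        expected = wmse(np.maximum(X[:, 0] * 0.5, -1), y, np.ones(20))
        assert total_loss(p, (X, R, y), cfg) == pytest.approx(expected)

    def test_perfect_deterministic_model(self):
        p = VARNNParams(p=1, w=np.array([0.5]), sigma0_sq=1.0)
        X = np.array([[0.2], [0.4]])
        R = np.zeros((2, 1))
        y = np.array([0.1, 0.2])
        cfg = TrainingConfig(lambda1=0.0, lambda2=0.0)
        assert total_loss(p, (X, R, y), cfg) == 0.0


class TestSplitData:
    def design(self, n=100, sessions=1):
        per = n // sessions
        return Design(X=np.zeros((n, 1)), R=np.zeros((n, 1)), y=np.zeros(n),
                      session_id=np.repeat(np.arange(sessions), per))

    def test_exact_eighty_twenty(self):
        tr, va = split_data(self.design(100), 0.8, seed=0)
        assert len(tr) == 80 and len(va) == 20

    def test_disjoint_exhaustive(self):
        d = self.design(90, sessions=3)
        tr, va = split_data(d, 0.8, seed=1)
        assert set(tr) & set(va) == set()
        assert np.array_equal(np.sort(np.concatenate([tr, va])), np.arange(90))

    def test_reproducible(self):
        d = self.design(100)
        assert np.array_equal(split_data(d, 0.8, 5)[0], split_data(d, 0.8, 5)[0])


class TestEarlyStopping:
    def test_triggers_at_tenth_consecutive_epoch(self):
        """Scripted curve: training keeps falling, validation stalls above it;
        the rule fires exactly when the streak reaches the patience."""
        stop = EarlyStopping(patience=10)
        stopped_at = None
        for epoch in range(40):
            train = 0.1 if epoch >= 5 else 1.0
            val = 0.5 if epoch < 5 else 0.6  # improves early, then stalls above train
            if stop.update(train, val):
                stopped_at = epoch
                break
        assert stopped_at == 14  # streak of val > train began at epoch 5
        assert stop.streak == 10

    def test_no_trigger_while_validation_improves(self):
        stop = EarlyStopping(patience=3)
        val = 1.0
        for _ in range(50):
            val *= 0.99  # always above train but improving
            assert not stop.update(0.1, val)

    def test_min_epochs_defers_stop(self):
        stop = EarlyStopping(patience=2, min_epochs=10)
        fired = [stop.update(0.1, 0.5) for _ in range(10)]
        assert not any(fired[:9]) and fired[9]


class TestReparameterization:
    def test_gradient_estimate_is_unbiased(self, rng):
        """Average reparameterized gradient vs a finite difference of the
        Monte-Carlo expectation on an order-1 toy problem."""
        X = rng.normal(0, 0.2, size=(8, 1))
        R = rng.integers(0, 2, size=(8, 1)).astype(float)
        y = rng.normal(0, 0.2, size=8)
        g = np.ones(8)
        w0, sp, sm = np.array([0.4]), 0.04, 0.16

        n_mc = 10_000
        xis = rng.standard_normal((n_mc, 8, 1))
        grads = np.array([
            reparam_loss_and_grads(w0, 0.0, X, R, y, sp, sm, g, xi)[1][0]
            for xi in xis])

        eps = 1e-4
        def mc_loss(w):
            return np.mean([
                reparam_loss_and_grads(np.array([w]), 0.0, X, R, y, sp, sm, g, xi)[0]
                for xi in xis])
        fd = (mc_loss(0.4 + eps) - mc_loss(0.4 - eps)) / (2 * eps)
        se = grads.std() / np.sqrt(n_mc)
        assert grads.mean() == pytest.approx(fd, abs=4 * se + 1e-6)

    def test_zero_noise_matches_deterministic_loss(self, rng):
        X = rng.normal(size=(10, 1))
        R = np.zeros((10, 1))
        y = rng.normal(size=10)
        xi = rng.standard_normal((10, 1))
        loss, _, _ = reparam_loss_and_grads(np.array([0.3]), 0.0, X, R, y,
                                            0.0, 0.0, np.ones(10), xi)
        det = np.mean((np.maximum(0.3 * X[:, 0], -1) - y) ** 2)
        assert loss == pytest.approx(det)


class TestFitControls:
    def test_arnn_weight_recovery(self):
        """Weights of a known additive-noise generator are recovered to
        better than 0.05 per coefficient from 10 sessions x 1,000 trials."""
        truth = VARNNParams(p=1, w=np.array([0.5]), sigma0_sq=0.01)
        sessions = vt.simulate_sessions(vt.VARNNSampler(truth), 10, 1000, seed=42)
        fit = vt.fit_varnn(sessions, TrainingConfig(p=5, n_restarts=2,
                                                    epochs=400, seed=0))
        padded = np.zeros(5)
        padded[0] = 0.5
        assert np.abs(fit.params.w - padded).max() < 0.05

    def test_shuffled_data_has_no_structure(self, low_order_sessions):
        """Destroying trial order drives fitted weights toward zero and the
        validation residual toward one."""
        rng = np.random.default_rng(8)
        shuffled = []
        for s in low_order_sessions[:5]:
            perm = rng.permutation(len(s))
            shuffled.append(vt.Session(t_p=s.t_p[perm], t_t=s.t_t[perm],
                                       e=s.e[perm], r=s.r[perm]))
        fit = vt.fit_varnn(shuffled, TrainingConfig(p=5, n_restarts=2,
                                                    epochs=300, seed=1))
        assert np.abs(fit.params.w).max() < 0.08
        assert fit.residual_ratio == pytest.approx(1.0, abs=0.08)

    def test_gru_learns_on_structured_not_on_noise(self, rng):
        truth = VARNNParams(p=1, w=np.array([0.6]), sigma0_sq=0.01)
        structured = vt.simulate_sessions(vt.VARNNSampler(truth), 2, 800, seed=13)
        cfg = TrainingConfig(n_restarts=1, epochs=150, seed=5)
        fit = vt.fit_gru(structured, cfg, variant="gru1")
        assert fit.residual_ratio < 0.85

        noise = [vt.Session.from_errors(rng.normal(0, 0.1, 800),
                                        rng.integers(0, 2, 800)) for _ in range(2)]
        fit0 = vt.fit_gru(noise, cfg, variant="gru2")
        assert fit0.residual_ratio == pytest.approx(1.0, abs=0.1)

    def test_divergent_fit_raises_with_context(self, low_order_sessions):
        import warnings

        cfg = TrainingConfig(n_restarts=1, epochs=100, gru_learning_rate=1e5,
                             hidden_size=4, seed=0)
        with pytest.raises(RuntimeError, match="restart 0"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vt.fit_gru(low_order_sessions[:1], cfg)

    def test_reward_blind_params_average_variances(self):
        p = vt.presets.low_order_varnn_params()
        q = vt.reward_blind_params(p)
        avg = 0.5 * (p.sigma_plus_sq + p.sigma_minus_sq)
        assert q.sigma_plus_sq == q.sigma_minus_sq == pytest.approx(avg)
        assert np.array_equal(q.w, p.w)
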