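"""Model fitting: heteroscedastic weighted-MSE objective, complexity penalty,
randomly-weighted null, and SGD training of the vARNN/ARNN and GRU models.

The residual term is the inverse-variance weighted MSE (Aitken weighting),

    Res_wMSE = (1/N) sum_n g_n [e_hat_n - e_n]^2,   g_n = 1 / sigma_n^2,

which reduces to the ordinary MSE under uniform weights.  The penalty

    P = lambda1 * (1/p) sum_i [ 2 / (1 + exp(-c1 |w_i|^(1/c2))) - 1 ]
      + lambda2 * [ sigma_minus_sq/sigma_plus_sq + sigma_plus_sq/sigma_minus_sq ]

combines a smooth sparsity surrogate on the autoregressive weights (steep near
zero, saturating at 1) with a symmetric term keeping the two weight-noise
variances in a reasonable ratio.

Training alternates, per epoch, a weighted-least-squares step on the mean
parameters — with the trial weights g_n frozen at the epoch's start
(iteratively-reweighted scheme) and the weight noise reparameterized as
w_i * (1 + sqrt(var(r)) * xi), xi ~ Normal(0,1), so the gradient flows through
the deterministic path — and Gaussian likelihood steps on the three noise
variances.  The likelihood step carries the log sigma_n^2 normalizer that the
squared-error term alone lacks; without it the noise variances are not
identifiable (shrinking them only ever reduces a frozen-weight squared error).
All gradients are analytic; no autodiff framework is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gru import (GRUParams, VARIANTS, gru_backward, gru_forward, variant_inputs)
from .task_sim import Session
from .varnn import VARNNParams, activation
from .analysis import residual_ratio

__all__ = [
    "TrainingConfig",
    "FitResult",
    "Design",
    "build_design",
    "split_data",
    "wmse",
    "rwmse",
    "rwmse_null",
    "penalty",
    "total_loss",
    "reparam_loss_and_grads",
    "EarlyStopping",
    "fit_varnn",
    "fit_arnn",
    "fit_gru",
    "reward_blind_params",
]

_LOGVAR_MIN, _LOGVAR_MAX = math.log(1e-8), math.log(10.0)


@dataclass
class TrainingConfig:
    """Hyperparameters shared by the fitting routines.

    ``lambda1``/``lambda2`` default to 0.01 * var(e) of the training data when
    left as None.  ``p`` is the autoregressive order the vARNN/ARNN fit is
    initialized with; the sparsity penalty shrinks surplus lags toward zero.
    """

    p: int = 20
    lambda1: float | None = None
    lambda2: float | None = None
    c1: float = 3.0
    c2: float = 3.0
    split_fraction: float = 0.8
    learning_rate: float = 1e-2
    lr_variance: float = 0.1
    variance_steps: int = 2          # likelihood updates of the noise variances per epoch
    variance_warmup: int = 50        # epochs before the noise variances start updating
    min_epochs: int = 100            # epochs before early stopping can trigger
    epochs: int = 500
    segment_length: int = 100        # GRU training segment length (50% overlap)
    n_restarts: int = 10
    patience: int = 10
    objective: str = "wmse"          # "wmse" or "mse"
    hidden_size: int = 32
    l1: float = 1e-4                 # GRU gate-weight L1 coefficient
    gru_learning_rate: float = 0.2
    gru_momentum: float = 0.9
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.objective not in ("wmse", "mse"):
            raise ValueError("objective must be 'wmse' or 'mse'")


@dataclass
class FitResult:
    """Outcome of a multi-restart fit: best-validation parameters, the
    normalized validation residual, and per-epoch loss history."""

    params: object
    residual_ratio: float
    loss_history: list
    restart_losses: list
    seed: int | None = None

    def __post_init__(self):
        if self.residual_ratio < 0:
            raise ValueError("residual ratio must be non-negative")


# ---------------------------------------------------------------------------
# data plumbing


@dataclass
class Design:
    """Lagged regression layout pooled over sessions.

    Row n holds the p-lag history of one forecast target: ``X[n, i]`` and
    ``R[n, i]`` are the error and feedback i+1 trials back, ``y[n]`` the target
    error.  The first p trials of each session (incomplete histories) are
    excluded.
    """

    X: np.ndarray
    R: np.ndarray
    y: np.ndarray
    session_id: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def rows(self, idx) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.X[idx], self.R[idx], self.y[idx]


def build_design(sessions, p: int) -> Design:
    """Assemble the lag matrices from one or more sessions (burn-in excluded)."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    Xs, Rs, ys, sid = [], [], [], []
    for k, s in enumerate(sessions):
        T = len(s)
        if T <= p:
            continue
        e, r = s.e, s.r.astype(float)
        n_t = T - p
        X = np.empty((n_t, p))
        R = np.empty((n_t, p))
        for i in range(p):
            X[:, i] = e[p - 1 - i : T - 1 - i]
            R[:, i] = r[p - 1 - i : T - 1 - i]
        Xs.append(X)
        Rs.append(R)
        ys.append(e[p:])
        sid.append(np.full(n_t, k))
    if not Xs:
        raise ValueError(f"no session has more than p={p} trials")
    return Design(np.concatenate(Xs), np.concatenate(Rs), np.concatenate(ys),
                  np.concatenate(sid))


def split_data(design: Design, split_fraction: float = 0.8,
               seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation indices over forecast targets,
    sampled randomly without replacement within each session."""
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for k in np.unique(design.session_id):
        idx = np.nonzero(design.session_id == k)[0]
        perm = rng.permutation(idx)
        n_train = int(round(split_fraction * idx.size))
        train.append(perm[:n_train])
        val.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(val))


# ---------------------------------------------------------------------------
# objective pieces


def wmse(forecast_means, observations, variances) -> float:
    """(1/N) sum g_n [e_hat_n - e_n]^2 with g_n = 1/sigma_n^2."""
    m = np.asarray(forecast_means, dtype=float)
    y = np.asarray(observations, dtype=float)
    v = np.asarray(variances, dtype=float)
    if not (m.shape == y.shape == v.shape):
        raise ValueError("forecasts, observations and variances must have equal length")
    if (v <= 0).any():
        raise ValueError("non-positive predictive variance: degenerate model weighting")
    return float(np.mean((m - y) ** 2 / v))


def rwmse(forecast_means, observations, rng: np.random.Generator) -> float:
    """Self-normalized randomly-weighted residual: sum g [m - y]^2 / sum g,
    g ~ Uniform(0, 1). One draw; see :func:`rwmse_null` for the null."""
    m = np.asarray(forecast_means, dtype=float)
    y = np.asarray(observations, dtype=float)
    if m.shape != y.shape:
        raise ValueError("forecasts and observations must have equal length")
    g = rng.uniform(0.0, 1.0, size=m.size)
    return float(g @ (m - y) ** 2 / g.sum())


def rwmse_null(forecast_means, observations, n_replicates: int = 1000,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Null distribution of the randomly-weighted residual (fresh uniform
    weights per replicate)."""
    rng = rng or np.random.default_rng()
    return np.array([rwmse(forecast_means, observations, rng)
                     for _ in range(n_replicates)])


def _sparsity_term(w: np.ndarray, c1: float, c2: float) -> float:
    u = np.abs(w) ** (1.0 / c2)
    return float(np.mean(2.0 / (1.0 + np.exp(-c1 * u)) - 1.0))


def _sparsity_grad(w: np.ndarray, c1: float, c2: float) -> np.ndarray:
    a = np.maximum(np.abs(w), 1e-8)
    u = a ** (1.0 / c2)
    ex = np.exp(-c1 * u)
    dpen_du = 2.0 * ex * c1 / (1.0 + ex) ** 2
    du_dw = (1.0 / c2) * a ** (1.0 / c2 - 1.0) * np.sign(w)
    return dpen_du * du_dw / w.size


def penalty(params: VARNNParams, config: TrainingConfig,
            ratio_term: bool = True) -> float:
    """Complexity penalty P: sparsity surrogate on weights plus the symmetric
    variance-ratio term (lambda2 * [x + 1/x], minimized at equal variances)."""
    lam1 = 0.0 if config.lambda1 is None else config.lambda1
    lam2 = 0.0 if config.lambda2 is None else config.lambda2
    P = lam1 * _sparsity_term(params.w, config.c1, config.c2)
    if ratio_term and lam2 > 0.0:
        sp, sm = params.sigma_plus_sq, params.sigma_minus_sq
        if sp <= 0 or sm <= 0:
            raise ValueError("variance-ratio penalty requires positive weight-noise variances")
        P += lam2 * (sm / sp + sp / sm)
    return float(P)


def total_loss(params: VARNNParams, data, config: TrainingConfig,
               ratio_term: bool | None = None) -> float:
    """Loss = Res + P on the given rows (a Design, or (X, R, y) arrays).

    The residual uses the deterministic forecast mean and, for the wMSE
    objective, the closed-form predictive variances as weights.
    """
    X, R, y = (data.X, data.R, data.y) if isinstance(data, Design) else data
    mean = activation(X @ params.w + params.b)
    if ratio_term is None:
        ratio_term = not params.is_arnn
    if config.objective == "wmse":
        S = params.sigma_plus_sq * R + params.sigma_minus_sq * (1.0 - R)
        var = (X**2 * S) @ params.w**2 + params.sigma0_sq
        res = wmse(mean, y, var)
    else:
        res = float(np.mean((mean - y) ** 2))
    return res + penalty(params, config, ratio_term=ratio_term)


def reparam_loss_and_grads(w, b, X, R, y, sigma_plus_sq, sigma_minus_sq, g, xi):
    """Frozen-weight wMSE of one reparameterized weight-noise draw, with its
    analytic gradients w.r.t. (w, b).

    The effective weight on lag i of row n is w_i * (1 + s_{ni} xi_{ni}) with
    s = sqrt(sigma(r)); the draw ``xi`` is exogenous, so this is an unbiased
    estimator of the expected loss and its gradient over the weight noise.
    Returns (loss, grad_w, grad_b).
    """
    w = np.asarray(w, dtype=float)
    s = np.sqrt(sigma_plus_sq * R + sigma_minus_sq * (1.0 - R))
    Xeff = X * (1.0 + s * xi)
    z = Xeff @ w + b
    e_hat = activation(z)
    rho = e_hat - y
    n = y.size
    loss = float(np.mean(g * rho**2))
    live = (z > -1.0).astype(float)
    core = (2.0 / n) * g * rho * live
    return loss, core @ Xeff, float(core.sum())


class EarlyStopping:
    """Stop when the validation loss exceeds the training loss for
    ``patience`` consecutive epochs, none of which improved on the best
    validation loss so far.

    The second clause guards against a false trigger right at the start of
    training: with a fixed split the validation half can sit persistently
    (slightly) above the training half for reasons of sampling alone, even
    while both are still falling.  A sustained val > train streak with no new
    validation optimum is the overfitting signature the rule is after.
    """

    def __init__(self, patience: int = 10, min_epochs: int = 0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_epochs = min_epochs
        self.streak = 0
        self.best_val = np.inf
        self.best_epoch = -1
        self.epoch = -1

    def update(self, train_loss: float, val_loss: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        self.epoch += 1
        improved = val_loss < self.best_val
        if improved:
            self.best_val = val_loss
            self.best_epoch = self.epoch
        self.streak = self.streak + 1 if (val_loss > train_loss and not improved) else 0
        return self.streak >= self.patience and self.epoch + 1 >= self.min_epochs


# ---------------------------------------------------------------------------
# vARNN / ARNN fitting


def _varnn_variances(X, R, w, sp, sm, s0):
    return (X**2 * (sp * R + sm * (1.0 - R))) @ w**2 + s0


def _fit_noise_variances(rho_sq, Ap, Am, lam2, starts=None):
    """Maximum-likelihood noise variances for fixed mean parameters.

    Minimizes mean(rho^2/var + log var) + lam2 * (sm/sp + sp/sm) over
    (sigma_plus_sq, sigma_minus_sq, sigma0_sq) in log space with L-BFGS from
    several starts; var_n = Ap_n * sp + Am_n * sm + s0.  Direct minimization
    avoids the instability of iteratively-reweighted updates when the
    squared-residual noise is heavy-tailed.
    """
    from scipy.optimize import minimize

    n = rho_sq.size
    s_tot = float(rho_sq.mean())

    def nll_and_grad(lv):
        sp, sm, s0 = np.exp(lv)
        var = Ap * sp + Am * sm + s0
        nll = float(np.mean(rho_sq / var + np.log(var)))
        dvar = (1.0 / var - rho_sq / var**2) / n
        grad = np.array([dvar @ Ap, dvar @ Am, dvar.sum()]) * np.exp(lv)
        if lam2 > 0:
            nll += lam2 * (sm / sp + sp / sm)
            grad[0] += lam2 * (1.0 / sm - sm / sp**2) * sp
            grad[1] += lam2 * (1.0 / sp - sp / sm**2) * sm
        return nll, grad

    if starts is None:
        starts = [
            np.log([0.01, 0.01, s_tot]),
            np.log([0.2, 0.2, 0.5 * s_tot]),
            np.log([0.05, 0.4, 0.7 * s_tot]),
        ]
    bounds = [(np.log(1e-8), np.log(2.0))] * 2 + [(np.log(1e-10), np.log(10.0))]
    best, best_val = None, np.inf
    for x0 in starts:
        out = minimize(nll_and_grad, np.clip(x0, -18, 0.7), jac=True,
                       method="L-BFGS-B", bounds=bounds)
        if out.fun < best_val:
            best, best_val = out.x, out.fun
    return tuple(np.exp(best))


def _variance_irls_step(rho_sq, Ap, Am, var_prev, floor):
    """One iteratively-reweighted step toward the Gaussian-ML noise variances.

    The likelihood stationarity condition sum_n (var_n - rho_n^2) F_nj /
    var_n^2 = 0 is a weighted least-squares fit of rho^2 on the variance
    design F = [Ap, Am, 1] with weights 1/var^2; iterating with weights from
    the previous iterate is standard IRLS for variance models.  Solved with a
    non-negativity constraint and floored away from zero.
    """
    from scipy.optimize import nnls

    F = np.column_stack([Ap, Am, np.ones_like(Ap)])
    sw = 1.0 / var_prev
    theta, _ = nnls(F * sw[:, None], rho_sq * sw)
    return np.maximum(theta, floor)


def _nll_score(params: VARNNParams, X, R, y, config, ratio_term: bool) -> float:
    """Penalized Gaussian negative log-likelihood (up to constants) used for
    epoch and restart selection: mean(rho^2/var + log var) + P.

    Unlike the raw weighted residual, this is a proper scoring rule in the
    noise variances — the bare wMSE can be driven to zero by inflating them.
    """
    rho = y - activation(X @ params.w + params.b)
    var = _varnn_variances(X, R, params.w, params.sigma_plus_sq,
                           params.sigma_minus_sq, params.sigma0_sq)
    nll = float(np.mean(rho**2 / var + np.log(var)))
    return nll + penalty(params, config, ratio_term=ratio_term)


def _fit_varnn_once(design, tr, va, config, rng, fix_weight_noise, lam1, lam2):
    p = design.p
    Xt, Rt, yt = design.rows(tr)
    Xv, Rv, yv = design.rows(va)
    n_tr = yt.size

    w = rng.normal(0.0, 0.1, size=p)
    b = 0.0
    vel_w = np.zeros(p)
    vel_b = 0.0
    momentum = 0.9
    # Polyak-style averaging of the mean parameters: the reparameterized
    # gradient is stochastic, so the iterates jitter around the optimum even
    # after convergence; the trailing average removes that jitter
    ema_w, ema_b, ema_rate = w.copy(), 0.0, 0.1
    var_y = float(design.y.var())
    if fix_weight_noise:
        sp = sm = 0.0
        s0 = var_y
    else:
        sp = sm = 0.01
        s0 = 0.5 * var_y
    lv = np.log(np.maximum([sp, sm, s0], 1e-8))

    stopper = EarlyStopping(config.patience, config.min_epochs)
    best = None
    best_candidate_val = np.inf
    history = []
    warmup = min(config.variance_warmup, max(config.epochs - 1, 0))
    Xt_sq = Xt**2
    Ap_base = Xt_sq * Rt
    Am_base = Xt_sq * (1.0 - Rt)

    for epoch in range(config.epochs):
        sp, sm, s0 = (0.0, 0.0, float(np.exp(lv[2]))) if fix_weight_noise else tuple(np.exp(lv))
        # ---- frozen weights for this epoch
        if config.objective == "wmse":
            g_tr = 1.0 / _varnn_variances(Xt, Rt, w, sp, sm, s0)
        else:
            g_tr = np.ones(n_tr)
        # ---- mean step on a fresh reparameterized draw
        xi = rng.standard_normal((n_tr, p)) if not fix_weight_noise else np.zeros((n_tr, p))
        _, gw, gb = reparam_loss_and_grads(w, b, Xt, Rt, yt, sp, sm, g_tr, xi)
        gw = gw + lam1 * _sparsity_grad(w, config.c1, config.c2)
        vel_w = momentum * vel_w - config.learning_rate * gw
        vel_b = momentum * vel_b - config.learning_rate * gb
        w = w + vel_w
        b = b + vel_b
        if epoch < warmup:
            ema_w, ema_b = w.copy(), b
        else:
            ema_w = (1.0 - ema_rate) * ema_w + ema_rate * w
            ema_b = (1.0 - ema_rate) * ema_b + ema_rate * b
        # ---- noise-variance likelihood steps (on the averaged mean model)
        rho = yt - activation(Xt @ ema_w + ema_b)
        rho_sq = rho**2
        if fix_weight_noise:
            lv[2] = np.clip(np.log(max(float(rho_sq.mean()), 1e-8)),
                            _LOGVAR_MIN, _LOGVAR_MAX)
            s0 = float(np.exp(lv[2]))
        elif epoch >= warmup:
            Ap = Ap_base @ ema_w**2
            Am = Am_base @ ema_w**2
            for _ in range(config.variance_steps):
                sp, sm, s0 = np.exp(lv)
                var = Ap * sp + Am * sm + s0
                prop = _variance_irls_step(rho_sq, Ap, Am, var, floor=1e-6)
                # geometric half-step damping: the squared-residual regression
                # has heavy-tailed noise, and an undamped jump to an inflated
                # weight-noise variance collapses the trial weights
                lv_prop = np.log(np.maximum(prop, 1e-8))
                lv = np.clip(0.5 * (lv + lv_prop), _LOGVAR_MIN, _LOGVAR_MAX)
                # weight noise is a relative perturbation of the synaptic
                # weights; cap it at a physically plausible level
                lv[:2] = np.minimum(lv[:2], np.log(2.0))
            sp, sm, s0 = np.exp(lv)
        # ---- bookkeeping, early stopping on the validation loss
        params = VARNNParams(p=p, w=ema_w.copy(), b=float(ema_b),
                             sigma_plus_sq=0.0 if fix_weight_noise else float(sp),
                             sigma_minus_sq=0.0 if fix_weight_noise else float(sm),
                             sigma0_sq=float(s0))
        train_loss = _nll_score(params, Xt, Rt, yt, config, not fix_weight_noise)
        val_loss = _nll_score(params, Xv, Rv, yv, config, not fix_weight_noise)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise RuntimeError(f"fit diverged at epoch {epoch} (non-finite loss)")
        history.append((train_loss, val_loss))
        # epochs before the variance warm-up carry the initial noise variances
        # and are not candidate models
        candidate = fix_weight_noise or epoch >= warmup
        if candidate and val_loss <= best_candidate_val:
            best_candidate_val = val_loss
            best = params
        if stopper.update(train_loss, val_loss) and candidate:
            break

    if not fix_weight_noise:
        # final maximum-likelihood refinement of the noise variances at the
        # selected mean parameters (the in-training updates only need to be
        # good enough to weight the mean step)
        rho_sq = (yt - activation(Xt @ best.w + best.b)) ** 2
        Ap = Ap_base @ best.w**2
        Am = Am_base @ best.w**2
        sp, sm, s0 = _fit_noise_variances(rho_sq, Ap, Am, lam2)
        best = VARNNParams(p=p, w=best.w, b=best.b, sigma_plus_sq=float(sp),
                           sigma_minus_sq=float(sm), sigma0_sq=float(s0))
        best_candidate_val = _nll_score(best, Xv, Rv, yv, config, True)
    return best, best_candidate_val, history


def fit_varnn(sessions, config: TrainingConfig | None = None,
              fix_weight_noise: bool = False) -> FitResult:
    """Fit a vARNN (or, with ``fix_weight_noise``, an ARNN) by multi-restart SGD.

    Per epoch: one weighted-least-squares gradient step on (w, b) with the
    trial weights frozen and the weight noise reparameterized, followed by
    Gaussian-likelihood steps on the noise variances.  The returned parameters
    come from the restart with the lowest best-validation loss; the residual
    ratio is evaluated on the validation split (inverse-variance weighted for
    the wMSE objective, uniform otherwise).
    """
    config = config or TrainingConfig()
    design = build_design(sessions, config.p)
    if design.n <= 10 * config.p:
        raise ValueError(
            f"too few usable trials ({design.n}) for order p={config.p}")
    rng = np.random.default_rng(config.seed)
    tr, va = split_data(design, config.split_fraction,
                        seed=int(rng.integers(2**31)))
    var_tr = float(design.y[tr].var())
    lam1 = config.lambda1 if config.lambda1 is not None else 0.01 * var_tr
    lam2 = (config.lambda2 if config.lambda2 is not None else 0.01 * var_tr)
    if fix_weight_noise:
        lam2 = 0.0
    cfg = TrainingConfig(**{**config.__dict__, "lambda1": lam1, "lambda2": lam2})

    best_params, best_val, best_hist = None, np.inf, None
    restart_losses = []
    for k in range(config.n_restarts):
        try:
            params, val, hist = _fit_varnn_once(
                design, tr, va, cfg, rng, fix_weight_noise, lam1, lam2)
        except RuntimeError as err:
            raise RuntimeError(f"restart {k}: {err}") from err
        restart_losses.append(val)
        if val < best_val:
            best_params, best_val, best_hist = params, val, hist

    Xv, Rv, yv = design.rows(va)
    mean_v = activation(Xv @ best_params.w + best_params.b)
    if config.objective == "wmse" and not fix_weight_noise:
        var_v = _varnn_variances(Xv, Rv, best_params.w, best_params.sigma_plus_sq,
                                 best_params.sigma_minus_sq, best_params.sigma0_sq)
        res = residual_ratio(mean_v, yv, var_v)
    else:
        res = residual_ratio(mean_v, yv)
    return FitResult(params=best_params, residual_ratio=res,
                     loss_history=best_hist, restart_losses=restart_losses,
                     seed=config.seed)


def fit_arnn(sessions, config: TrainingConfig | None = None) -> FitResult:
    """ARNN fit: the vARNN procedure with both weight-noise variances pinned
    at zero (uniform trial weights; only w, b and sigma0_sq are learned)."""
    return fit_varnn(sessions, config, fix_weight_noise=True)


def reward_blind_params(params: VARNNParams) -> VARNNParams:
    """Remove the reward effect: both weight-noise variances set to their
    average, preserving the total weight noise (used to generate GRU_3
    training data)."""
    avg = 0.5 * (params.sigma_plus_sq + params.sigma_minus_sq)
    return VARNNParams(p=params.p, w=params.w.copy(), b=params.b,
                       sigma_plus_sq=avg, sigma_minus_sq=avg,
                       sigma0_sq=params.sigma0_sq)


# ---------------------------------------------------------------------------
# GRU fitting


def fit_gru(sessions, config: TrainingConfig | None = None,
            variant: str = "gru1") -> FitResult:
    """Teacher-forced one-step GRU training with L1 gate regularization.

    Sessions are cut into segments of ``segment_length`` input rows with 50%
    overlap (h_0 = 0 at each segment start); each forecast target contributes
    to the loss exactly once (overlapping rows are masked out of the second
    copy).  Plain masked MSE, SGD with momentum, early stopping when the
    validation loss exceeds the training loss ``patience`` epochs in a row.
    """
    variant = variant.lower()
    if variant not in VARIANTS:
        raise ValueError(f"unknown GRU variant {variant!r}")
    config = config or TrainingConfig()
    if isinstance(sessions, Session):
        sessions = [sessions]
    d = 1 if variant == "gru2" else 2
    L = config.segment_length
    hop = max(1, L // 2)
    rng = np.random.default_rng(config.seed)

    # --- assemble segments and a global target index for splitting;
    #     each target row is loss-active in exactly one (the first) segment
    seg_X, seg_y, seg_fresh = [], [], []
    target_session = []
    base = 0
    for si, s in enumerate(sessions):
        e, r = s.e, s.r
        n_rows = len(s) - 1          # row t forecasts e[t+1]
        if n_rows < 1:
            continue
        Xs = variant_inputs(e[:-1], r[:-1], variant)
        ys = e[1:]
        starts = list(range(0, max(n_rows - L, 0) + 1, hop))
        if starts[-1] + L < n_rows:
            starts.append(max(n_rows - L, 0))
        covered = 0
        for s0 in starts:
            s1 = min(s0 + L, n_rows)
            Xseg = np.zeros((L, d))
            yseg = np.zeros(L)
            fresh = np.full(L, -1, dtype=np.int64)   # global target index or -1
            Xseg[: s1 - s0] = Xs[s0:s1]
            yseg[: s1 - s0] = ys[s0:s1]
            lo = max(s0, covered)
            fresh[lo - s0 : s1 - s0] = base + np.arange(lo, s1)
            covered = max(covered, s1)
            seg_X.append(Xseg)
            seg_y.append(yseg)
            seg_fresh.append(fresh)
        target_session.extend([si] * n_rows)
        base += n_rows
    if not seg_X:
        raise ValueError("sessions too short to train a GRU")
    X = np.stack(seg_X)               # (B, L, d)
    Y = np.stack(seg_y)               # (B, L)
    FRESH = np.stack(seg_fresh)       # (B, L) global target ids, -1 = inactive

    n_targets = base
    fake = Design(X=np.zeros((n_targets, 1)), R=np.zeros((n_targets, 1)),
                  y=np.zeros(n_targets), session_id=np.asarray(target_session))
    tr_idx, va_idx = split_data(fake, config.split_fraction,
                                seed=int(rng.integers(2**31)))
    is_train = np.zeros(n_targets, dtype=bool)
    is_train[tr_idx] = True
    active = FRESH >= 0
    mask_tr = active & np.where(active, is_train[np.maximum(FRESH, 0)], False)
    mask_va = active & ~mask_tr
    n_tr, n_va = int(mask_tr.sum()), int(mask_va.sum())

    def masked_mse(yhat, mask):
        diff = np.where(mask, yhat - Y, 0.0)
        return float((diff**2).sum() / mask.sum())

    best_overall, best_overall_val, best_hist = None, np.inf, None
    restart_losses = []
    for k in range(config.n_restarts):
        params = GRUParams.init(config.hidden_size, d, rng)
        vel = {f: np.zeros_like(np.asarray(getattr(params, f), dtype=float))
               for f in ("W_r", "W_f", "W_h", "b_r", "b_f", "b_h", "readout_w")}
        vel["readout_b"] = 0.0
        stopper = EarlyStopping(config.patience, config.min_epochs)
        best, history = None, []
        for epoch in range(config.epochs):
            yhat, hs, caches = gru_forward(params, X)
            dy = np.where(mask_tr, 2.0 * (yhat - Y) / n_tr, 0.0)
            grads = gru_backward(params, hs, caches, dy)
            for f in ("W_r", "W_f", "W_h"):
                grads[f] = grads[f] + config.l1 * np.sign(getattr(params, f))
            for f, gval in grads.items():
                vel[f] = config.gru_momentum * vel[f] - config.gru_learning_rate * gval
                setattr(params, f, getattr(params, f) + vel[f])
            train_loss = masked_mse(yhat, mask_tr)
            val_loss = masked_mse(yhat, mask_va)
            if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
                raise RuntimeError(f"GRU fit diverged (restart {k}, epoch {epoch})")
            history.append((train_loss, val_loss))
            if val_loss <= stopper.best_val:
                best = params.copy()
            if stopper.update(train_loss, val_loss):
                break
        restart_losses.append(stopper.best_val)
        if stopper.best_val < best_overall_val:
            best_overall, best_overall_val, best_hist = best, stopper.best_val, history

    yhat, _, _ = gru_forward(best_overall, X)
    res = residual_ratio(yhat[mask_va], Y[mask_va])
    return FitResult(params=best_overall, residual_ratio=res,
                     loss_history=best_hist, restart_losses=restart_losses,
                     seed=config.seed)
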