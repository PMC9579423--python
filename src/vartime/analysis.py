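"""Descriptive statistics of trial-by-trial timing series.

Two behavioral signatures drive the modeling:

* long-range serial dependence — quantified by the partial autocorrelation
  function (PACF) with a trial-shuffle confidence band; for an AR(p) process
  the PACF is nonzero through lag p and cuts off beyond it;
* reward-gated variability — the variance of the next error conditioned on the
  previous trial's error and feedback: negative feedback is followed by larger
  variability than positive feedback at matched previous error.

Plus the normalized residual ratio used to compare forecasting models: the
(optionally inverse-variance-weighted) unexplained variance divided by the
total variance of the observations, a weighted analog of 1 - R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

from .task_sim import Session

__all__ = [
    "ParCorrProfile",
    "ConditionedStats",
    "partial_autocorrelation",
    "pacf_ols",
    "pacf_durbin_levinson",
    "conditioned_stats",
    "reward_gated_variance_test",
    "residual_ratio",
    "running_mean",
    "significant_run_length",
    "infer_order",
]


# ---------------------------------------------------------------------------
# partial autocorrelation


def pacf_ols(series: np.ndarray, max_lag: int) -> np.ndarray:
    """PACF by lagged-regressor least squares.

    For each lag k the series is regressed (with intercept) on its first k
    lags over trials t = k .. n-1; the coefficient of lag k is the partial
    autocorrelation at lag k.  All k regressions are solved from one Gram
    matrix accumulated over the common sample, with exact per-lag row
    corrections, so the result is identical to running each regression
    separately.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= 3 * max_lag:
        raise ValueError(
            f"series of length {n} too short for max_lag={max_lag} (need > {3 * max_lag})"
        )
    # design over the common rows t in [max_lag, n): columns [1, x_{t-1}, ..., x_{t-K}]
    K = max_lag
    lagmat = sliding_window_view(x, K + 1)[:, ::-1]   # row t-K: [x_t, x_{t-1}, ..., x_{t-K}]
    y = lagmat[:, 0]
    Z = np.empty((n - K, K + 1))
    Z[:, 0] = 1.0
    Z[:, 1:] = lagmat[:, 1:]
    G = Z.T @ Z
    c = Z.T @ y

    out = np.empty(K)
    for k in range(1, K + 1):
        Gk = G[: k + 1, : k + 1].copy()
        ck = c[: k + 1].copy()
        # restore rows t in [k, K) that the common sample dropped
        for t in range(k, K):
            z = np.empty(k + 1)
            z[0] = 1.0
            z[1:] = x[t - 1 :: -1][:k]
            Gk += np.outer(z, z)
            ck += z * x[t]
        beta = np.linalg.solve(Gk, ck)
        out[k - 1] = beta[-1]
    return out


def pacf_durbin_levinson(series: np.ndarray, max_lag: int) -> np.ndarray:
    """PACF via the Durbin–Levinson recursion on the sample autocorrelation
    (biased, demeaned estimator). Used as an independent cross-check of
    :func:`pacf_ols`; the two agree up to edge effects of order max_lag/n."""
    x = np.asarray(series, dtype=float)
    n = x.size
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 : n + max_lag] / n
    rho = acov / acov[0]
    pacf = np.empty(max_lag)
    phi = np.zeros((max_lag + 1, max_lag + 1))
    for k in range(1, max_lag + 1):
        if k == 1:
            phi[1, 1] = rho[1]
        else:
            num = rho[k] - phi[k - 1, 1:k] @ rho[1:k][::-1]
            den = 1.0 - phi[k - 1, 1:k] @ rho[1:k]
            phi[k, k] = num / den
            phi[k, 1:k] = phi[k - 1, 1:k] - phi[k, k] * phi[k - 1, 1:k][::-1]
        pacf[k - 1] = phi[k, k]
    return pacf


@dataclass
class ParCorrProfile:
    """PACF coefficients for lags 1..max_lag with pooled shuffle quantiles."""

    lags: np.ndarray
    coefficients: np.ndarray
    band_low: float
    band_high: float
    n_shuffles: int

    def significant(self) -> np.ndarray:
        """Boolean mask of lags whose coefficient exceeds the 99% band."""
        return self.coefficients > self.band_high


def partial_autocorrelation(
    series: np.ndarray,
    max_lag: int,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> ParCorrProfile:
    """PACF with a trial-shuffle confidence band.

    The band is the pooled (1%, 99%) quantile pair of the PACF values at lags
    1..max_lag computed over ``n_shuffles`` random permutations of the series,
    which destroy all serial structure while preserving the marginal
    distribution.
    """
    x = np.asarray(series, dtype=float)
    coef = pacf_ols(x, max_lag)
    rng = rng or np.random.default_rng()
    null = np.empty((n_shuffles, max_lag))
    for s in range(n_shuffles):
        null[s] = pacf_ols(rng.permutation(x), max_lag)
    lo, hi = np.quantile(null.ravel(), [0.01, 0.99])
    return ParCorrProfile(
        lags=np.arange(1, max_lag + 1),
        coefficients=coef,
        band_low=float(lo),
        band_high=float(hi),
        n_shuffles=n_shuffles,
    )


def infer_order(sessions, max_lag: int = 20, n_shuffles: int = 200,
                rng: np.random.Generator | None = None) -> int:
    """Choose an autoregressive order from the data's partial autocorrelation:
    the last lag of the consecutive run above the 99% shuffle band (at least 1).

    This mirrors how the order is set in practice — from the partial
    correlation analysis of the series to be fitted.
    """
    from .task_sim import Session

    if isinstance(sessions, Session):
        sessions = [sessions]
    series = np.concatenate([s.e for s in sessions])
    prof = partial_autocorrelation(series, max_lag, n_shuffles=n_shuffles, rng=rng)
    return max(1, significant_run_length(prof))


def significant_run_length(profile: ParCorrProfile) -> int:
    """Last lag of the consecutive run, starting at lag 1, of PACF
    coefficients above the 99% shuffle band (0 when lag 1 is already below)."""
    sig = profile.significant()
    run = 0
    for flag in sig:
        if not flag:
            break
        run += 1
    return run


# ---------------------------------------------------------------------------
# reward-conditioned trial statistics


@dataclass
class ConditionedStats:
    """Statistics of e_n conditioned on the previous trial's error bin and feedback."""

    bin_edges: np.ndarray      # len n_bins + 1, on e_{n-1}
    bin_centers: np.ndarray    # mean e_{n-1} per bin
    counts: np.ndarray
    means: np.ndarray          # E[e_n | bin]
    variances: np.ndarray      # Var[e_n | bin]
    reward_fraction: np.ndarray  # P[r_{n-1} = 1 | bin]
    means_by_r: np.ndarray     # (n_bins, 2): columns r_{n-1} = 0, 1; NaN if empty
    variances_by_r: np.ndarray
    counts_by_r: np.ndarray


def _transitions(sessions) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool (e_{n-1}, r_{n-1}, e_n) transitions; never across session boundaries."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    e_prev, r_prev, e_next = [], [], []
    for s in sessions:
        e_prev.append(s.e[:-1])
        r_prev.append(s.r[:-1])
        e_next.append(s.e[1:])
    return (np.concatenate(e_prev), np.concatenate(r_prev), np.concatenate(e_next))


def conditioned_stats(sessions, n_bins: int = 8, min_count: int = 50) -> ConditionedStats:
    """Per-bin mean/variance of e_n and reward fraction, by e_{n-1} bin.

    Bins are equal-count (quantile) bins of e_{n-1}; bins thinner than
    ``min_count`` transitions are merged with their neighbor.
    """
    e_prev, r_prev, e_next = _transitions(sessions)
    n = e_prev.size
    if n < 2 * min_count:
        raise ValueError("too few transitions for conditioned statistics")
    n_bins = max(1, min(n_bins, n // min_count))
    edges = np.quantile(e_prev, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, e_prev, side="right") - 1, 0, len(edges) - 2)

    # merge undersized bins leftward
    while len(edges) > 2:
        cnt = np.bincount(idx, minlength=len(edges) - 1)
        small = np.nonzero(cnt < min_count)[0]
        if small.size == 0:
            break
        j = small[0]
        edges = np.delete(edges, j if j > 0 else 1)
        idx = np.clip(np.searchsorted(edges, e_prev, side="right") - 1, 0, len(edges) - 2)

    nb = len(edges) - 1
    centers = np.empty(nb)
    counts = np.empty(nb, dtype=int)
    means = np.empty(nb)
    variances = np.empty(nb)
    rfrac = np.empty(nb)
    means_by_r = np.full((nb, 2), np.nan)
    vars_by_r = np.full((nb, 2), np.nan)
    counts_by_r = np.zeros((nb, 2), dtype=int)
    for j in range(nb):
        m = idx == j
        centers[j] = e_prev[m].mean()
        counts[j] = m.sum()
        means[j] = e_next[m].mean()
        variances[j] = e_next[m].var(ddof=1)
        rfrac[j] = r_prev[m].mean()
        for r in (0, 1):
            mr = m & (r_prev == r)
            counts_by_r[j, r] = mr.sum()
            if mr.sum() >= 2:
                means_by_r[j, r] = e_next[mr].mean()
                vars_by_r[j, r] = e_next[mr].var(ddof=1)
    return ConditionedStats(edges, centers, counts, means, variances, rfrac,
                            means_by_r, vars_by_r, counts_by_r)


def reward_gated_variance_test(sessions):
    """One-sided F-test for Var[e_n | r_{n-1}=0] > Var[e_n | r_{n-1}=1],
    controlling for the previous error.

    The mean dependence of e_n on e_{n-1} (and a per-feedback intercept) is
    partialled out by least squares; the residual variances of the two
    feedback groups are then compared with an F ratio.  Under additive output
    noise alone the residual variance is independent of the feedback, so the
    test is calibrated for the ARNN limit; multiplicative feedback-gated
    weight noise inflates the r = 0 group.

    Returns (var_ratio, p_value) with var_ratio = s0^2 / s1^2.
    """
    e_prev, r_prev, e_next = _transitions(sessions)
    Z = np.column_stack([np.ones_like(e_prev), e_prev, r_prev])
    resid = e_next - Z @ np.linalg.lstsq(Z, e_next, rcond=None)[0]
    m0 = r_prev == 0
    n0, n1 = int(m0.sum()), int((~m0).sum())
    if n0 < 3 or n1 < 3:
        raise ValueError("insufficient trials in one of the feedback strata")
    s0 = float(resid[m0] @ resid[m0]) / (n0 - 1)
    s1 = float(resid[~m0] @ resid[~m0]) / (n1 - 1)
    F = s0 / s1
    p = float(sps.f.sf(F, n0 - 1, n1 - 1))
    return F, p


# ---------------------------------------------------------------------------
# model-comparison metric


def residual_ratio(forecasts, observations, variances=None) -> float:
    """Normalized residual Res: weighted unexplained variance over total variance.

    ``forecasts`` may be a sequence of :class:`~vartime.varnn.Prediction`
    (their variances supply the weights) or an array of means with an optional
    ``variances`` array.  Weights are g_n = 1 / sigma_n^2, self-normalized;
    with uniform weights Res equals 1 - R^2.  Res = 1 means structureless,
    Res = 0 fully predictable.
    """
    obs = np.asarray(observations, dtype=float)
    if len(forecasts) and hasattr(forecasts[0], "variance"):
        means = np.array([f.mean for f in forecasts])
        variances = np.array([f.variance for f in forecasts])
    else:
        means = np.asarray(forecasts, dtype=float)
    if means.shape != obs.shape:
        raise ValueError("forecasts and observations must have equal length")
    total = obs.var()
    if total == 0:
        raise ValueError("observations have zero variance; residual ratio undefined")
    if variances is None:
        g = np.ones_like(obs)
    else:
        variances = np.asarray(variances, dtype=float)
        if (variances <= 0).any():
            raise ValueError("predictive variances must be positive for weighting")
        g = 1.0 / variances
    unexplained = float(g @ (means - obs) ** 2 / g.sum())
    return unexplained / total


def running_mean(series: np.ndarray, window: int = 20) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    if window == 1:
        return x.copy()
    n = x.size
    # even windows take one extra point on the left (pandas convention)
    half_lo = window // 2
    half_hi = (window - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
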