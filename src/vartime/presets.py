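"""Reference parameter sets for simulation studies.

The human series these simulations emulate show (a) partial autocorrelation
decaying over roughly 20 trials, (b) overall error SD around 0.1, (c) about
half the trials rewarded, and (d) a fitted weight-noise variance ratio
sigma_plus_sq / sigma_minus_sq with median 0.226 — noise shrinks after
success.  The defaults below reproduce those regimes.
"""

from __future__ import annotations

import numpy as np

from .varnn import VARNNParams

__all__ = [
    "default_varnn_params",
    "default_arnn_params",
    "low_order_varnn_params",
    "low_order_arnn_params",
    "pacf_demo_arnn_params",
    "recovery_grid",
]


def _geometric_weights(p: int, total: float = 0.8, decay: float = 0.85) -> np.ndarray:
    w = decay ** np.arange(p)
    return total * w / w.sum()


def default_varnn_params(p: int = 20) -> VARNNParams:
    """Order-20 geometric-decay weights (sum 0.8) giving a human-like PACF
    profile; variance ratio sigma_plus/sigma_minus = 0.227; sigma0 = 0.06."""
    return VARNNParams(p=p, w=_geometric_weights(p), b=0.0,
                       sigma_plus_sq=0.1, sigma_minus_sq=0.44, sigma0_sq=0.0036)


def default_arnn_params(p: int = 20) -> VARNNParams:
    """The reward-blind limit of :func:`default_varnn_params`."""
    q = default_varnn_params(p)
    q.sigma_plus_sq = q.sigma_minus_sq = 0.0
    return q


def low_order_varnn_params() -> VARNNParams:
    """Order-1 set with a strong lag-1 weight; used where the reward-gated
    variance signature itself is the object of study."""
    return VARNNParams(p=1, w=np.array([0.5]), b=0.0,
                       sigma_plus_sq=0.1, sigma_minus_sq=0.44, sigma0_sq=0.01)


def low_order_arnn_params() -> VARNNParams:
    q = low_order_varnn_params()
    q.sigma_plus_sq = q.sigma_minus_sq = 0.0
    return q


def pacf_demo_arnn_params() -> VARNNParams:
    """Order-20 ARNN with uniform weights 0.04 and sigma0 = 0.1: the series
    whose PACF stays above the shuffle band through exactly lag 20."""
    return VARNNParams(p=20, w=np.full(20, 0.04), b=0.0, sigma0_sq=0.01)


def recovery_grid() -> list[VARNNParams]:
    """Ground-truth grid for the parameter-recovery study: orders 1/3/5,
    weights within [0.05, 0.6], variance ratios sigma_minus/sigma_plus of
    1, 2 and 4 around sigma_plus_sq = 0.1."""
    weight_sets = {1: [0.5], 3: [0.4, 0.2, 0.1], 5: [0.3, 0.2, 0.15, 0.1, 0.05]}
    grid = []
    for p, w in weight_sets.items():
        for ratio in (1.0, 2.0, 4.0):
            grid.append(VARNNParams(p=p, w=np.array(w), b=0.0,
                                    sigma_plus_sq=0.1, sigma_minus_sq=0.1 * ratio,
                                    sigma0_sq=0.01))
    return grid
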