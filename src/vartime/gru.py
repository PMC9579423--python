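"""Gated-recurrent-unit baseline for one-step error forecasting.

The GRU consumes the previous trial's outcome — the error alone (variant
``GRU_2``) or the error and the binary feedback (``GRU_1``/``GRU_3``) — and
maintains a hidden state updated through reset/forget gates:

    r_n  = sigmoid(W_r [X_n; h_{n-1}] + b_r)
    f_n  = sigmoid(W_f [X_n; h_{n-1}] + b_f)
    h~_n = tanh(W_h [X_n; r_n ⊙ h_{n-1}] + b_h)
    h_n  = (1 - f_n) ⊙ h_{n-1} + f_n ⊙ h~_n

A linear readout of the hidden state gives the forecast.  ``GRU_3`` shares
GRU_1's architecture; it differs only in the training data (a simulation with
the reward effect on the weight noise removed).  Forward and backward passes
are implemented directly in numpy; the backward pass is verified against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GRUParams", "gru_step", "gru_forecast", "gru_forward", "gru_backward",
           "variant_inputs", "GRUSampler", "VARIANTS"]

VARIANTS = ("gru1", "gru2", "gru3")

_WEIGHT_FIELDS = ("W_r", "W_f", "W_h", "b_r", "b_f", "b_h", "readout_w", "readout_b")


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class GRUParams:
    """GRU weights. Gate matrices have shape (hidden, input_dim + hidden)."""

    hidden_size: int
    input_dim: int
    W_r: np.ndarray
    W_f: np.ndarray
    W_h: np.ndarray
    b_r: np.ndarray
    b_f: np.ndarray
    b_h: np.ndarray
    readout_w: np.ndarray
    readout_b: float

    def __post_init__(self):
        H, d = self.hidden_size, self.input_dim
        for name in ("W_r", "W_f", "W_h"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (H, d + H):
                raise ValueError(f"{name} must have shape ({H}, {d + H}), got {m.shape}")
            setattr(self, name, m)
        for name in ("b_r", "b_f", "b_h"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (H,):
                raise ValueError(f"{name} must have shape ({H},)")
            setattr(self, name, v)
        self.readout_w = np.asarray(self.readout_w, dtype=float)
        if self.readout_w.shape != (H,):
            raise ValueError("readout_w must have shape (hidden,)")
        self.readout_b = float(self.readout_b)

    @classmethod
    def init(cls, hidden_size: int = 32, input_dim: int = 2,
             rng: np.random.Generator | None = None) -> "GRUParams":
        """Uniform(-k, k) gate weights with k = 1/sqrt(input_dim + hidden);
        biases start at zero."""
        rng = rng or np.random.default_rng()
        H, d = hidden_size, input_dim
        k = 1.0 / np.sqrt(d + H)
        mk = lambda: rng.uniform(-k, k, size=(H, d + H))
        return cls(hidden_size=H, input_dim=d, W_r=mk(), W_f=mk(), W_h=mk(),
                   b_r=np.zeros(H), b_f=np.zeros(H), b_h=np.zeros(H),
                   readout_w=rng.uniform(-k, k, size=H), readout_b=0.0)

    def copy(self) -> "GRUParams":
        return GRUParams(self.hidden_size, self.input_dim,
                         *(np.array(getattr(self, f), copy=True) if f != "readout_b"
                           else self.readout_b for f in _WEIGHT_FIELDS))

    def to_dict(self) -> dict:
        d = {"hidden_size": self.hidden_size, "input_dim": self.input_dim}
        for f in _WEIGHT_FIELDS:
            v = getattr(self, f)
            d[f] = v.tolist() if isinstance(v, np.ndarray) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GRUParams":
        kw = {f: np.asarray(d[f]) if f.startswith(("W", "b_", "readout_w")) else d[f]
              for f in _WEIGHT_FIELDS}
        return cls(hidden_size=int(d["hidden_size"]), input_dim=int(d["input_dim"]), **kw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GRUParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def gru_step(params: GRUParams, x_n: np.ndarray, h_prev: np.ndarray):
    """One GRU update. ``x_n`` (..., input_dim), ``h_prev`` (..., hidden).

    Returns (h_n, cache) where cache holds the intermediates for backprop.
    """
    x_n = np.atleast_2d(np.asarray(x_n, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    if x_n.shape[-1] != params.input_dim:
        raise ValueError(f"input dim {x_n.shape[-1]} != {params.input_dim}")
    if h_prev.shape[-1] != params.hidden_size:
        raise ValueError("hidden state dimension mismatch")
    cat = np.concatenate([x_n, h_prev], axis=-1)
    r = _sigmoid(cat @ params.W_r.T + params.b_r)
    f = _sigmoid(cat @ params.W_f.T + params.b_f)
    cat_h = np.concatenate([x_n, r * h_prev], axis=-1)
    h_tilde = np.tanh(cat_h @ params.W_h.T + params.b_h)
    h = (1.0 - f) * h_prev + f * h_tilde
    return h, (x_n, h_prev, r, f, h_tilde)


def gru_forward(params: GRUParams, X: np.ndarray):
    """Roll the GRU over batched sequences and read out every step.

    ``X``: (batch, T, input_dim).  Returns (forecasts (batch, T),
    hidden (batch, T, H), caches list) with h_0 = 0.
    """
    B, T, d = X.shape
    H = params.hidden_size
    h = np.zeros((B, H))
    hs = np.empty((B, T, H))
    caches = []
    for t in range(T):
        h, cache = gru_step(params, X[:, t, :], h)
        hs[:, t, :] = h
        caches.append(cache)
    y = hs @ params.readout_w + params.readout_b
    return y, hs, caches


def gru_backward(params: GRUParams, hs: np.ndarray, caches, dy: np.ndarray):
    """Backpropagation through time.

    ``dy``: (batch, T) gradient of the loss w.r.t. each step's forecast.
    Returns a dict of gradients keyed like the parameter fields.
    """
    B, T, H = hs.shape
    g = {f: np.zeros_like(np.asarray(getattr(params, f), dtype=float))
         for f in _WEIGHT_FIELDS}
    g["readout_b"] = 0.0
    dh_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, r, f, h_tilde = caches[t]
        h_t = hs[:, t, :]
        dh = dh_next + dy[:, t][:, None] * params.readout_w
        g["readout_w"] += dy[:, t] @ h_t
        g["readout_b"] += float(dy[:, t].sum())

        df = dh * (h_tilde - h_prev)
        dh_tilde = dh * f
        dh_prev = dh * (1.0 - f)

        da_h = dh_tilde * (1.0 - h_tilde**2)
        cat_h = np.concatenate([x, r * h_prev], axis=-1)
        g["W_h"] += da_h.T @ cat_h
        g["b_h"] += da_h.sum(axis=0)
        dcat_h = da_h @ params.W_h
        drh = dcat_h[:, params.input_dim:]
        dr = drh * h_prev
        dh_prev += drh * r

        da_f = df * f * (1.0 - f)
        cat = np.concatenate([x, h_prev], axis=-1)
        g["W_f"] += da_f.T @ cat
        g["b_f"] += da_f.sum(axis=0)
        dh_prev += (da_f @ params.W_f)[:, params.input_dim:]

        da_r = dr * r * (1.0 - r)
        g["W_r"] += da_r.T @ cat
        g["b_r"] += da_r.sum(axis=0)
        dh_prev += (da_r @ params.W_r)[:, params.input_dim:]

        dh_next = dh_prev
    return g


def variant_inputs(e: np.ndarray, r: np.ndarray, variant: str) -> np.ndarray:
    """Input rows X_t for each trial t: what the network sees when forecasting
    trial t+1.  gru1/gru3 use [e_t, r_t]; gru2 uses [e_t] only."""
    variant = variant.lower()
    if variant not in VARIANTS:
        raise ValueError(f"unknown GRU variant {variant!r}; expected one of {VARIANTS}")
    e = np.asarray(e, dtype=float)
    if variant == "gru2":
        return e[:, None].copy()
    return np.stack([e, np.asarray(r, dtype=float)], axis=-1)


def gru_forecast(params: GRUParams, session_prefix, variant: str = "gru1") -> float:
    """One-step forecast of the trial following ``session_prefix``.

    Rolls the GRU from h_0 = 0 over the prefix's (e, r) trials and applies the
    linear readout to the final hidden state.  Stateless between calls.
    """
    e = np.asarray(getattr(session_prefix, "e", session_prefix), dtype=float)
    r = getattr(session_prefix, "r", None)
    if r is None:
        raise ValueError("session_prefix must provide e and r")
    if e.size < 1:
        raise ValueError("prefix must contain at least one trial")
    X = variant_inputs(e, np.asarray(r), variant)[None, :, :]
    if X.shape[-1] != params.input_dim:
        raise ValueError(
            f"variant {variant} needs input_dim={X.shape[-1]}, params have {params.input_dim}")
    y, _, _ = gru_forward(params, X)
    return float(y[0, -1])


class GRUSampler:
    """Closed-loop generative handle: GRU forecast plus additive Gaussian noise."""

    def __init__(self, params: GRUParams, sigma0_sq: float, variant: str = "gru1"):
        if variant.lower() not in VARIANTS:
            raise ValueError(f"unknown GRU variant {variant!r}")
        self.params = params
        self.sigma0_sq = float(sigma0_sq)
        self.variant = variant.lower()
        self.reset()

    def reset(self) -> None:
        self._h = np.zeros((1, self.params.hidden_size))
        self._pending = None

    def step(self, r_prev: int | None, rng: np.random.Generator) -> float:
        e_prev = 0.0 if self._pending is None else self._pending
        r_in = 0.0 if r_prev is None else float(r_prev)
        x = variant_inputs(np.array([e_prev]), np.array([r_in]), self.variant)
        self._h, _ = gru_step(self.params, x, self._h)
        mean = float(self._h[0] @ self.params.readout_w + self.params.readout_b)
        e_n = mean + (rng.normal(0.0, np.sqrt(self.sigma0_sq)) if self.sigma0_sq > 0 else 0.0)
        self._pending = e_n
        return e_n
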