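"""Closed-loop Cue-Set-Go timing-task environment.

On each trial the agent produces a duration ``t_p`` that is compared against a
hidden target ``t_t`` (drawn once per session from Normal(800 ms, 80 ms)); the
relative error is ``e = (t_p - t_t) / t_t`` and binary feedback ``r`` is given
when ``|e|`` falls inside a symmetric acceptance window.  The window is
calibrated to the agent's own performance — a running median of recent ``|e|``
— so that roughly half of all trials are rewarded, mirroring the human task.

The simulator doubles as the synthetic-data generator for the whole package:
any generative model exposing ``reset()`` and ``step(r_prev, rng)`` can be run
in the loop, the emitted error defines ``t_p = t_t * (1 + e)``, and the
resulting feedback is fed back into the model on the next trial.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Trial",
    "Session",
    "AcceptanceWindow",
    "sample_target",
    "relative_error",
    "give_feedback",
    "update_window",
    "simulate_session",
    "simulate_sessions",
]

#: window half-width used during warm-up, before enough trials exist to calibrate
WARMUP_HALF_WIDTH = 0.1
#: number of initial trials run at the warm-up width before calibration starts
WARMUP_TRIALS = 50


@dataclass(frozen=True)
class Trial:
    """One behavioral trial. ``t_p``/``t_t`` may be NaN when a session was
    loaded from a file that recorded only (e, r)."""

    index: int  # 1-based
    t_p: float  # produced duration, ms
    t_t: float  # target duration, ms
    e: float    # relative error, dimensionless
    r: int      # binary feedback

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("trial index is 1-based")
        if self.r not in (0, 1):
            raise ValueError(f"reward must be 0 or 1, got {self.r}")
        if self.e <= -1.0:
            raise ValueError(f"relative error must exceed -1, got {self.e}")
        if np.isfinite(self.t_t) and np.isfinite(self.t_p):
            if self.t_t <= 0 or self.t_p <= 0:
                raise ValueError("durations must be positive")
            if abs(self.e - (self.t_p - self.t_t) / self.t_t) > 1e-9 * max(1.0, abs(self.e)):
                raise ValueError("e inconsistent with (t_p - t_t)/t_t")


@dataclass
class Session:
    """One behavioral run: aligned per-trial arrays (t_p, t_t, e, r)."""

    t_p: np.ndarray
    t_t: np.ndarray
    e: np.ndarray
    r: np.ndarray
    target_mean: float = 800.0
    target_sd: float = 80.0
    seed: int | None = None

    def __post_init__(self):
        self.t_p = np.asarray(self.t_p, dtype=float)
        self.t_t = np.asarray(self.t_t, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        self.r = np.asarray(self.r, dtype=int)
        n = self.e.size
        if n < 1:
            raise ValueError("a session must contain at least one trial")
        if not (self.t_p.size == self.t_t.size == self.r.size == n):
            raise ValueError("per-trial arrays must have equal length")
        if not np.isin(self.r, (0, 1)).all():
            raise ValueError("rewards must be binary")
        if (self.e <= -1.0).any():
            raise ValueError("relative errors must exceed -1")

    def __len__(self) -> int:
        return self.e.size

    @property
    def trials(self) -> Iterator[Trial]:
        for i in range(len(self)):
            yield Trial(i + 1, float(self.t_p[i]), float(self.t_t[i]),
                        float(self.e[i]), int(self.r[i]))

    @classmethod
    def from_errors(cls, e: np.ndarray, r: np.ndarray, t_t: float | np.ndarray = np.nan,
                    **kw) -> "Session":
        e = np.asarray(e, dtype=float)
        t_t_arr = np.broadcast_to(np.asarray(t_t, dtype=float), e.shape).copy()
        t_p = t_t_arr * (1.0 + e)
        return cls(t_p=t_p, t_t=t_t_arr, e=e, r=np.asarray(r), **kw)


@dataclass
class AcceptanceWindow:
    """Symmetric threshold on |e|; calibrated from the recent |e| history."""

    half_width: float = WARMUP_HALF_WIDTH
    calibration_span: int = 100

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.calibration_span < 1:
            raise ValueError("calibration_span must be >= 1")


def sample_target(target_mean: float, target_sd: float,
                  rng: np.random.Generator) -> float:
    """Draw a target duration from Normal(target_mean, target_sd), redrawing
    any non-positive values."""
    if target_mean <= 0:
        raise ValueError(f"target_mean must be positive, got {target_mean}")
    if target_sd < 0:
        raise ValueError(f"target_sd must be non-negative, got {target_sd}")
    if target_sd == 0:
        return float(target_mean)
    t = rng.normal(target_mean, target_sd)
    while t <= 0:
        t = rng.normal(target_mean, target_sd)
    return float(t)


def relative_error(t_p: float, t_t: float) -> float:
    """e = (t_p - t_t) / t_t."""
    if t_t <= 0:
        raise ValueError(f"target duration must be positive, got {t_t}")
    return (t_p - t_t) / t_t


def give_feedback(e: float, window: AcceptanceWindow) -> int:
    """r = 1 iff |e| <= half_width (boundary rewarded), else 0."""
    return int(abs(e) <= window.half_width)


def update_window(window: AcceptanceWindow,
                  recent_abs_errors: Sequence[float]) -> AcceptanceWindow:
    """Recalibrate the window to the median |e| over the calibration span.

    The median threshold has reward rate one-half as its fixed point.  An
    empty history leaves the window unchanged.
    """
    recent = np.asarray(list(recent_abs_errors), dtype=float)
    if recent.size == 0:
        return window
    recent = recent[-window.calibration_span:]
    med = float(np.median(recent))
    if med <= 0:  # degenerate (all-zero) history: keep the previous width
        return window
    return AcceptanceWindow(half_width=med, calibration_span=window.calibration_span)


def simulate_session(
    model,
    n_trials: int,
    target_mean: float = 800.0,
    target_sd: float = 80.0,
    seed: int | None = None,
    window: AcceptanceWindow | None = None,
    rng: np.random.Generator | None = None,
) -> Session:
    """Run a generative model in the closed task loop for ``n_trials`` trials.

    The target is sampled once per session.  The acceptance window stays at
    the warm-up width for the first ``WARMUP_TRIALS`` trials, then tracks the
    running median of |e| over the previous ``calibration_span`` trials.
    Fully reproducible from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    window = window or AcceptanceWindow()
    t_t = sample_target(target_mean, target_sd, rng)

    model.reset()
    span = window.calibration_span
    abs_hist: deque[float] = deque(maxlen=span)
    e_arr = np.empty(n_trials)
    r_arr = np.empty(n_trials, dtype=int)
    r_prev: int | None = None
    for n in range(n_trials):
        e_n = model.step(r_prev, rng)
        if not np.isfinite(e_n):
            raise RuntimeError(f"model emitted a non-finite error at trial {n + 1}")
        r_n = give_feedback(e_n, window)
        e_arr[n] = e_n
        r_arr[n] = r_n
        abs_hist.append(abs(e_n))
        if n + 1 >= WARMUP_TRIALS:
            window = update_window(window, abs_hist)
        r_prev = r_n

    t_t_arr = np.full(n_trials, t_t)
    return Session(t_p=t_t_arr * (1.0 + e_arr), t_t=t_t_arr, e=e_arr, r=r_arr,
                   target_mean=target_mean, target_sd=target_sd, seed=seed)


def simulate_sessions(model, n_sessions: int, n_trials: int, seed: int,
                      target_mean: float = 800.0, target_sd: float = 80.0,
                      **kw) -> list[Session]:
    """Simulate ``n_sessions`` independent sessions, seeds fanned out from one
    master seed via SeedSequence spawning."""
    children = np.random.SeedSequence(seed).spawn(n_sessions)
    out = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        s = simulate_session(model, n_trials, target_mean=target_mean,
                             target_sd=target_sd, rng=rng, **kw)
        s.seed = seed
        out.append(s)
    return out
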