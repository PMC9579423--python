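"""Session file round-tripping, parameter files, and the reproduction pipeline.

Session dialect: delimited text (tab by default, comma accepted) with header
``trial  t_p_ms  t_t_ms  e  r`` and one row per trial.  The reader tolerates
missing produced/target durations as long as the error and reward columns are
present, since behavioral archives often record only (e, r).
"""

from __future__ import annotations

import glob as _glob
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import presets
from .analysis import (partial_autocorrelation, reward_gated_variance_test,
                       significant_run_length)
from .gru import GRUParams
from .task_sim import Session, simulate_sessions
from .training import FitResult, TrainingConfig, fit_arnn, fit_gru, fit_varnn
from .varnn import VARNNParams, VARNNSampler

__all__ = ["write_session", "write_sessions", "read_sessions",
           "load_params", "save_params", "save_fit_result",
           "RunConfig", "run_reproduction"]

log = logging.getLogger("vartime")

_COLUMNS = ["trial", "t_p_ms", "t_t_ms", "e", "r"]


def write_session(session: Session, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame({
        "trial": np.arange(1, len(session) + 1),
        "t_p_ms": session.t_p,
        "t_t_ms": session.t_t,
        "e": session.e,
        "r": session.r,
    })
    df.to_csv(path, sep=sep, index=False)


def write_sessions(sessions, out_dir: str | Path, prefix: str = "session") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, s in enumerate(sessions):
        p = out_dir / f"{prefix}_{k:03d}.tsv"
        write_session(s, p)
        paths.append(p)
    return paths


def _read_one(path: Path) -> Session | None:
    text = path.read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty session file, skipped")
        return None
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("e", "r") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for c in ("t_p_ms", "t_t_ms"):
        if c not in df.columns:
            df[c] = np.nan
    r = df["r"].to_numpy()
    bad = np.nonzero(~np.isin(r, (0, 1)))[0]
    if bad.size:
        raise ValueError(f"{path}, row {bad[0] + 2}: reward must be 0 or 1, got {r[bad[0]]}")
    e = df["e"].to_numpy(dtype=float)
    bad = np.nonzero(~(e > -1.0))[0]
    if bad.size:
        raise ValueError(f"{path}, row {bad[0] + 2}: relative error must exceed -1")
    return Session(t_p=df["t_p_ms"].to_numpy(dtype=float),
                   t_t=df["t_t_ms"].to_numpy(dtype=float),
                   e=e, r=r.astype(int))


def read_sessions(path_glob: str) -> list[Session]:
    """Read all session files matching a glob (or a single path)."""
    paths = sorted(_glob.glob(str(path_glob))) or [str(path_glob)]
    out = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        s = _read_one(p)
        if s is not None:
            out.append(s)
    if not out:
        warnings.warn(f"no usable sessions matched {path_glob!r}")
    return out


# ---------------------------------------------------------------------------
# parameter / config files


def load_params(path: str | Path):
    """Load VARNN or GRU parameters from a flat JSON/YAML file (the key set
    decides which)."""
    path = Path(path)
    d = yaml.safe_load(path.read_text())
    if "hidden_size" in d:
        return GRUParams.from_dict(d)
    return VARNNParams.from_dict(d)


def save_params(params, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d))
    else:
        path.write_text(json.dumps(d, indent=1))


def save_fit_result(fit: FitResult, out_dir: str | Path, name: str) -> None:
    """Persist a fit: params JSON, loss-history CSV, summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_params(fit.params, out / f"{name}_params.json")
    pd.DataFrame(fit.loss_history, columns=["train_loss", "val_loss"]).to_csv(
        out / f"{name}_loss_history.csv", index_label="epoch")
    summary = {
        "model": name,
        "residual_ratio": fit.residual_ratio,
        "restart_losses": list(map(float, fit.restart_losses)),
        "n_epochs": len(fit.loss_history),
        "seed": fit.seed,
    }
    (out / f"{name}_fit.json").write_text(json.dumps(summary, indent=1))


# ---------------------------------------------------------------------------
# end-to-end reproduction pipeline


@dataclass
class RunConfig:
    """Scale and seeding of the simulate -> fit -> analyze -> compare pipeline."""

    n_sessions: int = 10
    n_trials: int = 1000
    seed: int = 0
    p_fit: int = 20
    n_restarts: int = 3
    epochs: int = 400
    gru_epochs: int = 250
    max_lag: int = 40
    n_shuffles: int = 200
    n_null: int = 1000
    models: tuple = ("varnn", "arnn", "gru1")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["models"] = list(self.models)
        return d

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def run_reproduction(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate vARNN sessions, fit all requested models, run the behavioral
    analyses, and return (and optionally write) a JSON-serializable report.

    All stages draw their seeds from the master seed via SeedSequence
    spawning, so the report is byte-identical across runs with the same
    config.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]
    truth = presets.low_order_varnn_params()
    sessions = simulate_sessions(VARNNSampler(truth), config.n_sessions,
                                 config.n_trials, seed=seeds[0])
    pooled_e = np.concatenate([s.e for s in sessions])

    log.info("analyzing %d sessions (%d trials)", len(sessions), pooled_e.size)
    pacf = partial_autocorrelation(sessions[0].e, config.max_lag,
                                   n_shuffles=config.n_shuffles,
                                   rng=np.random.default_rng(seeds[1]))
    F, p_var = reward_gated_variance_test(sessions)

    residuals: dict[str, list[float]] = {}
    fits = {}
    for model in config.models:
        res_list = []
        for k, s in enumerate(sessions):
            cfg = TrainingConfig(p=config.p_fit, n_restarts=config.n_restarts,
                                 epochs=config.epochs, seed=seeds[2] + k)
            if model == "varnn":
                fit = fit_varnn(s, cfg)
            elif model == "arnn":
                fit = fit_arnn(s, cfg)
            elif model.startswith("gru"):
                cfg.epochs = config.gru_epochs
                fit = fit_gru(s, cfg, variant=model)
            else:
                raise ValueError(f"unknown model {model!r}")
            res_list.append(fit.residual_ratio)
            fits[f"{model}_session{k}"] = fit
        residuals[model] = res_list
        log.info("model %s: median residual ratio %.3f", model, np.median(res_list))

    report = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "true_params": truth.to_dict(),
        "reward_fraction": float(np.mean([s.r.mean() for s in sessions])),
        "pacf_significant_run": significant_run_length(pacf),
        "reward_variance_F": float(F),
        "reward_variance_p": float(p_var),
        "residual_ratios": residuals,
        "residual_medians": {m: float(np.median(v)) for m, v in residuals.items()},
    }
    if "varnn" in residuals:
        others = [m for m in residuals if m != "varnn"]
        report["varnn_wins"] = {
            m: int(np.sum(np.asarray(residuals["varnn"]) < np.asarray(residuals[m])))
            for m in others}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, fit in fits.items():
            save_fit_result(fit, out / "fits", name)
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
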