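"""Experiment orchestration: seeded multi-run experiments, parameter sweeps
with lowest-MSRE selection, trial-aligned prediction profiles, and log/summary
serialization.

Seed policy: run ``i`` of an experiment uses ``seed_base + i``, from which
independent sub-streams are derived for the environment and the learner
initialization, so runs are independent and every number in a summary is
recomputable from the config alone.
"""

from __future__ import annotations

import itertools
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .environments import (
    TraceConditioningConfig, NoisyPatterningConfig, TracePatterningConfig,
    make_env, NOISY_PATTERNING_PRESETS,
)
from .returns import ReturnSpec, compute_returns, msre, aggregate_runs, RunSummary
from .representations import make_representation, trace_decay_from_expected_isi
from .linear_td import TDHyper, run_linear_agent
from .recurrent import RecurrentConfig, run_recurrent_agent

__all__ = [
    "RunConfig", "ProfileSlice", "config_digest", "build_env",
    "run", "run_single", "sweep", "extract_profile",
    "write_log_csv", "read_log_csv", "load_config",
]

_ENV_KINDS = {
    "trace_conditioning": TraceConditioningConfig,
    "noisy_patterning": NoisyPatterningConfig,
    "trace_patterning": TracePatterningConfig,
}

_LINEAR_REPS = ("presence", "tile_coded_traces", "microstimulus", "esn")


@dataclass
class RunConfig:
    """Fully serializable experiment description.

    ``env`` holds the environment kind and its parameters; ``agent`` the
    learner kind (linear representation or recurrent architecture) and its
    hyperparameters.  Unspecified values fall back to the dataclass defaults
    of the underlying configs.
    """

    env: dict
    agent: dict
    n_steps: int = 200_000
    n_runs: int = 5
    seed_base: int = 0

    def to_dict(self) -> dict:
        return {"env": dict(self.env), "agent": dict(self.agent),
                "n_steps": self.n_steps, "n_runs": self.n_runs,
                "seed_base": self.seed_base}


def config_digest(obj) -> str:
    """Stable short digest of a config-like mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def build_env(env_dict: dict, seed: int | None = None):
    """Instantiate an environment from a flat config mapping.

    ``kind`` selects the benchmark; ``preset`` (noisy patterning only) expands
    a named difficulty preset before explicit keys are applied.
    """
    spec = dict(env_dict)
    kind = spec.pop("kind")
    preset = spec.pop("preset", None)
    if kind not in _ENV_KINDS:
        raise ValueError(f"unknown environment kind {kind!r}; "
                         f"expected one of {sorted(_ENV_KINDS)}")
    if preset is not None:
        if kind != "noisy_patterning":
            raise ValueError("presets are defined for noisy_patterning only")
        spec = {**NOISY_PATTERNING_PRESETS[preset], **spec}
    for key in ("isi_range", "iti_range", "distractor_mean_intervals"):
        if key in spec and spec[key] is not None:
            spec[key] = tuple(spec[key])
    if seed is not None:
        spec["seed"] = int(seed)
    return make_env(_ENV_KINDS[kind](**spec))


def _run_seeds(seed: int) -> tuple[int, np.random.Generator]:
    """Derive the env seed and the init generator for one run."""
    env_ss, init_ss = np.random.SeedSequence(seed).spawn(2)
    env_seed = int(env_ss.generate_state(1)[0] % (2 ** 31))
    return env_seed, np.random.default_rng(init_ss)


def run_single(config: RunConfig, run_index: int) -> tuple[dict, float, float]:
    """Execute one seeded run; returns (log, msre, gamma)."""
    seed = config.seed_base + run_index
    env_seed, init_rng = _run_seeds(seed)
    env = build_env(config.env, seed=env_seed)
    agent = dict(config.agent)
    kind = agent.pop("kind")
    gamma = float(agent.pop("gamma", env.gamma))
    tail_tolerance = float(agent.pop("tail_tolerance", 1e-8))

    if kind == "linear":
        rep_kind = agent.pop("representation")
        if rep_kind not in _LINEAR_REPS:
            raise ValueError(f"unknown representation {rep_kind!r}")
        hyper = TDHyper(
            alpha=float(agent.pop("alpha", TDHyper.alpha)),
            lam=float(agent.pop("lam", TDHyper.lam)),
            gamma=gamma,
            optimizer=agent.pop("optimizer", "adam"),
        )
        tau = agent.pop("tau", None)
        if tau is None and rep_kind in ("tile_coded_traces", "microstimulus"):
            tau = trace_decay_from_expected_isi(env.expected_isi)
        rep_seed = int(init_rng.integers(2 ** 31))
        rep = make_representation(rep_kind, env.layout.d, tau=tau,
                                  seed=rep_seed, **agent)
        log = run_linear_agent(env, rep, hyper, config.n_steps)
    elif kind == "recurrent":
        augment = bool(agent.pop("augment", False))
        taus = agent.pop("augment_taus", None)
        if augment and taus is None:
            taus = (trace_decay_from_expected_isi(env.expected_isi),)
        rc = RecurrentConfig(gamma=gamma, augment=augment,
                             augment_taus=tuple(taus or ()), **agent)
        log = run_recurrent_agent(env, rc, config.n_steps, init_seed=init_rng)
    else:
        raise ValueError(f"unknown agent kind {kind!r}")

    rs = compute_returns(log["us"], ReturnSpec(gamma, tail_tolerance))
    log["return"] = rs.values
    log["valid"] = rs.valid_mask
    value = msre(log["prediction"], rs.values, rs.valid_mask)
    return log, value, gamma


def run(config: RunConfig, outdir: str | Path | None = None,
        overwrite: bool = False, write_logs: bool = False) -> RunSummary:
    """Execute ``n_runs`` independent seeded runs and aggregate MSRE.

    With ``outdir`` set, writes ``summary.json`` (embedding the resolved
    config, its digest, and the seed base) and optionally per-run log CSVs;
    refuses to overwrite an existing summary unless ``overwrite`` is given.
    """
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if (out / "summary.json").exists() and not overwrite:
            raise FileExistsError(
                f"{out / 'summary.json'} exists; pass overwrite=True to replace")
    values = []
    for i in range(config.n_runs):
        log, value, _ = run_single(config, i)
        values.append(value)
        if out is not None and write_logs:
            write_log_csv(log, out / f"run{i:03d}.csv")
    digest = config_digest(config.to_dict())
    summary = aggregate_runs(values, n_steps=config.n_steps,
                             config_digest=digest, seed=config.seed_base)
    if out is not None:
        payload = {
            "msre": summary.msre, "stderr": summary.stderr,
            "n_runs": summary.n_runs, "n_steps": summary.n_steps,
            "per_run_msre": values, "config": config.to_dict(),
            "config_digest": digest, "seed_base": config.seed_base,
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=2))
    return summary


def sweep(config: RunConfig, grid: dict[str, list]) -> tuple[RunConfig, pd.DataFrame]:
    """Cartesian-product hyperparameter sweep, selecting the lowest mean MSRE.

    Grid keys address agent parameters by name, or environment parameters
    with an ``env.`` prefix.  Ties break toward the smallest hyperparameter
    values (combinations are enumerated in ascending order and a later
    combination must be strictly better to displace the incumbent).
    """
    names = sorted(grid)
    rows = []
    best = None
    for combo in itertools.product(*(sorted(grid[k]) for k in names)):
        cfg = RunConfig(env=dict(config.env), agent=dict(config.agent),
                        n_steps=config.n_steps, n_runs=config.n_runs,
                        seed_base=config.seed_base)
        for name, value in zip(names, combo):
            if name.startswith("env."):
                cfg.env[name[4:]] = value
            else:
                cfg.agent[name] = value
        summary = run(cfg)
        rows.append({**dict(zip(names, combo)), "msre": summary.msre,
                     "stderr": summary.stderr})
        if best is None or summary.msre < best[0]:
            best = (summary.msre, cfg)
    return best[1], pd.DataFrame(rows)


@dataclass
class ProfileSlice:
    """Trial-aligned averages; offset 0 is the CS onset."""

    offsets: np.ndarray
    mean_prediction: np.ndarray
    mean_return: np.ndarray
    mean_us: np.ndarray
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets,
            "mean_prediction": self.mean_prediction,
            "mean_return": self.mean_return,
            "mean_us": self.mean_us,
        })


def extract_profile(log: dict, window: tuple[int, int] = (-5, 40),
                    require_pattern_active: bool = False) -> ProfileSlice:
    """Average prediction/return curves aligned at CS onsets.

    Only trials whose whole window lies inside the log (and inside the
    return-validity mask) contribute.  ``require_pattern_active`` keeps only
    trials where an activation pattern occurred (patterning benchmarks).
    """
    trial_id = np.asarray(log["trial_id"])
    onsets = np.flatnonzero(np.diff(trial_id) > 0) + 1
    if trial_id[0] >= 0:
        onsets = np.r_[0, onsets]
    lo, hi = window
    n = trial_id.shape[0]
    valid = np.asarray(log.get("valid", np.ones(n, dtype=bool)))
    keep = []
    for t in onsets:
        if t + lo < 0 or t + hi >= n or not valid[t + hi]:
            continue
        if require_pattern_active and not log["pattern_active"][t]:
            continue
        keep.append(t)
    if not keep:
        raise ValueError("no complete trials inside the requested window")
    offsets = np.arange(lo, hi + 1)
    idx = np.asarray(keep)[:, None] + offsets[None, :]
    return ProfileSlice(
        offsets=offsets,
        mean_prediction=np.asarray(log["prediction"])[idx].mean(axis=0),
        mean_return=np.asarray(log["return"])[idx].mean(axis=0),
        mean_us=np.asarray(log["us"])[idx].mean(axis=0),
        n_trials=len(keep),
    )


_LOG_COLUMNS = ("prediction", "us", "return", "valid", "phase", "trial_id")


def write_log_csv(log: dict, path: str | Path) -> None:
    """Per-step log with the shared schema (one row per step)."""
    n = len(log["prediction"])
    frame = pd.DataFrame({"step": np.arange(n)})
    for col in _LOG_COLUMNS:
        if col in log:
            frame[col] = log[col]
    frame.to_csv(path, index=False)


def read_log_csv(path: str | Path) -> dict:
    frame = pd.read_csv(path)
    return {col: frame[col].to_numpy() for col in frame.columns}
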