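"""Synthetic change-detection task: stimulus generation and the simulated
OU observer.

Trials present a Poisson click train at 60 Hz whose rate steps by a signed
delta (+-10/30/50 Hz) at a change time drawn from a truncated exponential
hazard; a cue beforehand is informative ("increase"/"decrease") or
uninformative ("either").  The observer is the same OU process the
likelihood describes (see :mod:`clickchange.oufp`), simulated forward with
Euler-Maruyama plus a Brownian-bridge crossing test, a Gaussian non-decision
time, and — under the uninformative cue — two processes racing on one click
train with independent noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._kernels import simulate_paths
from .oufp import _depressed_magnitudes
from .params import ModelParams, ObserverParams, ParameterError, TaskConfig

__all__ = [
    "Trial",
    "BehavioralRecord",
    "draw_change_time",
    "generate_trial",
    "simulate_observer",
    "classify_outcome",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "condition_label",
]

OUTCOMES = (
    "hit",
    "miss",
    "false_alarm",
    "wrong_direction",
    "early_excluded",
    "opposite_cue_excluded",
)


@dataclass
class Trial:
    trial_id: int
    cue: str                  # increase | decrease | either
    direction: str            # increase | decrease
    delta: float              # signed Hz
    change_time: float        # s from stimulus onset
    clicks: np.ndarray        # ordered click times, s
    max_time: float           # change_time + response window

    def validate(self, config: TaskConfig) -> "Trial":
        if self.cue not in ("increase", "decrease", "either"):
            raise ValueError(f"bad cue {self.cue!r}")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"bad direction {self.direction!r}")
        if np.sign(self.delta) != (1 if self.direction == "increase" else -1):
            raise ValueError("delta sign must match direction")
        if self.cue != "either" and self.cue != self.direction:
            raise ValueError("informative cue must match direction")
        if not (config.min_prechange <= self.change_time <= config.change_max + 1e-9):
            raise ValueError("change_time outside the allowed interval")
        if self.clicks.size:
            if np.any(np.diff(self.clicks) <= 0):
                raise ValueError("clicks must be strictly increasing")
            if self.clicks[0] < 0 or self.clicks[-1] > self.max_time + 1e-9:
                raise ValueError("clicks outside [0, max_time]")
        return self


@dataclass
class BehavioralRecord:
    trial_id: int
    response_time: Optional[float]    # s from stimulus onset, None = no response
    reported_dir: Optional[str]
    outcome: str


def draw_change_time(config: TaskConfig, rng: np.random.Generator) -> float:
    """Draw a change time with a flat hazard on (min_prechange, change_max).

    The change time is ``min_prechange + E`` with ``E`` exponential (mean
    ``change_mean``), re-drawn until the total does not exceed
    ``change_max`` — an exponential truncated by rejection, which leaves the
    hazard constant on the interior of the interval.
    """
    config.validate()
    limit = config.change_max - config.min_prechange
    if limit <= 0:
        return config.min_prechange
    while True:
        e = rng.exponential(config.change_mean)
        if e <= limit:
            return config.min_prechange + e


def _poisson_train(rate: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def generate_trial(config: TaskConfig, rng: np.random.Generator, trial_id: int = 0) -> Trial:
    """One trial: cue, change, and the piecewise-homogeneous click train."""
    config.validate()
    direction = "increase" if rng.random() < config.p_increase else "decrease"
    cue = direction if rng.random() < config.p_informed else "either"
    mag = float(config.deltas[rng.integers(len(config.deltas))])
    delta = mag if direction == "increase" else -mag
    t_change = draw_change_time(config, rng)
    max_time = t_change + config.response_window
    pre = _poisson_train(config.baseline_rate, 0.0, t_change, rng)
    post = _poisson_train(config.baseline_rate + delta, t_change, max_time, rng)
    clicks = np.concatenate([pre, post])
    return Trial(
        trial_id=trial_id,
        cue=cue,
        direction=direction,
        delta=delta,
        change_time=t_change,
        clicks=clicks,
        max_time=max_time,
    ).validate(config)


def classify_outcome(
    trial: Trial,
    response_time: Optional[float],
    reported_dir: Optional[str],
    config: TaskConfig,
) -> str:
    """Label a behavioral response following the task's analysis rules.

    Precedence: attention-lapse exclusions first (responses within 0.75 s of
    onset; responses opposite an informative cue), then false alarms
    (responses before the change), hits and wrong-direction reports within
    the response window, and misses (no response).
    """
    if response_time is None:
        return "miss"
    if response_time < 0:
        raise ValueError("response_time must be >= 0")
    if response_time < config.early_exclusion:
        return "early_excluded"
    if trial.cue != "either" and reported_dir is not None and reported_dir != trial.cue:
        return "opposite_cue_excluded"
    if response_time <= trial.change_time:
        return "false_alarm"
    if response_time <= trial.change_time + config.response_window + 1e-9:
        if reported_dir == trial.direction:
            return "hit"
        return "wrong_direction"
    return "miss"


def _observer_processes(trial_cue: str, params: ObserverParams) -> list[tuple[str, ModelParams]]:
    if trial_cue == "increase":
        return [("increase", params.informed_increase)]
    if trial_cue == "decrease":
        return [("decrease", params.informed_decrease)]
    return [
        ("increase", params.uninformed_increase),
        ("decrease", params.uninformed_decrease),
    ]


def simulate_observer(
    trial: Trial,
    params: ObserverParams,
    rng: np.random.Generator,
    config: TaskConfig | None = None,
    sim_dt: float = 0.002,
    pre_bound_time: float = 0.8,
) -> BehavioralRecord:
    """Simulate the OU observer on one trial and classify the outcome.

    Bounds are inactive for the first ``pre_bound_time`` seconds.  Under the
    uninformative cue both detection processes run on the same click train
    with independent noise; the first bound crossing determines the reported
    direction, and a single Gaussian non-decision time is added to the
    crossing time.  A response the non-decision time pushes past the end of
    the stimulus is a miss.
    """
    if sim_dt > 0.02:
        raise ParameterError("sim_dt must be <= 0.02 s")
    config = config or TaskConfig()
    procs = _observer_processes(trial.cue, params)
    best_t, best_dir, ndt_ref = np.inf, None, procs[0][1]
    for direction, p in procs:
        p.validate()
        t_c = _simulate_crossing(trial, p, rng, sim_dt, pre_bound_time)
        if t_c is not None and t_c < best_t:
            best_t, best_dir = t_c, direction
    if best_dir is None:
        return BehavioralRecord(trial.trial_id, None, None, "miss")
    rt = best_t + rng.normal(ndt_ref.ndt_mean, ndt_ref.ndt_sd)
    rt = max(rt, 0.0)
    if rt > trial.max_time:
        return BehavioralRecord(trial.trial_id, None, None, "miss")
    outcome = classify_outcome(trial, rt, best_dir, config)
    return BehavioralRecord(trial.trial_id, float(rt), best_dir, outcome)


def binned_drive_substeps(
    clicks: np.ndarray,
    mags: np.ndarray,
    max_time: float,
    sim_dt: float,
    model_dt: float = 0.02,
) -> np.ndarray:
    """Effective clicks per simulation substep, using the model's input
    convention: clicks are counted in ``model_dt`` bins and drive the DV at
    a constant rate within each bin."""
    n_steps = int(np.ceil(max_time / sim_dt - 1e-9))
    n_bins = int(np.ceil(max_time / model_dt - 1e-9))
    counts = np.zeros(max(n_bins, 1))
    if clicks.size:
        idx = np.minimum((clicks / model_dt).astype(np.int64), n_bins - 1)
        np.add.at(counts, idx, mags)
    centers = (np.arange(n_steps) + 0.5) * sim_dt
    bins = np.minimum((centers / model_dt).astype(np.int64), n_bins - 1)
    return counts[bins] * (sim_dt / model_dt)


def _simulate_crossing(
    trial: Trial,
    p: ModelParams,
    rng: np.random.Generator,
    sim_dt: float,
    pre_bound_time: float,
    n_paths: int = 1,
) -> Optional[float]:
    mags = np.ones(trial.clicks.size)
    if p.depression_enabled and trial.clicks.size:
        mags = _depressed_magnitudes(trial.clicks, p.dep_scale, p.dep_tau)
    drive_sub = binned_drive_substeps(trial.clicks, mags, trial.max_time, sim_dt)
    n_steps = drive_sub.shape[0]
    noise = rng.standard_normal((n_paths, n_steps))
    bridge = rng.random((n_paths, n_steps))
    crossed, t_cross, _ = simulate_paths(
        drive_sub,
        n_paths,
        trial.max_time,
        sim_dt,
        p.tau,
        p.sigma_process,
        p.bound_up if p.bound_up is not None else np.inf,
        p.bound_down if p.bound_down is not None else -np.inf,
        pre_bound_time,
        noise,
        bridge,
    )
    return float(t_cross[0]) if crossed[0] else None


def generate_dataset(
    config: TaskConfig,
    params: ObserverParams,
    n_trials: int,
    seed: int,
    sim_dt: float = 0.002,
):
    """Generate ``n_trials`` trials with simulated responses.

    Returns (trials DataFrame, clicks dict keyed by trial_id).  The frame
    has one row per trial with stimulus fields and the behavioral outcome;
    reproducible given ``seed``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    config.validate()
    params.validate()
    rng = np.random.default_rng(seed)
    rows = []
    clicks: dict[int, np.ndarray] = {}
    for i in range(n_trials):
        tr = generate_trial(config, rng, trial_id=i)
        rec = simulate_observer(tr, params, rng, config, sim_dt=sim_dt)
        rows.append(
            {
                "trial_id": i,
                "cue": tr.cue,
                "direction": tr.direction,
                "delta_hz": tr.delta,
                "change_time_s": tr.change_time,
                "max_time_s": tr.max_time,
                "response_time_s": rec.response_time,
                "reported_dir": rec.reported_dir,
                "outcome": rec.outcome,
            }
        )
        clicks[i] = tr.clicks
    return pd.DataFrame(rows), clicks


def condition_label(row) -> str:
    """informed/uninformed x increase/decrease label for one trial row."""
    prefix = "uninformed" if row["cue"] == "either" else "informed"
    return f"{prefix}_{row['direction']}"


# ---------------------------------------------------------------------------
# on-disk format: a delimiter-separated trial table plus a JSON-lines click
# sidecar keyed by trial_id


def write_dataset(trials: pd.DataFrame, clicks: dict, out_dir, metadata: dict | None = None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = trials.copy()
    df["response_time_s"] = df["response_time_s"].map(
        lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.6f}"
    )
    df["reported_dir"] = df["reported_dir"].fillna("")
    for col in ("change_time_s", "max_time_s", "delta_hz"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df.to_csv(out / "trials.tsv", sep="\t", index=False)
    with open(out / "clicks.jsonl", "w") as fh:
        for tid, cl in clicks.items():
            fh.write(
                json.dumps(
                    {"trial_id": int(tid), "clicks": [round(float(c), 6) for c in cl]}
                )
                + "\n"
            )
    if metadata is not None:
        with open(out / "metadata.json", "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_dataset(in_dir):
    path = Path(in_dir)
    if not (path / "trials.tsv").exists():
        raise FileNotFoundError(f"no trial table at {path / 'trials.tsv'}")
    df = pd.read_csv(path / "trials.tsv", sep="\t", dtype={"reported_dir": "string"})
    df["response_time_s"] = pd.to_numeric(df["response_time_s"], errors="coerce")
    df["reported_dir"] = df["reported_dir"].replace({pd.NA: None, "": None})
    df["reported_dir"] = df["reported_dir"].where(df["reported_dir"].notna(), None)
    clicks: dict[int, np.ndarray] = {}
    with open(path / "clicks.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            clicks[int(rec["trial_id"])] = np.asarray(rec["clicks"], dtype=float)
    return df, clicks
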