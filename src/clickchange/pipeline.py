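"""End-to-end orchestration: simulate -> analyze -> reverse-correlate ->
fit -> compare, plus the parameter-recovery harness.

Every output directory carries a metadata file with the configuration
hash, the seeds in play, and solver settings, so any stochastic output can
be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import metrics as met
from . import revcorr as rc
from .fitting import FitSpec, fit_mle, approximate_posterior
from .params import ModelParams, ObserverParams, SolverConfig, TaskConfig
from .task import generate_dataset, write_dataset

logger = logging.getLogger("clickchange")

DEFAULT_CONFIG = {
    "seed": 0,
    "n_trials": 1000,
    "task": {},
    "observer": {},
    "solver": {},
    "fit": {"enabled": False, "conditions": ["informed_increase"]},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = {**DEFAULT_CONFIG, **cfg}
    return merged


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _build_objects(cfg: dict):
    task = TaskConfig.from_dict(cfg.get("task") or {}) if cfg.get("task") else TaskConfig()
    obs_cfg = cfg.get("observer") or {}
    if obs_cfg:
        base = ObserverParams()
        for name, d in obs_cfg.items():
            cur = getattr(base, name).to_dict()
            cur.update(d)
            setattr(base, name, ModelParams(**cur))
        observer = base.validate()
    else:
        observer = ObserverParams()
    solver = SolverConfig(**(cfg.get("solver") or {})).validate()
    return task, observer, solver


def _stage(name, fn, outputs, errors):
    t0 = time.time()
    try:
        result = fn()
        logger.info("stage=%s status=ok wall_s=%.2f", name, time.time() - t0)
        outputs[name] = result
        return result
    except Exception as exc:  # retain partial outputs, record the failure
        logger.exception("stage=%s status=failed", name)
        errors[name] = f"{type(exc).__name__}: {exc}"
        return None


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Run simulate/analyze/revcorr (and optionally fit) into ``out_dir``.

    Deterministic given the config seed.  Returns a summary dict; stage
    failures are recorded there (and in the metadata file) and leave
    earlier outputs in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    task, observer, solver = _build_objects(cfg)
    seed = int(cfg.get("seed", 0))
    meta = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "solver": {"dt": solver.dt, "n_grid": solver.n_grid},
    }
    outputs: dict = {}
    errors: dict = {}

    def simulate():
        trials, clicks = generate_dataset(
            task, observer, int(cfg.get("n_trials", 1000)), seed
        )
        write_dataset(trials, clicks, out, metadata=meta)
        return trials, clicks

    dataset = _stage("simulate", simulate, outputs, errors)

    if dataset is not None:
        trials, clicks = dataset

        n_boot = int((cfg.get("analysis") or {}).get("n_boot", 1000))

        def analyze():
            rows = []
            for cond in met.CONDITIONS:
                try:
                    s = met.fit_threshold(
                        trials, cond, n_boot=n_boot,
                        rng=np.random.default_rng(seed + 10),
                    )
                    for d, r, lo, hi, n in zip(
                        s.deltas, s.hit_rates, s.ci_low, s.ci_high, s.n_per_delta
                    ):
                        rows.append(
                            dict(condition=cond, metric="hit_rate", delta=d,
                                 value=r, ci_low=lo, ci_high=hi, n=n)
                        )
                    rows.append(
                        dict(condition=cond, metric="threshold_hz", delta=np.nan,
                             value=s.threshold, ci_low=s.threshold_ci[0],
                             ci_high=s.threshold_ci[1], n=s.n_per_delta.sum())
                    )
                    m, (lo, hi), n = met.reaction_times(
                        trials, cond, n_boot=n_boot,
                        rng=np.random.default_rng(seed + 11),
                    )
                    rows.append(
                        dict(condition=cond, metric="mean_rt_s", delta=np.nan,
                             value=m, ci_low=lo, ci_high=hi, n=n)
                    )
                except met.EstimatorError as exc:
                    logger.warning("analyze %s: %s", cond, exc)
            for cond, s in met.false_alarm_rates(trials).items():
                rows.append(
                    dict(condition=cond, metric="fa_rate", delta=np.nan,
                         value=s.rate, ci_low=s.ci_low, ci_high=s.ci_high,
                         n=s.denominator)
                )
            frame = pd.DataFrame(rows)
            frame.to_csv(out / "behavior_summary.tsv", sep="\t", index=False)
            return frame

        _stage("analyze", analyze, outputs, errors)

        def revcorr():
            rows = []
            for cond in met.CONDITIONS:
                try:
                    k = rc.kernel_start(rc.fa_kernel((trials, clicks), cond))
                    amp, ci, n, n_short = rc.kernel_amplitude(
                        (trials, clicks), cond, n_boot=n_boot,
                        rng=np.random.default_rng(seed + 12),
                    )
                    pd.DataFrame(
                        {"lag_s": k.t, "mean_rate_hz": k.mean_rate, "sem_hz": k.sem}
                    ).to_csv(out / f"kernel_{cond}.tsv", sep="\t", index=False)
                    rows.append(
                        dict(condition=cond, n_trials=k.n_trials,
                             amplitude_hz=amp, amplitude_ci_low=ci[0],
                             amplitude_ci_high=ci[1],
                             start_s=k.start_time,
                             start_defined=k.start_defined)
                    )
                except rc.RevcorrError as exc:
                    logger.warning("revcorr %s: %s", cond, exc)
            frame = pd.DataFrame(rows)
            frame.to_csv(out / "kernel_summary.tsv", sep="\t", index=False)
            return frame

        _stage("revcorr", revcorr, outputs, errors)

        fit_cfg = cfg.get("fit") or {}
        if fit_cfg.get("enabled"):

            def fit():
                results = {}
                for cond in fit_cfg.get("conditions", ["informed_increase"]):
                    spec = FitSpec(
                        condition=cond,
                        solver=solver,
                        seed=seed,
                        **{
                            k: v
                            for k, v in fit_cfg.items()
                            if k in ("n_screen", "n_polish", "maxfev",
                                     "shared_tau", "hessian_subsample")
                        },
                    )
                    res = approximate_posterior(
                        (trials, clicks), spec, fit_mle((trials, clicks), spec)
                    )
                    res.summary_frame().to_csv(
                        out / f"fit_{cond}.tsv", sep="\t", index=False
                    )
                    results[cond] = res
                return results

            _stage("fit", fit, outputs, errors)

    meta["stage_errors"] = errors
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    if errors:
        raise RuntimeError(f"pipeline stages failed: {sorted(errors)}")
    return outputs


# ---------------------------------------------------------------------------
# parameter recovery


RECOVERY_PARAMS = ("tau", "bound_up", "sigma_process", "ndt_mean", "ndt_sd")


def run_recovery(
    generating_points: Optional[list] = None,
    n_replicates: int = 10,
    trials_per_replicate: int = 1000,
    seed: int = 0,
    condition: str = "informed_increase",
    solver: Optional[SolverConfig] = None,
    fit_kwargs: Optional[dict] = None,
    warm_start: bool = True,
) -> pd.DataFrame:
    """Generate-and-refit exercise: how well are known parameters recovered?

    For each generating point and replicate, a synthetic dataset of
    ``trials_per_replicate`` trials of the requested condition is simulated
    from the OU observer at the generating parameters, the model is re-fit
    blind, and the point estimates, credible intervals, and coverage flags
    are recorded.  Returns one row per (point, replicate, parameter);
    aggregate bias/RMSE are recomputable from the rows.
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    if generating_points is None:
        generating_points = [
            {"tau": 0.4, "bound_up": 78.3, "sigma_process": 4.0,
             "ndt_mean": 0.35, "ndt_sd": 0.06}
        ]
    if not generating_points:
        raise ValueError("empty generating grid")
    solver = solver or SolverConfig(n_grid=201)
    fit_kwargs = {
        "n_screen": 8,
        "maxfev": 60,
        "inner_maxfev": 40,
        "hessian_subsample": 400,
        **(fit_kwargs or {}),
    }
    side = "decrease" if condition == "informed_decrease" else "increase"
    task = TaskConfig(
        p_informed=1.0, p_increase=1.0 if side == "increase" else 0.0
    )
    rows = []
    ss = np.random.SeedSequence(seed)
    for ip, point in enumerate(generating_points):
        gen = ModelParams(
            tau=point["tau"],
            bound_up=point.get("bound_up") if side == "increase" else None,
            bound_down=point.get("bound_down") if side == "decrease" else None,
            sigma_process=point["sigma_process"],
            ndt_mean=point.get("ndt_mean", 0.35),
            ndt_sd=point.get("ndt_sd", 0.06),
        )
        observer = ObserverParams()
        setattr(observer, f"informed_{side}", gen)
        carry = None  # replicate k+1 starts its search at replicate k's fit
        for rep in range(n_replicates):
            child = ss.spawn(1)[0]
            rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            try:
                trials, clicks = generate_dataset(
                    task, observer, trials_per_replicate, rep_seed
                )
                kw = dict(fit_kwargs)
                if warm_start and carry is not None:
                    kw["extra_starts"] = [carry]
                    kw["n_screen"] = 2
                    kw["maxfev"] = min(kw.get("maxfev", 60), 40)
                    kw["n_coord_sweeps"] = 1
                spec = FitSpec(
                    condition=condition, solver=solver, seed=rep_seed, **kw,
                )
                fit = approximate_posterior(
                    (trials, clicks), spec, fit_mle((trials, clicks), spec)
                )
                if warm_start:
                    carry = {
                        n: fit.mle_params[n] for n in spec.slow_names()
                    }
            except Exception as exc:
                logger.exception("recovery point=%d rep=%d failed", ip, rep)
                rows.append(
                    dict(point=ip, replicate=rep, parameter="__failed__",
                         true=np.nan, estimate=np.nan, ci_low=np.nan,
                         ci_high=np.nan, covered=False, error=str(exc))
                )
                continue
            truth = gen.to_dict()
            for name in fit.spec.param_names():
                tv = truth.get(name)
                if tv is None:
                    continue
                est = fit.params[name]
                lo, hi = fit.ci_low[name], fit.ci_high[name]
                rows.append(
                    dict(point=ip, replicate=rep, parameter=name, true=tv,
                         estimate=est, ci_low=lo, ci_high=hi,
                         covered=bool(lo <= tv <= hi), error="")
                )
    return pd.DataFrame(rows)


def recovery_aggregates(report: pd.DataFrame) -> pd.DataFrame:
    """Bias, relative bias, RMSE and coverage per generating point/param."""
    ok = report[report["parameter"] != "__failed__"]
    rows = []
    for (ip, name), g in ok.groupby(["point", "parameter"]):
        err = g["estimate"] - g["true"]
        rows.append(
            dict(point=ip, parameter=name, true=g["true"].iloc[0],
                 n=len(g), bias=err.mean(),
                 rel_bias=err.mean() / g["true"].iloc[0],
                 rmse=np.sqrt((err**2).mean()),
                 coverage=g["covered"].mean())
        )
    return pd.DataFrame(rows)
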