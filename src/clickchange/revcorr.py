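"""Psychophysical reverse correlation of false-alarm trials.

False alarms are responses to stimulus noise, so averaging the smoothed
click rate aligned to the response reveals which stimulus fluctuations
drove the decision ("detection kernels").  The kernel's amplitude (mean
click-rate deviation from the 60 Hz baseline over the final second) indexes
how much evidence a response required, and the kernel's start point indexes
the timescale of evidence evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .params import BASELINE_RATE

__all__ = [
    "instantaneous_rate",
    "fa_kernel",
    "kernel_amplitude",
    "kernel_start",
    "KernelResult",
]

FILTER_SIGMA = 0.075   # s, half-Gaussian smoothing width
KERNEL_SPAN = 1.5      # s of pre-response stimulus
KERNEL_STEP = 0.01     # s, kernel time resolution


class RevcorrError(ValueError):
    """Raised when no qualifying false-alarm trials exist."""


@dataclass
class KernelResult:
    condition: str
    t: np.ndarray               # s relative to response; increasing, ends at 0
    mean_rate: np.ndarray       # Hz
    sem: np.ndarray             # Hz
    n_trials: int
    n_per_point: np.ndarray = None
    amplitude: float = np.nan
    amplitude_ci: tuple = (np.nan, np.nan)
    start_time: float = np.nan
    start_ci: tuple = (np.nan, np.nan)
    start_defined: bool = True
    baseline: float = BASELINE_RATE


def instantaneous_rate(
    clicks: np.ndarray,
    grid: np.ndarray,
    sigma: float = FILTER_SIGMA,
) -> np.ndarray:
    """Smoothed click rate in Hz: clicks convolved with a causal
    half-Gaussian filter of width ``sigma``.

    The filter is supported on times after the click and normalized to unit
    area, so a steady train at rate r reads r Hz once the filter has
    charged.  Superposition holds exactly (the output is linear in the
    click train).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    clicks = np.asarray(clicks, float)
    grid = np.asarray(grid, float)
    if clicks.size == 0:
        return np.zeros(grid.size)
    dtm = grid[:, None] - clicks[None, :]
    scale = np.sqrt(2.0 / np.pi) / sigma
    out = np.where(dtm >= 0.0, np.exp(-0.5 * (dtm / sigma) ** 2), 0.0)
    return scale * out.sum(axis=1)


def _qualifying_fas(trials: pd.DataFrame, condition: str) -> pd.DataFrame:
    """False alarms of one condition group (cue x reported direction).

    Informed groups take cue-consistent false alarms (cue-opposite
    responses were excluded at classification); uninformed groups split by
    the reported direction.
    """
    t = trials.copy()
    fa = t[t["outcome"] == "false_alarm"]
    side = "increase" if condition.endswith("increase") else "decrease"
    if condition.startswith("informed"):
        return fa[fa["cue"] == side]
    return fa[(fa["cue"] == "either") & (fa["reported_dir"] == side)]


def fa_kernel(
    dataset,
    condition: str,
    window: float = KERNEL_SPAN,
    sigma: float = FILTER_SIGMA,
    step: float = KERNEL_STEP,
) -> KernelResult:
    """Response-aligned mean smoothed click rate over false-alarm trials.

    Each qualifying trial's instantaneous rate is evaluated on a grid of
    lags ending at the response; the kernel is the across-trial mean with
    its SEM.  Lags reaching before stimulus onset on a given trial are
    omitted for that trial (short-RT trials contribute only their covered
    lags).
    """
    trials, clicks = dataset
    fa = _qualifying_fas(trials, condition)
    if not len(fa):
        raise RevcorrError(f"no qualifying false alarms for {condition}")
    lags = np.arange(-round(window / step), 1) * step
    acc = np.zeros(lags.size)
    acc2 = np.zeros(lags.size)
    cnt = np.zeros(lags.size, dtype=int)
    for _, row in fa.iterrows():
        rt = float(row["response_time_s"])
        tgrid = rt + lags
        valid = tgrid >= 0.0
        rate = instantaneous_rate(clicks[row["trial_id"]], tgrid[valid], sigma)
        acc[valid] += rate
        acc2[valid] += rate**2
        cnt[valid] += 1
    ok = cnt > 0
    mean = np.full(lags.size, np.nan)
    sem = np.full(lags.size, np.nan)
    mean[ok] = acc[ok] / cnt[ok]
    var = np.zeros(lags.size)
    var[ok] = np.maximum(acc2[ok] / cnt[ok] - mean[ok] ** 2, 0.0)
    sem[ok] = np.sqrt(var[ok] / np.maximum(cnt[ok], 1))
    return KernelResult(
        condition=condition,
        t=lags,
        mean_rate=mean,
        sem=sem,
        n_trials=len(fa),
        n_per_point=cnt,
    )


def kernel_amplitude(
    dataset,
    condition: str,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
):
    """Mean click-rate deviation from baseline in the second before a
    false alarm: (clicks in [response - 1 s, response)) - 60, averaged
    over trials, with a bootstrap 5th/95th CI.

    Trials with less than 1 s of pre-response stimulus are excluded (their
    count is returned for logging).
    """
    rng = rng or np.random.default_rng(0)
    trials, clicks = dataset
    fa = _qualifying_fas(trials, condition)
    if not len(fa):
        raise RevcorrError(f"no qualifying false alarms for {condition}")
    devs = []
    n_short = 0
    for _, row in fa.iterrows():
        rt = float(row["response_time_s"])
        if rt < 1.0:
            n_short += 1
            continue
        cl = clicks[row["trial_id"]]
        k = int(np.sum((cl >= rt - 1.0) & (cl < rt)))
        devs.append(k - BASELINE_RATE)
    if not devs:
        raise RevcorrError("no false alarms with >= 1 s of pre-response stimulus")
    devs = np.asarray(devs, float)
    idx = rng.integers(len(devs), size=(n_boot, len(devs)))
    means = devs[idx].mean(axis=1)
    lo, hi = np.percentile(means, [5, 95])
    return float(devs.mean()), (float(lo), float(hi)), len(devs), n_short


def _piecewise_sse(t, y, t0, t_ext, y_ext, baseline):
    pred = np.where(
        t <= t0,
        baseline,
        baseline + (y_ext - baseline) * (t - t0) / max(t_ext - t0, 1e-12),
    )
    pred = np.where(t > t_ext, y_ext, pred)
    return float(np.nansum((y - pred) ** 2))


def kernel_start(
    kernel: KernelResult,
    baseline: float = BASELINE_RATE,
    noise_sds: float = 2.0,
) -> KernelResult:
    """Kernel start point: knot of a two-segment fit (flat at baseline,
    then linear to the kernel extremum), found by grid search over
    candidate knots at the kernel's resolution; ties break toward the
    response (latest start).

    A kernel whose extremum does not exceed ``noise_sds`` SEMs from
    baseline has no defined start and is flagged.
    """
    t, y = kernel.t, kernel.mean_rate
    ok = ~np.isnan(y)
    t, y = t[ok], y[ok]
    sem = kernel.sem[ok]
    dev = np.abs(y - baseline)
    i_ext = int(np.argmax(dev))
    typ_sem = np.nanmedian(sem) if np.isfinite(np.nanmedian(sem)) else 0.0
    if dev[i_ext] <= noise_sds * typ_sem or dev[i_ext] == 0.0:
        kernel.start_defined = False
        kernel.start_time = np.nan
        return kernel
    t_ext, y_ext = t[i_ext], y[i_ext]
    best_t0, best_sse = None, np.inf
    for j in range(i_ext):
        sse = _piecewise_sse(t, y, t[j], t_ext, y_ext, baseline)
        if sse <= best_sse:  # <=: later knots win ties
            best_sse, best_t0 = sse, t[j]
    if best_t0 is None:
        kernel.start_defined = False
        kernel.start_time = np.nan
        return kernel
    kernel.start_defined = True
    kernel.start_time = float(best_t0)
    kernel.baseline = baseline
    return kernel


def kernel_start_ci(
    dataset,
    condition: str,
    n_boot: int = 200,
    rng: Optional[np.random.Generator] = None,
    **kernel_kwargs,
):
    """Bootstrap (over trials) CI for the kernel start point."""
    rng = rng or np.random.default_rng(0)
    trials, clicks = dataset
    fa = _qualifying_fas(trials, condition)
    if not len(fa):
        raise RevcorrError(f"no qualifying false alarms for {condition}")
    starts = []
    for _ in range(n_boot):
        idx = rng.integers(len(fa), size=len(fa))
        boot_trials = fa.iloc[idx].reset_index(drop=True)
        # fa_kernel looks up by trial_id, so duplicated rows are fine
        boot = (boot_trials, clicks)
        try:
            k = kernel_start(fa_kernel(boot, condition, **kernel_kwargs))
        except RevcorrError:
            continue
        if k.start_defined:
            starts.append(k.start_time)
    if not starts:
        return (np.nan, np.nan)
    lo, hi = np.percentile(starts, [5, 95])
    return (float(lo), float(hi))
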