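"""Model-free behavioral summaries: hit rates, psychometric thresholds,
false-alarm estimators, reaction times, and bootstrap inference.

Conventions follow the change-detection task's analysis rules: hit rates
condition on the change having occurred (false-alarm trials are removed
from the denominator), informed false-alarm rates count cue-consistent
premature responses against all trials of that cue, and uninformed rates
in each direction discount the opposite direction's false alarms from the
denominator (a false alarm in one direction masks a potential later one in
the other).  Interval conventions: binomial rates carry exact
(Clopper-Pearson) 95% intervals; bootstrap intervals are the 5th/95th
percentiles of 1000 resampled statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from statsmodels.stats.proportion import proportion_confint

from .task import condition_label

__all__ = [
    "hit_rate",
    "psychometric_table",
    "fit_threshold",
    "false_alarm_rates",
    "reaction_times",
    "bootstrap_test",
    "PsychometricSummary",
    "FARateSummary",
]

N_BOOT = 1000

CONDITIONS = (
    "informed_increase",
    "informed_decrease",
    "uninformed_increase",
    "uninformed_decrease",
)

_CHANGE_OUTCOMES = ("hit", "miss", "wrong_direction")


class EstimatorError(ValueError):
    """Raised when a rate or threshold is undefined for the given data."""


@dataclass
class PsychometricSummary:
    condition: str
    deltas: np.ndarray
    hit_rates: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_per_delta: np.ndarray
    threshold: float = np.nan
    threshold_ci: tuple = (np.nan, np.nan)
    extrapolated: bool = False
    sigmoid: dict = field(default_factory=dict)


@dataclass
class FARateSummary:
    condition: str
    rate: float
    numerator: int
    denominator: int
    ci_low: float
    ci_high: float


def _with_condition(trials: pd.DataFrame) -> pd.DataFrame:
    if "condition" not in trials.columns:
        trials = trials.copy()
        trials["condition"] = trials.apply(condition_label, axis=1)
    return trials


def _analysis_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop attention-lapse exclusions; keep everything else."""
    t = _with_condition(trials)
    return t[~t["outcome"].isin(["early_excluded", "opposite_cue_excluded"])]


def hit_rate(trials: pd.DataFrame, condition: str, delta: float):
    """Hit rate at one |delta| with an exact binomial 95% CI.

    The denominator contains trials of the condition whose change actually
    occurred (hits, misses, wrong-direction reports); false alarms and
    excluded trials are removed.
    """
    t = _analysis_frame(trials)
    sub = t[
        (t["condition"] == condition)
        & (t["delta_hz"].abs() == abs(delta))
        & t["outcome"].isin(_CHANGE_OUTCOMES)
    ]
    n = len(sub)
    if n == 0:
        raise EstimatorError(
            f"no qualifying trials for {condition} at delta {delta}"
        )
    k = int((sub["outcome"] == "hit").sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return k / n, (float(lo), float(hi)), k, n


def psychometric_table(trials: pd.DataFrame, condition: str) -> PsychometricSummary:
    """Per-delta hit rates with exact binomial CIs for one condition."""
    t = _analysis_frame(trials)
    sub = t[(t["condition"] == condition) & t["outcome"].isin(_CHANGE_OUTCOMES)]
    if not len(sub):
        raise EstimatorError(f"no qualifying trials for {condition}")
    deltas = np.sort(sub["delta_hz"].abs().unique())
    rates, lows, highs, ns = [], [], [], []
    for d in deltas:
        r, (lo, hi), _, n = hit_rate(trials, condition, d)
        rates.append(r)
        lows.append(lo)
        highs.append(hi)
        ns.append(n)
    return PsychometricSummary(
        condition=condition,
        deltas=deltas,
        hit_rates=np.array(rates),
        ci_low=np.array(lows),
        ci_high=np.array(highs),
        n_per_delta=np.array(ns),
    )


def _sigmoid(x, ceiling, midpoint, width):
    return ceiling / (1.0 + np.exp(-(x - midpoint) / width))


def _fit_sigmoid_threshold(deltas, rates, weights=None):
    """Least-squares logistic (floor 0, free ceiling <= 1) and the |delta|
    at 50% hits."""
    deltas = np.asarray(deltas, float)
    rates = np.asarray(rates, float)
    if len(deltas) < 3:
        raise EstimatorError("need at least 3 delta levels")
    if np.polyfit(deltas, rates, 1)[0] <= 0:
        raise EstimatorError("hit rates do not increase with |delta|")
    sigma = None
    if weights is not None:
        sigma = 1.0 / np.sqrt(np.maximum(np.asarray(weights, float), 1.0))
    p0 = (min(1.0, max(rates.max(), 0.6)), float(np.median(deltas)), 10.0)
    with warnings.catch_warnings():
        # an exact 3-point fit has no residual dof; the covariance warning
        # is expected and irrelevant (only the point fit is used)
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(
            _sigmoid, deltas, rates, p0=p0,
            bounds=([0.51, 0.0, 0.5], [1.0, 200.0, 100.0]),
            sigma=sigma, maxfev=5000,
        )
    ceiling, mid, width = popt
    if ceiling <= 0.5:
        raise EstimatorError("fitted ceiling below 50%: threshold undefined")
    thr = mid - width * np.log(ceiling / 0.5 - 1.0)
    return float(thr), {"ceiling": float(ceiling), "midpoint": float(mid),
                        "width": float(width)}


def fit_threshold(
    trials: pd.DataFrame,
    condition: str,
    n_boot: int = N_BOOT,
    rng: Optional[np.random.Generator] = None,
) -> PsychometricSummary:
    """Psychometric threshold: the |delta| giving a 50% hit rate on a
    logistic fit, with a trial-resampling bootstrap CI (5th/95th
    percentiles of ``n_boot`` refits).

    The threshold is signed by the condition's direction.  A fitted curve
    crossing 50% outside the tested delta range is flagged extrapolated.
    """
    rng = rng or np.random.default_rng(0)
    summ = psychometric_table(trials, condition)
    thr, sig = _fit_sigmoid_threshold(summ.deltas, summ.hit_rates, summ.n_per_delta)
    summ.extrapolated = not (summ.deltas.min() <= thr <= summ.deltas.max())
    t = _analysis_frame(trials)
    sub = t[(t["condition"] == condition) & t["outcome"].isin(_CHANGE_OUTCOMES)]
    dabs = sub["delta_hz"].abs().to_numpy()
    is_hit = (sub["outcome"] == "hit").to_numpy()
    n = len(sub)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        db, hb = dabs[idx], is_hit[idx]
        levels = np.sort(np.unique(db))
        if len(levels) < 3:
            continue
        rates = np.array([hb[db == d].mean() for d in levels])
        try:
            tb, _ = _fit_sigmoid_threshold(
                levels, rates, [np.sum(db == d) for d in levels]
            )
        except (EstimatorError, RuntimeError):
            continue
        boots.append(tb)
    sign = -1.0 if condition.endswith("decrease") else 1.0
    summ.threshold = sign * thr
    if boots:
        lo, hi = np.percentile(boots, [5, 95])
        summ.threshold_ci = tuple(sorted((sign * float(lo), sign * float(hi))))
    summ.sigmoid = sig
    return summ


def false_alarm_rates(trials: pd.DataFrame) -> dict[str, FARateSummary]:
    """False-alarm rate per condition with exact binomial CIs.

    Informed conditions: cue-consistent false alarms over all trials of
    that cue (cue-opposite responses stay in the denominator only).
    Uninformed, per direction: false alarms reported in that direction over
    the uninformed total minus the other direction's false alarms.
    """
    t = _with_condition(trials)
    t = t[t["outcome"] != "early_excluded"]
    out: dict[str, FARateSummary] = {}
    for cue in ("increase", "decrease"):
        sub = t[t["cue"] == cue]
        n = len(sub)
        if n == 0:
            raise EstimatorError(f"no trials with cue {cue}")
        k = int((sub["outcome"] == "false_alarm").sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        out[f"informed_{cue}"] = FARateSummary(
            f"informed_{cue}", k / n, k, n, float(lo), float(hi)
        )
    sub = t[t["cue"] == "either"]
    n_u = len(sub)
    fa = sub[sub["outcome"] == "false_alarm"]
    for d in ("increase", "decrease"):
        k = int((fa["reported_dir"] == d).sum())
        k_other = int((fa["reported_dir"] != d).sum())
        denom = n_u - k_other
        if denom <= 0:
            raise EstimatorError(f"empty denominator for uninformed {d}")
        lo, hi = proportion_confint(k, denom, alpha=0.05, method="beta")
        out[f"uninformed_{d}"] = FARateSummary(
            f"uninformed_{d}", k / denom, k, denom, float(lo), float(hi)
        )
    return out


def reaction_times(
    trials: pd.DataFrame,
    condition: str,
    n_boot: int = N_BOOT,
    rng: Optional[np.random.Generator] = None,
):
    """Mean hit reaction time (response minus change time) with a
    bootstrap CI (5th/95th percentiles of resampled means)."""
    rng = rng or np.random.default_rng(0)
    t = _with_condition(trials)
    hits = t[(t["condition"] == condition) & (t["outcome"] == "hit")]
    if not len(hits):
        raise EstimatorError(f"no hits for {condition}")
    rts = (hits["response_time_s"] - hits["change_time_s"]).to_numpy(dtype=float)
    m = float(rts.mean())
    idx = rng.integers(len(rts), size=(n_boot, len(rts)))
    means = rts[idx].mean(axis=1)
    lo, hi = np.percentile(means, [5, 95])
    return m, (float(lo), float(hi)), len(rts)


def bootstrap_test(
    a,
    b,
    statistic: Optional[Callable] = None,
    sided: str = "two",
    n_boot: int = N_BOOT,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Bootstrap hypothesis test between two samples.

    Two-sided: a t-statistic is referred to its pseudo-null distribution,
    built by pooling both groups and resampling groups of the original
    sizes with replacement; p is the fraction of null statistics whose
    absolute value reaches the observed one.  One-sided: each group is
    resampled from itself and p is the fraction of bootstrapped differences
    opposite in sign to the observed mean difference.  Both use add-one
    smoothing so p is never exactly zero.
    """
    rng = rng or np.random.default_rng(0)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise EstimatorError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    if sided == "two":
        stat = statistic or _welch_t
        obs = stat(a, b)
        na, nb = len(a), len(b)
        ia = rng.integers(len(pooled), size=(n_boot, na))
        ib = rng.integers(len(pooled), size=(n_boot, nb))
        null = np.array([stat(pooled[ia[i]], pooled[ib[i]]) for i in range(n_boot)])
        return float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_boot + 1))
    if sided == "one":
        obs = a.mean() - b.mean()
        if obs == 0:
            return 1.0
        ia = rng.integers(len(a), size=(n_boot, len(a)))
        ib = rng.integers(len(b), size=(n_boot, len(b)))
        diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
        return float((1 + np.sum(np.sign(diffs) == -np.sign(obs))) / (n_boot + 1))
    raise ValueError("sided must be 'two' or 'one'")


def _welch_t(a, b):
    va = a.var(ddof=1) / len(a) if len(a) > 1 else 0.0
    vb = b.var(ddof=1) / len(b) if len(b) > 1 else 0.0
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return (a.mean() - b.mean()) / denom
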