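"""Maximum-likelihood fitting of the OU change-detection model, posterior
approximation with credible intervals, and model-evidence comparison.

Three condition models are supported: ``informed_increase`` (single process,
upper bound), ``informed_decrease`` (single process, lower bound), and
``uninformed`` (two single-bound processes racing on the same click train,
with either separate or shared filter widths).

The point stage is a derivative-free search (screening starts followed by
Nelder-Mead) over a profile likelihood: the propagation-determining
parameters (filter widths, bounds, process noise) are the outer variables,
and for each outer candidate the two non-decision-time parameters — which
only move mass through a cheap convolution — are optimized in an inner loop
against cached bound-crossing densities.  The posterior stage is a Laplace
approximation at the optimum under the uniform prior box: a numerical
Hessian gives a Gaussian posterior, truncated to the box, from which
100,000 samples provide point estimates (posterior means), 5th/95th
credible intervals, and a log-model-evidence estimate used alongside
BIC/AIC for model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import qmc

from .oufp import ProcessEngine, TrialBatch
from .params import ModelParams, ParameterError, SolverConfig

__all__ = [
    "FitSpec",
    "FitResult",
    "condition_arrays",
    "fit_mle",
    "approximate_posterior",
    "compare_models",
    "fit_all_conditions",
    "parameter_contrast",
]

CONDITIONS = ("informed_increase", "informed_decrease", "uninformed")

DEFAULT_PRIORS = {
    "tau": (0.02, 2.0),
    "tau_inc": (0.02, 2.0),
    "tau_dec": (0.02, 2.0),
    "bound_up": (60.0, 150.0),
    "bound_down": (5.0, 60.0),
    "sigma_process": (0.1, 50.0),
    "ndt_mean": (0.1, 0.6),
    "ndt_sd": (0.01, 0.2),
}

_LOG_DIMS = ("tau", "tau_inc", "tau_dec", "sigma_process", "ndt_sd")
_NDT_NAMES = ("ndt_mean", "ndt_sd")


@dataclass
class FitSpec:
    """Model structure, priors, and optimizer settings for one condition."""

    condition: str = "informed_increase"
    shared_tau: bool = False          # uninformed model only
    depression_enabled: bool = False
    priors: dict = field(default_factory=dict)
    solver: SolverConfig = field(default_factory=SolverConfig)
    n_screen: int = 10                # screening starts (space-filling)
    n_polish: int = 1                 # Nelder-Mead runs from the best starts
    maxfev: int = 90                  # outer function evaluations per polish
    inner_maxfev: int = 40
    seed: int = 0
    hessian_subsample: Optional[int] = None
    n_posterior_samples: int = 100_000
    extra_starts: list = field(default_factory=list)  # slow-param dicts
    n_coord_sweeps: int = 2
    hessian_mode: str = "central"     # "central" | "forward"

    def param_names(self) -> list[str]:
        if self.condition == "informed_increase":
            return ["tau", "bound_up", "sigma_process", "ndt_mean", "ndt_sd"]
        if self.condition == "informed_decrease":
            return ["tau", "bound_down", "sigma_process", "ndt_mean", "ndt_sd"]
        if self.condition == "uninformed":
            taus = ["tau"] if self.shared_tau else ["tau_inc", "tau_dec"]
            return taus + ["bound_up", "bound_down", "sigma_process",
                           "ndt_mean", "ndt_sd"]
        raise ParameterError(f"unknown condition {self.condition!r}")

    def slow_names(self) -> list[str]:
        return [n for n in self.param_names() if n not in _NDT_NAMES]

    def prior_box(self) -> dict:
        box = dict(DEFAULT_PRIORS)
        box.update(self.priors)
        for name in self.param_names():
            lo, hi = box[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ParameterError(f"invalid prior range for {name}")
        return box

    def validate(self) -> "FitSpec":
        if self.condition not in CONDITIONS:
            raise ParameterError(f"unknown condition {self.condition!r}")
        self.prior_box()
        self.solver.validate()
        return self


@dataclass
class FitResult:
    """Point estimates, posterior summary, and model scores for one fit."""

    spec: FitSpec
    params: dict                       # point estimates (posterior mean if available)
    mle_params: dict
    loglik: float
    n_trials: int
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)
    posterior_samples: Optional[dict] = None
    evidence: Optional[float] = None
    bic: Optional[float] = None
    aic: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    def n_params(self) -> int:
        return len(self.spec.param_names())

    def summary_frame(self):
        import pandas as pd

        names = self.spec.param_names()
        return pd.DataFrame(
            {
                "parameter": names,
                "estimate": [self.params[n] for n in names],
                "mle": [self.mle_params[n] for n in names],
                "ci_low": [self.ci_low.get(n, np.nan) for n in names],
                "ci_high": [self.ci_high.get(n, np.nan) for n in names],
            }
        )


# ---------------------------------------------------------------------------
# data preparation

_INCLUDED = {"hit": 1, "false_alarm": 1, "miss": 0}


def condition_arrays(dataset) -> dict:
    """Group a (trials frame, clicks dict) dataset by fitted condition.

    Trials with excluded outcomes (early, opposite-cue, wrong-direction)
    are dropped.  Returns, per condition, the click trains, trial horizons,
    response times (NaN for misses), outcome codes (0 miss / 1 response),
    and — for the uninformed group — which responses reported an increase.
    """
    trials, clicks = dataset
    out: dict[str, dict] = {}
    for cond, cue in (
        ("informed_increase", "increase"),
        ("informed_decrease", "decrease"),
        ("uninformed", "either"),
    ):
        sub = trials[(trials["cue"] == cue) & trials["outcome"].isin(_INCLUDED)]
        if not len(sub):
            continue
        rts = sub["response_time_s"].to_numpy(dtype=float)
        out[cond] = {
            "trial_ids": sub["trial_id"].to_numpy(),
            "clicks": [clicks[t] for t in sub["trial_id"]],
            "max_time": sub["max_time_s"].to_numpy(dtype=float),
            "response_time": rts,
            "outcome_code": sub["outcome"].map(_INCLUDED).to_numpy(dtype=np.int8),
            "reported_up": (sub["reported_dir"] == "increase").to_numpy(dtype=bool),
        }
    return out


# ---------------------------------------------------------------------------
# parameter transforms


def _to_internal(name: str, v: float) -> float:
    return math.log(v) if name in _LOG_DIMS else v


def _from_internal(name: str, x: float) -> float:
    return math.exp(x) if name in _LOG_DIMS else x


def _internal_box(names, box):
    lo = np.array([_to_internal(n, box[n][0]) for n in names])
    hi = np.array([_to_internal(n, box[n][1]) for n in names])
    return lo, hi


def _clip_inside(x, lo, hi, frac=1e-6):
    pad = (hi - lo) * frac
    return np.clip(x, lo + pad, hi - pad)


# ---------------------------------------------------------------------------
# likelihood evaluation with propagation caching


class _Objective:
    """Profile likelihood for one condition with crossing-density caching.

    The inner (non-decision-time) likelihood uses an algebraically
    equivalent fast form of the window sum: summing the NDT-convolved
    density over the response window equals a dot product of the crossing
    density with differences of the NDT filter's cumulative sum at
    precomputed offsets, so no convolution is needed per inner iteration.
    """

    def __init__(self, dataset, spec: FitSpec):
        spec.validate()
        self.spec = spec
        arrs = condition_arrays(dataset).get(spec.condition)
        if arrs is None:
            raise ParameterError(f"no includable trials for {spec.condition}")
        self.arrs = arrs
        self.n_trials = len(arrs["clicks"])
        dep = ModelParams(
            bound_up=100.0, depression_enabled=spec.depression_enabled
        )
        self.batch = TrialBatch(
            arrs["clicks"], arrs["max_time"], dep, spec.solver,
            response_times=arrs["response_time"],
        )
        self.engine = ProcessEngine(self.batch, spec.solver)
        self.names = spec.param_names()
        self.slow = spec.slow_names()
        self.box = spec.prior_box()
        self._cache: dict = {}
        self._fast_cache: dict = {}
        self.nfev_slow = 0
        self._prepare_fast()

    # offsets retained when gathering crossing mass relative to the
    # response/end bin; covers the NDT filter's maximal support
    _OMAX = 96

    def _prepare_fast(self):
        a = self.arrs
        solver = self.spec.solver
        self.resp_mask = a["outcome_code"] == 1
        self.miss_mask = ~self.resp_mask
        rts = a["response_time"][self.resp_mask]
        self._k0 = np.ceil(
            (rts - solver.likelihood_window) / solver.dt - 0.5 - 1e-9
        ).astype(np.int64)
        self._k1 = np.floor(
            (rts + solver.likelihood_window) / solver.dt - 0.5 + 1e-9
        ).astype(np.int64)
        self._k0 = np.maximum(self._k0, 0)
        mt_miss = a["max_time"][self.miss_mask]
        kend = np.maximum(
            np.ceil(mt_miss / solver.dt - 1e-9).astype(np.int64) - 1, 0
        )
        self._kend_miss = kend
        o = np.arange(self._OMAX)
        # exact NDT survival argument for each retained offset
        t_centers = (kend[:, None] - o[None, :] + 0.5) * solver.dt
        self._X_miss = mt_miss[:, None] - t_centers

    @staticmethod
    def _gather_back(cross: np.ndarray, anchor: np.ndarray, omax: int):
        """M[i, o] = cross[i, anchor[i] - o] (zero outside the row)."""
        n, T = cross.shape
        o = np.arange(omax)
        idx = anchor[:, None] - o[None, :]
        valid = (idx >= 0) & (idx < T)
        M = cross[np.arange(n)[:, None], np.clip(idx, 0, T - 1)]
        M[~valid] = 0.0
        return M

    def _fast_pieces(self, slow_vals: dict):
        """Gathered crossing-mass blocks for the inner NDT likelihood."""
        key = tuple(round(slow_vals[n], 10) for n in self.slow)
        hit = self._fast_cache.get(key)
        if hit is not None:
            return hit
        pieces = self._crossings(slow_vals)
        resp, miss = self.resp_mask, self.miss_mask
        if pieces[0] == "single":
            _, cross, surv_end = pieces
            cross_resp = cross[resp]
            cross_miss = cross[miss]
            surv_miss = surv_end[miss]
        else:
            _, d_up, d_dn, joint_surv = pieces
            up = self.arrs["reported_up"][resp]
            cross_resp = np.where(up[:, None], d_up[resp], d_dn[resp])
            cross_miss = d_up[miss] + d_dn[miss]
            surv_miss = joint_surv[miss]
        om = self._OMAX
        csum = np.cumsum(cross_resp, axis=1)
        n = len(cross_resp)
        T = cross_resp.shape[1]
        # totals of crossing mass at bins earlier than the retained offsets:
        # their NDT cumulative weight is 1 (response certainly registered
        # before the window's leading edge is irrelevant there, weight
        # saturates), handled via the base terms
        def base(anchor):
            early = anchor - om
            val = np.zeros(n)
            ok = early >= 0
            val[ok] = csum[np.arange(n)[ok], np.minimum(early[ok], T - 1)]
            return val

        M1 = self._gather_back(cross_resp, self._k1, om)
        M0 = self._gather_back(cross_resp, self._k0 - 1, om)
        b1 = base(self._k1)
        b0 = base(self._k0 - 1)
        ML = self._gather_back(cross_miss, self._kend_miss, om)
        fast = (M1, M0, b1, b0, ML, surv_miss)
        if len(self._fast_cache) > 64:
            self._fast_cache.clear()
        self._fast_cache[key] = fast
        return fast

    def _ndt_cumweights(self, mu: float, sd: float) -> np.ndarray:
        """Cumulative NDT filter mass at integer bin offsets 0..OMAX-1."""
        solver = self.spec.solver
        stub = ModelParams(bound_up=100.0, ndt_mean=mu, ndt_sd=sd)
        from .oufp import ndt_kernel

        kern, j0 = ndt_kernel(stub, solver)
        kc = np.zeros(self._OMAX)
        m = len(kern)
        cs = np.cumsum(kern)
        o = np.arange(self._OMAX) - j0
        sel = (o >= 0) & (o < m)
        kc[sel] = cs[o[sel]]
        kc[o >= m] = 1.0
        return kc

    # -- model assembly ----------------------------------------------------

    def _model_params(self, values: dict, side: str) -> ModelParams:
        tau = values.get("tau")
        if tau is None:
            tau = values["tau_inc"] if side == "up" else values["tau_dec"]
        return ModelParams(
            tau=tau,
            bound_up=values.get("bound_up") if side == "up" else None,
            bound_down=values.get("bound_down") if side == "down" else None,
            sigma_process=values["sigma_process"],
            ndt_mean=values.get("ndt_mean", 0.3),
            ndt_sd=values.get("ndt_sd", 0.05),
            depression_enabled=self.spec.depression_enabled,
        )

    def _crossings(self, slow_vals: dict):
        key = tuple(round(slow_vals[n], 10) for n in self.slow)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.nfev_slow += 1
        if self.spec.condition == "uninformed":
            p_up = self._model_params(slow_vals, "up")
            p_dn = self._model_params(slow_vals, "down")
            cu, su, se_u = self.engine.crossing(p_up)
            cd, sd, se_d = self.engine.crossing(p_dn)
            su[:, -1] = se_u
            sd[:, -1] = se_d
            s_up_prev = np.concatenate((np.ones((len(su), 1)), su[:, :-1]), axis=1)
            s_dn_prev = np.concatenate((np.ones((len(sd), 1)), sd[:, :-1]), axis=1)
            both = cu * cd
            d_up = cu * s_dn_prev - 0.5 * both
            d_dn = cd * s_up_prev - 0.5 * both
            pieces = ("joint", d_up, d_dn, se_u * se_d)
        elif self.spec.condition == "informed_increase":
            p = self._model_params(slow_vals, "up")
            cross, _, surv_end = self.engine.crossing(p)
            pieces = ("single", cross, surv_end)
        else:
            p = self._model_params(slow_vals, "down")
            cross, _, surv_end = self.engine.crossing(p)
            pieces = ("single", cross, surv_end)
        if len(self._cache) > 4:  # raw densities are large; the compact
            self._cache.clear()   # gathered blocks carry the real cache

        self._cache[key] = pieces
        return pieces

    def loglik_given(self, slow_vals: dict, ndt_mean: float, ndt_sd: float) -> float:
        from scipy.special import ndtr

        M1, M0, b1, b0, ML, surv_miss = self._fast_pieces(slow_vals)
        floor = self.spec.solver.likelihood_floor
        ll = 0.0
        if len(M1):
            kc = self._ndt_cumweights(ndt_mean, ndt_sd)
            p = (b1 - b0) + M1 @ kc - M0 @ kc
            ll += np.log(np.maximum(p, floor)).sum()
        if len(ML):
            late = 1.0 - ndtr((self._X_miss - ndt_mean) / ndt_sd)
            p = surv_miss + np.einsum("ij,ij->i", ML, late)
            ll += np.log(np.maximum(p, floor)).sum()
        return float(ll)

    def loglik(self, values: dict) -> float:
        return self.loglik_given(values, values["ndt_mean"], values["ndt_sd"])

    # -- profile over the NDT parameters -----------------------------------

    def profile(self, slow_vals: dict, ndt_start: np.ndarray):
        """Best log-likelihood over (ndt_mean, ndt_sd) at fixed slow params."""
        lo, hi = _internal_box(_NDT_NAMES, self.box)

        def neg(x):
            x = _clip_inside(x, lo, hi)
            return -self.loglik_given(
                slow_vals,
                _from_internal("ndt_mean", x[0]),
                _from_internal("ndt_sd", x[1]),
            )

        x0 = _clip_inside(np.asarray(ndt_start, dtype=float), lo, hi)
        res = minimize(
            neg, x0, method="Nelder-Mead",
            options={"maxfev": self.spec.inner_maxfev, "fatol": 0.01,
                     "xatol": 1e-3},
        )
        best = _clip_inside(res.x, lo, hi)
        return -res.fun, best


def _heuristic_start(slow_names, box):
    """Physiologically motivated start: bounds about 2.5 shot-noise SDs
    from baseline at a mid-range filter width, moderate process noise."""
    tau0 = 0.3
    shot_sd = math.sqrt(60.0 / (2.0 * tau0))
    guess = {
        "tau": tau0,
        "tau_inc": tau0,
        "tau_dec": tau0,
        "bound_up": 60.0 + 2.5 * shot_sd,
        "bound_down": 60.0 - 2.5 * shot_sd,
        "sigma_process": 5.0,
    }
    out = []
    for n in slow_names:
        lo, hi = box[n]
        v = min(max(guess[n], lo), hi)
        out.append(_to_internal(n, v))
    return np.array(out)


def _space_filling_starts(lo, hi, n, seed):
    if n <= 0:
        return np.empty((0, lo.size))
    sampler = qmc.Sobol(d=lo.size, scramble=True, seed=seed)
    u = sampler.random(n)
    return lo + u * (hi - lo)


def fit_mle(dataset, spec: FitSpec) -> FitResult:
    """Point stage: screening starts plus Nelder-Mead on the profile
    likelihood.  Returns a FitResult without posterior fields."""
    spec.validate()
    obj = _Objective(dataset, spec)
    slow_names = obj.slow
    lo, hi = _internal_box(slow_names, obj.box)
    ndt_lo, ndt_hi = _internal_box(_NDT_NAMES, obj.box)
    rng = np.random.default_rng(spec.seed)

    center = 0.5 * (lo + hi)
    starts = [center, _heuristic_start(slow_names, obj.box)]
    for extra in spec.extra_starts:
        starts.insert(
            0,
            np.array([_to_internal(n, extra[n]) for n in slow_names]),
        )
    starts.extend(_space_filling_starts(lo, hi, spec.n_screen - 2, spec.seed))
    ndt_warm = 0.5 * (ndt_lo + ndt_hi)

    screened = []
    for x in starts:
        x = _clip_inside(np.asarray(x), lo, hi)
        vals = {n: _from_internal(n, xi) for n, xi in zip(slow_names, x)}
        ll, ndt_best = obj.profile(vals, ndt_warm)
        screened.append((ll, x, ndt_best))
    screened.sort(key=lambda t: -t[0])

    # best point seen anywhere, including intermediate optimizer evals
    best = {"ll": screened[0][0], "x": screened[0][1].copy(),
            "ndt": screened[0][2].copy()}
    state = {"ndt": screened[0][2].copy()}

    def neg_profile(x):
        x = _clip_inside(x, lo, hi)
        vals = {n: _from_internal(n, xi) for n, xi in zip(slow_names, x)}
        ll, ndt_best = obj.profile(vals, state["ndt"])
        state["ndt"] = ndt_best
        if ll > best["ll"]:
            best["ll"], best["x"], best["ndt"] = ll, x.copy(), ndt_best.copy()
        return -ll

    polish_lls = []
    for k in range(max(spec.n_polish, 1)):
        if k >= len(screened):
            break
        state["ndt"] = screened[k][2].copy()
        res = minimize(
            neg_profile, screened[k][1], method="Nelder-Mead",
            options={"maxfev": spec.maxfev, "fatol": 0.02, "xatol": 5e-3,
                     "adaptive": True},
        )
        polish_lls.append(-res.fun)

    # coordinate sweeps from the best point: guard against the search
    # stalling on a ridge or a flat face of the box (neg_profile itself
    # keeps `best` up to date)
    for _ in range(spec.n_coord_sweeps):
        ll_before = best["ll"]
        for i in range(len(slow_names)):
            span = hi[i] - lo[i]
            for off in (-0.25, -0.1, 0.1, 0.25):
                x_try = best["x"].copy()
                x_try[i] = np.clip(x_try[i] + off * span, lo[i], hi[i])
                neg_profile(x_try)
        minimize(
            neg_profile, best["x"], method="Nelder-Mead",
            options={"maxfev": max(spec.maxfev // 2, 30), "fatol": 0.01,
                     "xatol": 2e-3, "adaptive": True},
        )
        if best["ll"] <= ll_before + 0.05:
            break

    best_ll, best_x, best_ndt = best["ll"], best["x"], best["ndt"]
    if not np.isfinite(best_ll):
        raise RuntimeError("all optimizer starts failed to produce a finite likelihood")

    mle = {n: _from_internal(n, xi) for n, xi in zip(slow_names, best_x)}
    mle["ndt_mean"] = _from_internal("ndt_mean", best_ndt[0])
    mle["ndt_sd"] = _from_internal("ndt_sd", best_ndt[1])
    return FitResult(
        spec=spec,
        params=dict(mle),
        mle_params=mle,
        loglik=best_ll,
        n_trials=obj.n_trials,
        bic=len(spec.param_names()) * math.log(obj.n_trials) - 2.0 * best_ll,
        aic=2.0 * len(spec.param_names()) - 2.0 * best_ll,
        diagnostics={
            "screen_logliks": [s[0] for s in screened],
            "polish_logliks": polish_lls,
            "n_propagations": obj.nfev_slow,
        },
    )


# ---------------------------------------------------------------------------
# Laplace posterior stage


def _numerical_hessian(f, x0, steps, mode="central"):
    """Finite-difference Hessian of scalar f at x0.

    ``central`` is the accurate default; ``forward`` needs roughly a
    quarter of the evaluations (1 + 2d + d(d-1)/2) at reduced accuracy,
    adequate when only the log-determinant is consumed.
    """
    d = x0.size
    H = np.zeros((d, d))
    f0 = f(x0)
    if mode == "forward":
        f1 = np.empty(d)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = steps[i]
            f1[i] = f(x0 + ei)
            f2 = f(x0 + 2 * ei)
            H[i, i] = (f2 - 2.0 * f1[i] + f0) / steps[i] ** 2
        for i in range(d):
            for j in range(i + 1, d):
                e = np.zeros(d)
                e[i] = steps[i]
                e[j] = steps[j]
                fij = f(x0 + e)
                H[i, j] = H[j, i] = (fij - f1[i] - f1[j] + f0) / (steps[i] * steps[j])
        return H, f0
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = steps[i]
        fpp = f(x0 + ei)
        fmm = f(x0 - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / steps[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * steps[i] * steps[j])
    return H, f0


def approximate_posterior(dataset, spec: FitSpec, mle: FitResult) -> FitResult:
    """Posterior stage: Laplace approximation at the MLE under the uniform
    prior box.

    Produces posterior samples (Gaussian, truncated to the box), point
    estimates as posterior means, 5th/95th credible intervals, and a
    log-evidence estimate (Laplace integral with a box-truncation
    correction).  A posterior that piles onto a prior edge is flagged in
    the diagnostics rather than silently reported.
    """
    spec.validate()
    names = spec.param_names()
    box = spec.prior_box()
    lo, hi = _internal_box(names, box)
    x_hat = np.array([_to_internal(n, mle.mle_params[n]) for n in names])
    x_hat = _clip_inside(x_hat, lo, hi, 1e-4)

    sub = spec.hessian_subsample
    if sub is not None and sub < mle.n_trials:
        trials, clicks = dataset
        rng = np.random.default_rng(spec.seed + 1)
        # subsample within the fitted condition, preserving outcome mix
        keep = rng.permutation(len(trials))[: max(sub, 50)]
        sub_dataset = (trials.iloc[np.sort(keep)], clicks)
        obj = _Objective(sub_dataset, spec)
        scale = mle.n_trials / obj.n_trials
    else:
        obj = _Objective(dataset, spec)
        scale = 1.0

    def neg(x):
        x = _clip_inside(x, lo, hi)
        vals = {n: _from_internal(n, xi) for n, xi in zip(names, x)}
        return -obj.loglik(vals)

    # differencing step per dimension: a fixed fraction of the prior range
    # (large enough to average over the solver's sub-cell roughness)
    steps = 0.015 * (hi - lo)
    shrink = 0.45 if spec.hessian_mode == "forward" else 0.9
    steps = np.minimum(steps, np.minimum(x_hat - lo, hi - x_hat) * shrink)
    steps = np.maximum(steps, 1e-4)
    H, _ = _numerical_hessian(neg, x_hat, steps, mode=spec.hessian_mode)
    H = 0.5 * (H + H.T) * scale

    evals, evecs = np.linalg.eigh(H)
    floor = max(1e-8, 1e-6 * max(evals.max(), 1.0))
    degenerate = bool((evals < floor).any())
    evals = np.maximum(evals, floor)
    cov = (evecs / evals) @ evecs.T
    logdet_cov = float(-np.log(evals).sum())

    rng = np.random.default_rng(spec.seed + 2)
    n_s = spec.n_posterior_samples
    draws = rng.multivariate_normal(x_hat, cov, size=n_s, method="eigh")
    inside = np.all((draws >= lo) & (draws <= hi), axis=1)
    frac_inside = float(inside.mean())
    if inside.sum() >= max(1000, n_s // 100):
        draws = draws[inside]
    else:
        draws = np.clip(draws, lo, hi)
    natural = {
        n: (np.exp(draws[:, i]) if n in _LOG_DIMS else draws[:, i])
        for i, n in enumerate(names)
    }

    post_mean = {n: float(natural[n].mean()) for n in names}
    ci_low = {n: float(np.percentile(natural[n], 5)) for n in names}
    ci_high = {n: float(np.percentile(natural[n], 95)) for n in names}

    # edge-piling diagnostic
    edge_flags = {}
    for i, n in enumerate(names):
        span = hi[i] - lo[i]
        edge_flags[n] = bool(
            min(x_hat[i] - lo[i], hi[i] - x_hat[i]) < 0.01 * span
        )

    # Laplace evidence with the uniform prior expressed in internal
    # coordinates (Jacobian of the log transform included)
    d = len(names)
    log_prior = 0.0
    for i, n in enumerate(names):
        nat_lo, nat_hi = box[n]
        log_prior -= math.log(nat_hi - nat_lo)
        if n in _LOG_DIMS:
            log_prior += x_hat[i]  # |dx_natural/dx_internal| = exp(x)
    evidence = (
        mle.loglik
        + log_prior
        + 0.5 * d * math.log(2.0 * math.pi)
        + 0.5 * logdet_cov
        + math.log(max(frac_inside, 1.0 / n_s))
    )

    return FitResult(
        spec=spec,
        params=post_mean,
        mle_params=mle.mle_params,
        loglik=mle.loglik,
        n_trials=mle.n_trials,
        ci_low=ci_low,
        ci_high=ci_high,
        posterior_samples=natural,
        evidence=float(evidence),
        bic=mle.bic,
        aic=mle.aic,
        diagnostics={
            **mle.diagnostics,
            "hessian_degenerate": degenerate,
            "posterior_mass_in_box": frac_inside,
            "edge_flags": edge_flags,
        },
    )


def fit_model(dataset, spec: FitSpec) -> FitResult:
    """Convenience: point stage followed by the posterior stage."""
    return approximate_posterior(dataset, spec, fit_mle(dataset, spec))


# ---------------------------------------------------------------------------
# model comparison and joint condition fits


@dataclass
class ModelComparison:
    evidence_diff: float       # evidence(A) - evidence(B)
    delta_bic: float           # BIC(A) - BIC(B); negative favors A
    delta_aic: float
    winner_evidence: str
    winner_bic: str
    winner_aic: str
    fit_a: FitResult
    fit_b: FitResult


def compare_models(dataset, spec_a: FitSpec, spec_b: FitSpec) -> ModelComparison:
    """Fit two model structures on identical trials and score them.

    Evidence (higher wins), BIC and AIC (lower wins) are reported with the
    selected model per criterion.
    """
    if spec_a.condition != spec_b.condition:
        raise ParameterError("model comparison requires identical trial sets")
    # fit the smaller model first and seed the larger one with its optimum
    # (for nested pairs such as shared- vs separate-filter-width this
    # guarantees the larger model starts at least as well as the smaller);
    # if the larger model then wins by an amount that optimizer
    # under-convergence could explain, map its optimum back and give the
    # smaller model a polishing pass from there, so neither model's score
    # reflects a worse search rather than a worse structure
    a_first = len(spec_a.param_names()) <= len(spec_b.param_names())
    first, second = (spec_a, spec_b) if a_first else (spec_b, spec_a)
    mle_first = fit_mle(dataset, first)
    carry = _map_start(mle_first, second)
    if carry is not None:
        second.extra_starts = list(second.extra_starts) + [carry]
    mle_second = fit_mle(dataset, second)
    gap = mle_second.loglik - mle_first.loglik
    back = _map_start(mle_second, first)
    if back is not None and 0.0 < gap < 30.0:
        import dataclasses

        spec_back = dataclasses.replace(
            first,
            extra_starts=[back, {n: mle_first.mle_params[n]
                                 for n in first.slow_names()}],
            n_screen=2, maxfev=max(first.maxfev // 2, 25), n_coord_sweeps=0,
        )
        repolished = fit_mle(dataset, spec_back)
        if repolished.loglik > mle_first.loglik:
            mle_first = repolished
    fit_first = approximate_posterior(dataset, first, mle_first)
    fit_second = approximate_posterior(dataset, second, mle_second)
    fit_a, fit_b = (fit_first, fit_second) if a_first else (fit_second, fit_first)
    if fit_a.n_trials != fit_b.n_trials:
        raise ParameterError("model comparison requires identical trial sets")
    ev = fit_a.evidence - fit_b.evidence
    db = fit_a.bic - fit_b.bic
    da = fit_a.aic - fit_b.aic
    return ModelComparison(
        evidence_diff=float(ev),
        delta_bic=float(db),
        delta_aic=float(da),
        winner_evidence="A" if ev > 0 else "B",
        winner_bic="A" if db < 0 else "B",
        winner_aic="A" if da < 0 else "B",
        fit_a=fit_a,
        fit_b=fit_b,
    )


def _map_start(fit: FitResult, target_spec: FitSpec) -> Optional[dict]:
    """Translate a fitted optimum into a start for another model structure
    (e.g. a shared filter width seeding both separate widths)."""
    src = fit.mle_params
    out = {}
    for n in target_spec.slow_names():
        if n in src:
            out[n] = src[n]
        elif n in ("tau_inc", "tau_dec") and "tau" in src:
            out[n] = src["tau"]
        elif n == "tau" and "tau_inc" in src:
            out[n] = 0.5 * (src["tau_inc"] + src["tau_dec"])
        else:
            return None
    return out


def parameter_contrast(fit_a: FitResult, fit_b: FitResult, name_a: str,
                       name_b: str | None = None) -> dict:
    """Two-tailed test on the difference of analogous parameters.

    Uses a t-statistic on the posterior-sample differences between two
    independently fitted conditions.
    """
    from scipy.stats import norm

    name_b = name_b or name_a
    sa = fit_a.posterior_samples[name_a]
    sb = fit_b.posterior_samples[name_b]
    m = min(len(sa), len(sb))
    diff = sa[:m] - sb[:m]
    t = diff.mean() / max(diff.std(ddof=1), 1e-12)
    # the posterior-sample SD already measures the difference's dispersion,
    # so the statistic is referred to a standard normal
    p = 2.0 * norm.sf(abs(t))
    return {"difference": float(diff.mean()), "t": float(t), "p": float(p)}


def fit_all_conditions(dataset, base_spec: FitSpec | None = None,
                       shared_tau_uninformed: bool = False) -> dict:
    """Fit all three condition models with a shared NDT-variability term.

    Strategy: fit each condition independently, then re-optimize a single
    shared ``ndt_sd`` (with each condition's ``ndt_mean`` re-profiled
    against its cached crossing densities), and run the posterior stage at
    the shared optimum.  Returns {condition: FitResult} plus the shared
    value under the key ``"shared_ndt_sd"``.
    """
    base = base_spec or FitSpec()
    arrs = condition_arrays(dataset)
    missing = [c for c in CONDITIONS if c not in arrs]
    if missing:
        raise ParameterError(f"empty condition subsets: {missing}")

    objs: dict[str, _Objective] = {}
    mles: dict[str, FitResult] = {}
    for cond in CONDITIONS:
        spec = FitSpec(
            condition=cond,
            shared_tau=shared_tau_uninformed if cond == "uninformed" else False,
            depression_enabled=base.depression_enabled,
            priors=dict(base.priors),
            solver=base.solver,
            n_screen=base.n_screen,
            n_polish=base.n_polish,
            maxfev=base.maxfev,
            inner_maxfev=base.inner_maxfev,
            seed=base.seed,
            hessian_subsample=base.hessian_subsample,
            n_posterior_samples=base.n_posterior_samples,
        )
        mles[cond] = fit_mle(dataset, spec)
        objs[cond] = _Objective(dataset, spec)

    box = base.prior_box()

    def neg_shared(log_sd):
        sd = math.exp(log_sd)
        total = 0.0
        for cond in CONDITIONS:
            m = mles[cond].mle_params
            slow_vals = {n: m[n] for n in mles[cond].spec.slow_names()}

            def neg_mu(mu, cond=cond, slow_vals=slow_vals, sd=sd):
                return -objs[cond].loglik_given(slow_vals, mu, sd)

            r = minimize_scalar(
                neg_mu, bounds=box["ndt_mean"], method="bounded",
                options={"xatol": 1e-3},
            )
            total += -r.fun
        return -total

    r = minimize_scalar(
        neg_shared,
        bounds=(math.log(box["ndt_sd"][0]), math.log(box["ndt_sd"][1])),
        method="bounded",
        options={"xatol": 5e-3},
    )
    shared_sd = math.exp(r.x)

    results: dict = {}
    for cond in CONDITIONS:
        m = mles[cond]
        slow_vals = {n: m.mle_params[n] for n in m.spec.slow_names()}

        def neg_mu(mu, cond=cond, slow_vals=slow_vals):
            return -objs[cond].loglik_given(slow_vals, mu, shared_sd)

        rmu = minimize_scalar(
            neg_mu, bounds=box["ndt_mean"], method="bounded",
            options={"xatol": 1e-3},
        )
        m.mle_params["ndt_mean"] = float(rmu.x)
        m.mle_params["ndt_sd"] = float(shared_sd)
        m.params = dict(m.mle_params)
        m.loglik = float(-rmu.fun)
        results[cond] = approximate_posterior(dataset, m.spec, m)
    results["shared_ndt_sd"] = float(shared_sd)
    return results
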