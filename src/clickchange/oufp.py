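"""Click-driven Ornstein-Uhlenbeck decision model solved by Fokker-Planck
propagation.

The decision variable (DV) is a leaky estimate of the click rate in Hz:

    da = (c - a / tau) dt + sigma_process dW

where ``c`` is the per-bin input rate (clicks per bin divided by the bin
width, optionally reduced by short-term depression) and ``tau`` is the
exponential filter width.  Between clicks the DV relaxes toward zero; with a
steady 60 Hz train it fluctuates around 60 Hz.  Detection is a first passage
through a sticky (absorbing) bound, with bounds switched off for the first
0.8 s of the trial, and the reported response time adds a Gaussian
non-decision time.

The propagator advances a discretized DV distribution with the *exact*
one-step OU transition (Gaussian with mean ``alpha a + (1 - alpha) c tau``
and variance ``sigma^2 tau (1 - alpha^2) / 2``, ``alpha = exp(-dt/tau)``)
rather than a finite-difference approximation of the Fokker-Planck
operator; cell masses are reassigned by integrating that Gaussian over
destination cells, which conserves probability to machine precision.
Within-step bound crossings are resolved with a Brownian-bridge correction
so crossing probabilities have continuous-time semantics and converge to
fine-step Monte-Carlo simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import ndtr

from ._kernels import propagate_batch
from .params import BASELINE_RATE, ModelParams, ParameterError, SolverConfig

__all__ = [
    "DVGrid",
    "RTDist",
    "CrossingResult",
    "click_drive",
    "fp_step",
    "run_trial",
    "apply_ndt",
    "joint_rt",
    "trial_loglik",
    "dataset_loglik",
    "TrialBatch",
    "ProcessEngine",
]

# minimum step-kernel width, as a fraction of the grid spacing; keeps the
# deposit smooth (and the mean accurate) when sigma_process * sqrt(dt) is
# smaller than a grid cell
_MIN_KERNEL_CELLS = 0.35


class ConsistencyError(RuntimeError):
    """Internal solver check failed (probability not conserved)."""


@dataclass
class DVGrid:
    """Discretized DV distribution: interior mass plus absorbed mass."""

    values: np.ndarray        # (N,) cell centers, Hz, uniform spacing
    mass: np.ndarray          # (N,) probability mass per cell
    absorbed_up: float = 0.0
    absorbed_down: float = 0.0

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def total(self) -> float:
        return float(self.mass.sum() + self.absorbed_up + self.absorbed_down)

    def mean(self) -> float:
        m = self.mass.sum()
        return float((self.values * self.mass).sum() / m)

    def var(self) -> float:
        m = self.mass.sum()
        mu = (self.values * self.mass).sum() / m
        return float(((self.values - mu) ** 2 * self.mass).sum() / m)

    def check(self, tol: float = 1e-6) -> None:
        if abs(self.total() - 1.0) > tol:
            raise ConsistencyError(
                f"probability not conserved: total = {self.total():.9f}"
            )


@dataclass
class RTDist:
    """Response-time densities on the propagation time grid.

    ``t`` holds bin centers measured from stimulus onset.  The per-direction
    arrays are probability mass per bin; together with ``miss_mass`` they sum
    to one.  The axis extends past the trial end so that non-decision-time
    mass shifted beyond the stimulus is still accounted for.
    """

    t: np.ndarray
    density_up: Optional[np.ndarray]
    density_down: Optional[np.ndarray]
    miss_mass: float

    def total(self) -> float:
        s = self.miss_mass
        if self.density_up is not None:
            s += self.density_up.sum()
        if self.density_down is not None:
            s += self.density_down.sum()
        return float(s)


@dataclass
class CrossingResult:
    """Bound-crossing mass per time bin, before the non-decision time."""

    t: np.ndarray                       # bin centers from stimulus onset
    cross_up: Optional[np.ndarray]
    cross_down: Optional[np.ndarray]
    survival: np.ndarray                # interior mass after each bin
    survival_end: float


# ---------------------------------------------------------------------------
# click input


def click_drive(
    clicks: np.ndarray,
    max_time: float,
    params: ModelParams,
    dt: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin a click train and return (effective counts, drive in Hz) per bin.

    Without depression each click contributes exactly one unit to its bin's
    count.  With depression a click contributes the current adaptation
    state; immediately afterwards the state is multiplied by ``dep_scale``
    and then relaxes toward 1 with time constant ``dep_tau``.  The drive is
    the effective click rate ``C / dt`` in Hz, the fixed point toward which
    the DV relaxes during the bin.
    """
    clicks = np.asarray(clicks, dtype=float)
    if clicks.size > 1 and np.any(np.diff(clicks) < 0):
        raise ValueError("click times must be sorted")
    n_bins = int(np.ceil(max_time / dt - 1e-9))
    n_bins = max(n_bins, 1)
    counts = np.zeros(n_bins)
    if clicks.size:
        mags = np.ones(clicks.size)
        if params.depression_enabled:
            mags = _depressed_magnitudes(clicks, params.dep_scale, params.dep_tau)
        idx = np.minimum((clicks / dt).astype(np.int64), n_bins - 1)
        np.add.at(counts, idx, mags)
    return counts, counts / dt


def _depressed_magnitudes(clicks: np.ndarray, scale: float, tau_rec: float) -> np.ndarray:
    mags = np.empty(clicks.size)
    state = 1.0
    t_prev = None
    for i, t in enumerate(clicks):
        if t_prev is not None:
            state = 1.0 - (1.0 - state) * np.exp(-(t - t_prev) / tau_rec)
        mags[i] = state
        state *= scale
        t_prev = t
    return mags


# ---------------------------------------------------------------------------
# grid and one-step transition stencils


def build_grid(
    params: ModelParams,
    solver: SolverConfig,
    baseline: float = BASELINE_RATE,
) -> np.ndarray:
    """Uniform DV grid covering the origin, the bounds, and the range of
    filtered click rates the task can produce.

    The DV is a filtered click-rate estimate, so its mean path lives
    between 0 Hz and roughly twice the baseline (the largest post-change
    rate), with diffusive spread set by the stationary SD
    ``sigma sqrt(tau/2)``.  The grid pads both ends by several stationary
    SDs; mass that would leave the grid on an unbounded side is lumped at
    the edge cell (an effective reflection far from the region that
    matters, the neighborhood of the bound).
    """
    sig_stat = params.sigma_process * np.sqrt(params.tau / 2.0)
    pad = 4.0 * max(sig_stat, 3.0) + 5.0
    lo_anchor = 0.0 if params.bound_down is None else min(0.0, params.bound_down)
    hi_anchor = 2.0 * baseline
    if params.bound_up is not None:
        hi_anchor = max(hi_anchor, params.bound_up)
    return np.linspace(lo_anchor - pad, hi_anchor + pad, solver.n_grid)


def _step_stencils(
    grid: np.ndarray,
    params: ModelParams,
    dt: float,
    fixed_points: np.ndarray,
    active: bool,
):
    """Precompute one-step deposit stencils for each input level.

    For a source at grid point ``a`` and input fixed point ``f`` (Hz) the
    one-step law is Gaussian with mean ``alpha a + (1-alpha) f`` and SD
    ``s``.  Cell masses are Gaussian integrals over destination cells
    (clipped at active bounds); a Brownian-bridge factor moves the
    within-step crossing probability of each surviving path into the
    absorbed taps.  Tail mass beyond the stencil window or the grid edge is
    lumped into the outermost cell, which approximates reflection at the
    (far, negligible-mass) grid edges.

    Returns (K, lo, a_up, a_dn) with shapes (nq, N, L), (nq, N), (nq, N),
    (nq, N).
    """
    N = grid.size
    h = float(grid[1] - grid[0])
    tau, sigma = params.tau, params.sigma_process
    alpha = np.exp(-dt / tau)
    s_true = sigma * np.sqrt(tau * (1.0 - alpha**2) / 2.0)
    s = max(s_true, _MIN_KERNEL_CELLS * h)
    half = 4.5 * s
    L = 2 * int(np.ceil(half / h)) + 3
    # pad to the propagation kernel's unrolled widths (zero taps are free)
    if L <= 8:
        L = 8
    elif L <= 16:
        L = 16
    L = min(L, N)
    nq = len(fixed_points)

    b_up = params.bound_up if (active and params.bound_up is not None) else np.inf
    b_dn = params.bound_down if (active and params.bound_down is not None) else -np.inf

    K = np.zeros((nq, N, L))
    lo_idx = np.zeros((nq, N), dtype=np.int32)
    A_up = np.zeros((nq, N))
    A_dn = np.zeros((nq, N))

    src = grid  # (N,)
    lo_edge = grid[0] - 0.5 * h
    for iq, f in enumerate(fixed_points):
        mu = alpha * src + (1.0 - alpha) * f          # (N,)
        ctr = np.round((mu - grid[0]) / h).astype(np.int64)
        lo = np.clip(ctr - (L - 1) // 2, 0, N - L)    # (N,)
        lo_idx[iq] = lo.astype(np.int32)
        # destination cell edges for each source: (N, L+1)
        offs = np.arange(L + 1)
        edges = lo_edge + (lo[:, None] + offs[None, :]) * h
        # integration limits clipped at active bounds
        lo_lim = np.maximum(edges[:, :-1], b_dn)
        hi_lim = np.minimum(edges[:, 1:], b_up)
        z_hi = ndtr((hi_lim - mu[:, None]) / s)
        z_lo = ndtr((lo_lim - mu[:, None]) / s)
        w = np.clip(z_hi - z_lo, 0.0, None)           # (N, L)
        # endpoint mass beyond the bounds
        a_up = 1.0 - ndtr((b_up - mu) / s) if np.isfinite(b_up) else np.zeros(N)
        a_dn = ndtr((b_dn - mu) / s) if np.isfinite(b_dn) else np.zeros(N)
        # tail mass inside the bounds but beyond the stencil window: lump
        # into the outermost window cells
        low_cut = np.maximum(edges[:, 0], b_dn)
        hi_cut = np.minimum(edges[:, -1], b_up)
        w[:, 0] += np.clip(
            ndtr((low_cut - mu) / s) - (ndtr((b_dn - mu) / s) if np.isfinite(b_dn) else 0.0),
            0.0,
            None,
        )
        w[:, -1] += np.clip(
            (1.0 - ndtr((hi_cut - mu) / s))
            - (a_up if np.isfinite(b_up) else 0.0),
            0.0,
            None,
        )
        if active and s_true > 0.0:
            centers = 0.5 * (edges[:, :-1] + edges[:, 1:])
            surv = np.ones_like(w)
            p_up = np.zeros_like(w)
            p_dn = np.zeros_like(w)
            if np.isfinite(b_up):
                g0 = np.clip(b_up - src, 0.0, None)[:, None]
                g1 = np.clip(b_up - centers, 0.0, None)
                p_up = np.exp(-2.0 * g0 * g1 / (s_true * s_true))
            if np.isfinite(b_dn):
                g0 = np.clip(src - b_dn, 0.0, None)[:, None]
                g1 = np.clip(centers - b_dn, 0.0, None)
                p_dn = np.exp(-2.0 * g0 * g1 / (s_true * s_true))
            surv = (1.0 - p_up) * (1.0 - p_dn)
            tot_cross = w * (1.0 - surv)
            denom = p_up + p_dn
            with np.errstate(invalid="ignore", divide="ignore"):
                frac_up = np.where(denom > 0, p_up / np.maximum(denom, 1e-300), 0.0)
            a_up = a_up + (tot_cross * frac_up).sum(axis=1)
            a_dn = a_dn + (tot_cross * (1.0 - frac_up)).sum(axis=1)
            w = w * surv
        A_up[iq] = a_up
        A_dn[iq] = a_dn
        K[iq] = w
    return K, lo_idx, A_up, A_dn


def _activation_fractions(grid: np.ndarray, params: ModelParams):
    """Per-cell (kept, absorbed-up) fractions when bounds switch on."""
    h = float(grid[1] - grid[0])
    edges_lo = grid - 0.5 * h
    edges_hi = grid + 0.5 * h
    b_up = params.bound_up if params.bound_up is not None else np.inf
    b_dn = params.bound_down if params.bound_down is not None else -np.inf
    keep = (np.minimum(edges_hi, b_up) - np.maximum(edges_lo, b_dn)).clip(0.0, h) / h
    up = (edges_hi - np.maximum(edges_lo, b_up)).clip(0.0, h) / h
    return keep, up


def initial_mass(grid: np.ndarray, start: float = 0.0) -> np.ndarray:
    """Point mass at ``start`` split between the two neighboring cells."""
    h = float(grid[1] - grid[0])
    p = np.zeros(grid.size)
    x = (start - grid[0]) / h
    i = int(np.clip(np.floor(x), 0, grid.size - 2))
    frac = x - i
    p[i] = 1.0 - frac
    p[i + 1] = frac
    return p


# ---------------------------------------------------------------------------
# reference single-step propagation (used by tests and small studies; the
# batched numba path below is the workhorse for fitting)


def fp_step(
    state: DVGrid,
    drive: float,
    dt: float,
    params: ModelParams,
    bounds_active: bool,
) -> DVGrid:
    """One propagation step of the OU law at input rate ``drive`` (Hz)."""
    grid = state.values
    K, lo, a_up, a_dn = _step_stencils(
        grid, params, dt, np.array([drive], dtype=float), bounds_active
    )
    N, L = grid.size, K.shape[2]
    out = np.zeros(N)
    for i in np.nonzero(state.mass)[0]:
        w = state.mass[i]
        out[lo[0, i] : lo[0, i] + L] += w * K[0, i]
    new = DVGrid(
        values=grid,
        mass=out,
        absorbed_up=state.absorbed_up + float(state.mass @ a_up[0]),
        absorbed_down=state.absorbed_down + float(state.mass @ a_dn[0]),
    )
    new.check(1e-6)
    return new


def run_trial(
    clicks: np.ndarray,
    max_time: float,
    params: ModelParams,
    mode: str = "auto",
    solver: SolverConfig | None = None,
) -> CrossingResult:
    """Propagate one trial and return bound-crossing densities + survival.

    ``mode`` selects the bound structure: ``increase_only``,
    ``decrease_only``, or ``both`` (two independent single-bound processes
    combined at the level of crossing densities; see :func:`joint_rt`).
    ``auto`` infers the mode from which bounds the parameter set carries.
    """
    solver = (solver or SolverConfig()).validate()
    if max_time < solver.pre_bound_time:
        raise ValueError("trial must extend past the bound-free segment")
    if mode == "auto":
        if params.bound_up is not None and params.bound_down is not None:
            mode = "both"
        elif params.bound_up is not None:
            mode = "increase_only"
        else:
            mode = "decrease_only"
    if mode == "both":
        if params.bound_down is not None and params.bound_up is not None:
            if params.bound_down >= params.bound_up:
                raise ParameterError("bound_down must lie below bound_up")
        up = run_trial(clicks, max_time, _single(params, "up"), "increase_only", solver)
        dn = run_trial(clicks, max_time, _single(params, "down"), "decrease_only", solver)
        surv = up.survival * dn.survival
        return CrossingResult(
            t=up.t,
            cross_up=up.cross_up,
            cross_down=dn.cross_down,
            survival=surv,
            survival_end=float(up.survival_end * dn.survival_end),
        )
    side = "up" if mode == "increase_only" else "down"
    p = _single(params, side)
    p.validate()
    batch = TrialBatch([np.asarray(clicks, float)], [max_time], p, solver)
    engine = ProcessEngine(batch, solver)
    cross, surv, surv_end = engine.crossing(p)
    t = (np.arange(batch.max_steps) + 0.5) * solver.dt
    return CrossingResult(
        t=t,
        cross_up=cross[0] if side == "up" else None,
        cross_down=cross[0] if side == "down" else None,
        survival=surv[0],
        survival_end=float(surv_end[0]),
    )


def _single(params: ModelParams, side: str) -> ModelParams:
    d = params.to_dict()
    if side == "up":
        d["bound_down"] = None
    else:
        d["bound_up"] = None
    return ModelParams(**d)


# ---------------------------------------------------------------------------
# non-decision time and joint two-process distributions


def ndt_kernel(params: ModelParams, solver: SolverConfig) -> tuple[np.ndarray, int]:
    """Discretized Gaussian NDT filter: (weights, first offset bin).

    Supported on ``max(0, mu - 5 sd) .. mu + 5 sd``; the (unphysical)
    negative-latency tail and the far positive tail are lumped into the end
    taps so the filter sums to one exactly.
    """
    dt = solver.dt
    mu, sd = params.ndt_mean, params.ndt_sd
    j0 = max(0, int(np.floor((mu - solver.ndt_halfwidth_sd * sd) / dt)))
    j1 = int(np.ceil((mu + solver.ndt_halfwidth_sd * sd) / dt))
    edges = (np.arange(j0, j1 + 2) - 0.5) * dt
    cdf = ndtr((edges - mu) / sd)
    w = np.diff(cdf)
    w[0] += cdf[0]
    w[-1] += 1.0 - cdf[-1]
    return w, j0


def apply_ndt(
    crossing: np.ndarray,
    params: ModelParams,
    solver: SolverConfig | None = None,
) -> np.ndarray:
    """Convolve a bound-crossing density with the Gaussian NDT filter.

    Returns a density on an extended time axis (length ``len(crossing) +
    last kernel offset``); total mass is conserved to machine precision.
    """
    solver = solver or SolverConfig()
    w, j0 = ndt_kernel(params, solver)
    out = np.zeros(len(crossing) + j0 + len(w) - 1)
    full = np.convolve(crossing, w)
    out[j0 : j0 + len(full)] = full
    return out


def joint_rt(
    cross_up: np.ndarray,
    surv_up: np.ndarray,
    cross_down: np.ndarray,
    surv_down: np.ndarray,
    params: ModelParams,
    solver: SolverConfig | None = None,
) -> RTDist:
    """Combine two independent single-bound processes into per-direction
    response densities, then apply the non-decision time.

    The probability of an "increase" response in bin k is the upper
    process's crossing mass times the probability the lower process has not
    yet crossed, with the (tiny) same-bin double-crossing mass split evenly;
    this attribution telescopes exactly, so the two densities plus the joint
    survival sum to one.
    """
    solver = solver or SolverConfig()
    if cross_up.shape != cross_down.shape:
        raise ValueError("the two processes must share one time grid")
    s_up_prev = np.concatenate(([1.0], surv_up[:-1]))
    s_dn_prev = np.concatenate(([1.0], surv_down[:-1]))
    both = cross_up * cross_down
    d_up = cross_up * s_dn_prev - 0.5 * both
    d_dn = cross_down * s_up_prev - 0.5 * both
    miss = float(surv_up[-1] * surv_down[-1])
    dens_up = apply_ndt(d_up, params, solver)
    dens_dn = apply_ndt(d_dn, params, solver)
    t = (np.arange(len(dens_up)) + 0.5) * solver.dt
    return RTDist(t=t, density_up=dens_up, density_down=dens_dn, miss_mass=miss)


def single_rt(
    cross: np.ndarray,
    surv_end: float,
    params: ModelParams,
    side: str,
    solver: SolverConfig | None = None,
) -> RTDist:
    """RT distribution of a single-bound process after the NDT filter."""
    solver = solver or SolverConfig()
    dens = apply_ndt(cross, params, solver)
    t = (np.arange(len(dens)) + 0.5) * solver.dt
    if side == "up":
        return RTDist(t=t, density_up=dens, density_down=None, miss_mass=float(surv_end))
    return RTDist(t=t, density_up=None, density_down=dens, miss_mass=float(surv_end))


# ---------------------------------------------------------------------------
# trial likelihood


def _window_bins(rt: float, dt: float, half: float) -> tuple[int, int]:
    """Bin range [k0, k1] whose centers fall within ``rt +- half``."""
    k0 = int(np.ceil((rt - half) / dt - 0.5 - 1e-9))
    k1 = int(np.floor((rt + half) / dt - 0.5 + 1e-9))
    return max(k0, 0), k1


def trial_loglik(
    rtdist: RTDist,
    outcome: str,
    response_time: Optional[float],
    reported_dir: Optional[str],
    solver: SolverConfig | None = None,
    max_time: Optional[float] = None,
) -> float:
    """Log-likelihood of one behavioral record under an RT distribution.

    Response trials (hits and false alarms) sum the direction-matched
    density in a 0.2 s window centered on the response time (measured from
    stimulus onset); misses use the probability that no response registered
    by trial end — the un-crossed interior mass plus, when ``max_time`` is
    given, crossing mass whose non-decision time lands past the stimulus
    end.  A floor of 1e-10 keeps the result finite.
    """
    solver = solver or SolverConfig()
    if outcome not in ("hit", "false_alarm", "miss"):
        raise ValueError(f"outcome {outcome!r} is excluded from the likelihood")
    if outcome == "miss":
        p = rtdist.miss_mass
        if max_time is not None:
            reg = 0.0
            sel = rtdist.t <= max_time + 1e-9
            for dens in (rtdist.density_up, rtdist.density_down):
                if dens is not None:
                    reg += float(dens[sel].sum())
            p = max(1.0 - reg, 0.0)
        return float(np.log(max(p, solver.likelihood_floor)))
    if response_time is None:
        raise ValueError("response trials need a response time")
    dens = rtdist.density_up if reported_dir == "increase" else rtdist.density_down
    if dens is None:
        raise ValueError(f"model has no process for direction {reported_dir!r}")
    k0, k1 = _window_bins(response_time, solver.dt, solver.likelihood_window)
    k1 = min(k1, len(dens) - 1)
    p = float(dens[k0 : k1 + 1].sum()) if k1 >= k0 else 0.0
    return float(np.log(max(p, solver.likelihood_floor)))


# ---------------------------------------------------------------------------
# batched propagation over many trials


class TrialBatch:
    """Click trains of many trials preprocessed for batched propagation.

    Per-bin effective click counts are quantized to multiples of
    ``solver.dep_quantum`` (exact for undepressed integer counts) so that
    all trials share a small set of one-step transition stencils.
    """

    def __init__(self, clicks_list, max_times, params: ModelParams,
                 solver: SolverConfig, response_times=None):
        self.solver = solver
        dt = solver.dt
        n = len(clicks_list)
        if n == 0:
            raise ValueError("empty trial batch")
        steps = np.array(
            [max(int(np.ceil(mt / dt - 1e-9)), 1) for mt in max_times],
            dtype=np.int64,
        )
        if response_times is not None:
            # propagation past the response is not needed for the window
            # likelihood; 0.4 s of slack covers the NDT filter support
            slack = int(np.ceil(0.4 / dt))
            for i, rt in enumerate(response_times):
                if rt is not None and np.isfinite(rt):
                    k = int(np.ceil(rt / dt)) + slack
                    steps[i] = min(steps[i], max(k, 1))
        self.n_steps = steps.astype(np.int32)
        self.max_steps = int(steps.max())
        q = solver.dep_quantum if params.depression_enabled else 1.0
        levels: dict[int, int] = {}
        qidx = np.zeros((n, self.max_steps), dtype=np.int16)
        for i, (cl, mt) in enumerate(zip(clicks_list, max_times)):
            counts, _ = click_drive(cl, mt, params, dt)
            m = np.round(counts / q).astype(np.int64)
            for k in range(min(len(m), self.n_steps[i])):
                lv = int(m[k])
                if lv not in levels:
                    levels[lv] = len(levels)
                qidx[i, k] = levels[lv]
        self.q_idx = qidx
        self.level_values = np.array(sorted(levels, key=levels.get), dtype=float) * q
        self.dep_key = (params.depression_enabled, params.dep_scale, params.dep_tau)

    def fixed_points(self) -> np.ndarray:
        """Input rate (Hz) for each stencil level."""
        return self.level_values / self.solver.dt


class ProcessEngine:
    """Crossing densities of one single-bound process across a TrialBatch."""

    def __init__(self, batch: TrialBatch, solver: SolverConfig | None = None):
        self.batch = batch
        self.solver = solver or batch.solver

    def crossing(self, params: ModelParams):
        """Return (cross, surv, surv_end) for every trial in the batch.

        ``cross`` is the (n_trials, max_steps) bound-crossing mass per bin
        for whichever single bound ``params`` carries.
        """
        params.validate()
        if (params.bound_up is None) == (params.bound_down is None):
            raise ParameterError("ProcessEngine expects exactly one bound")
        if self.batch.dep_key != (
            params.depression_enabled, params.dep_scale, params.dep_tau
        ):
            raise ParameterError("batch was preprocessed with other depression settings")
        solver = self.solver
        nsub = solver.n_substeps
        grid = build_grid(params, solver)
        fps = self.batch.fixed_points()
        dt_sub = solver.dt / nsub
        k_free, lo_free, _, _ = _step_stencils(grid, params, dt_sub, fps, False)
        k_abs, lo_abs, a_up, a_dn = _step_stencils(grid, params, dt_sub, fps, True)
        keep, up = _activation_fractions(grid, params)
        act_step = int(round(solver.pre_bound_time / dt_sub))
        p0 = initial_mass(grid, 0.0)
        if nsub == 1:
            q_idx, n_steps = self.batch.q_idx, self.batch.n_steps
        else:
            q_idx = np.repeat(self.batch.q_idx, nsub, axis=1)
            n_steps = (self.batch.n_steps * nsub).astype(np.int32)
        cu, cd, surv, surv_end = propagate_batch(
            p0, q_idx, n_steps, act_step,
            k_free, lo_free, k_abs, lo_abs, a_up, a_dn, keep, up,
        )
        if nsub > 1:
            n, T = self.batch.q_idx.shape
            cu = cu.reshape(n, T, nsub).sum(axis=2)
            cd = cd.reshape(n, T, nsub).sum(axis=2)
            surv = surv.reshape(n, T, nsub)[:, :, -1]
        cross = cu if params.bound_up is not None else cd
        return cross, surv, surv_end


# ---------------------------------------------------------------------------
# dataset likelihood


def _cumsum_window(dens: np.ndarray, k0: np.ndarray, k1: np.ndarray) -> np.ndarray:
    """Row-wise sums dens[i, k0[i]..k1[i]] via cumulative sums."""
    c = np.cumsum(dens, axis=1)
    n = dens.shape[1]
    k1c = np.minimum(k1, n - 1)
    hi = c[np.arange(len(k0)), k1c]
    lo = np.where(k0 > 0, c[np.arange(len(k0)), np.maximum(k0 - 1, 0)], 0.0)
    out = hi - lo
    out[k1 < k0] = 0.0
    return out


def _convolve_ndt(cross: np.ndarray, params: ModelParams, solver: SolverConfig) -> np.ndarray:
    from scipy.signal import fftconvolve

    w, j0 = ndt_kernel(params, solver)
    full = fftconvolve(cross, w[None, :], axes=1)
    if j0:
        full = np.pad(full, ((0, 0), (j0, 0)))
    return full


def _late_response_mass(
    cross: np.ndarray,
    max_times: np.ndarray,
    params: ModelParams,
    solver: SolverConfig,
) -> np.ndarray:
    """Crossing mass whose response (crossing + NDT) lands after trial end.

    A bound crossing whose motor response would register only after the
    stimulus has ended produces no observable response — behaviorally a
    miss.  For each trial this is sum_k cross[k] * P(NDT > max_time - t_k)
    under the Gaussian non-decision time.
    """
    t = (np.arange(cross.shape[1]) + 0.5) * solver.dt
    z = (max_times[:, None] - t[None, :] - params.ndt_mean) / params.ndt_sd
    return (cross * (1.0 - ndtr(z))).sum(axis=1)


def loglik_single(
    cross: np.ndarray,
    surv_end: np.ndarray,
    params: ModelParams,
    outcomes: np.ndarray,
    response_times: np.ndarray,
    solver: SolverConfig,
    max_times: Optional[np.ndarray] = None,
) -> float:
    """Summed log-likelihood for a single-bound model.

    ``outcomes`` is an int8 array: 0 = miss, 1 = cue-consistent response
    (hit or false alarm).  Response times are measured from stimulus onset.
    The miss probability is the mass that produced no registered response:
    interior survival plus crossings whose non-decision time lands past the
    end of the stimulus (see docs/methods.md).
    """
    ll = 0.0
    floor = solver.likelihood_floor
    miss = outcomes == 0
    if miss.any():
        p_miss = surv_end[miss].copy()
        if max_times is not None:
            p_miss += _late_response_mass(cross[miss], max_times[miss], params, solver)
        ll += np.log(np.maximum(p_miss, floor)).sum()
    resp = ~miss
    if resp.any():
        dens = _convolve_ndt(cross[resp], params, solver)
        rts = response_times[resp]
        k0 = np.ceil((rts - solver.likelihood_window) / solver.dt - 0.5 - 1e-9).astype(int)
        k1 = np.floor((rts + solver.likelihood_window) / solver.dt - 0.5 + 1e-9).astype(int)
        k0 = np.maximum(k0, 0)
        p = _cumsum_window(dens, k0, k1)
        ll += np.log(np.maximum(p, floor)).sum()
    return float(ll)


def loglik_joint(
    cross_up: np.ndarray,
    surv_up: np.ndarray,
    cross_dn: np.ndarray,
    surv_dn: np.ndarray,
    ndt_params: ModelParams,
    outcomes: np.ndarray,
    response_times: np.ndarray,
    reported_up: np.ndarray,
    solver: SolverConfig,
    max_times: Optional[np.ndarray] = None,
) -> float:
    """Summed log-likelihood for the two-process (uninformed) model.

    ``outcomes``: 0 = miss, 1 = response; ``reported_up`` flags responses
    attributed to the increase process.  As in :func:`loglik_single`, the
    miss probability includes first crossings whose response would land
    past trial end.
    """
    ll = 0.0
    floor = solver.likelihood_floor
    miss = outcomes == 0
    s_up_prev = np.concatenate((np.ones((len(surv_up), 1)), surv_up[:, :-1]), axis=1)
    s_dn_prev = np.concatenate((np.ones((len(surv_dn), 1)), surv_dn[:, :-1]), axis=1)
    both = cross_up * cross_dn
    d_up = cross_up * s_dn_prev - 0.5 * both
    d_dn = cross_dn * s_up_prev - 0.5 * both
    if miss.any():
        # miss trials always propagate to trial end, so the trailing
        # survival column is end-of-trial survival
        joint_surv = surv_up[miss, -1] * surv_dn[miss, -1]
        p_miss = joint_surv
        if max_times is not None:
            p_miss = p_miss + _late_response_mass(
                d_up[miss] + d_dn[miss], max_times[miss], ndt_params, solver
            )
        ll += np.log(np.maximum(p_miss, floor)).sum()
    resp = ~miss
    if resp.any():
        d_up = d_up[resp]
        d_dn = d_dn[resp]
        rts = response_times[resp]
        k0 = np.ceil((rts - solver.likelihood_window) / solver.dt - 0.5 - 1e-9).astype(int)
        k1 = np.floor((rts + solver.likelihood_window) / solver.dt - 0.5 + 1e-9).astype(int)
        k0 = np.maximum(k0, 0)
        up_mask = reported_up[resp]
        dens_up = _convolve_ndt(d_up[up_mask], ndt_params, solver) if up_mask.any() else None
        dens_dn = _convolve_ndt(d_dn[~up_mask], ndt_params, solver) if (~up_mask).any() else None
        p = np.empty(resp.sum())
        if dens_up is not None:
            p[up_mask] = _cumsum_window(dens_up, k0[up_mask], k1[up_mask])
        if dens_dn is not None:
            p[~up_mask] = _cumsum_window(dens_dn, k0[~up_mask], k1[~up_mask])
        ll += np.log(np.maximum(p, floor)).sum()
    return float(ll)


def dataset_loglik(
    dataset,
    params_by_condition: dict,
    solver: SolverConfig | None = None,
) -> float:
    """Total log-likelihood of a behavioral dataset.

    ``params_by_condition`` maps ``informed_increase`` / ``informed_decrease``
    to single-bound ModelParams and ``uninformed`` to a pair
    ``(params_increase, params_decrease)`` of single-bound ModelParams whose
    NDT fields must agree (the combined response uses one motor delay).
    Trials with excluded outcomes (early, opposite-cue, wrong-direction) are
    rejected; every includable trial must map to a model.
    """
    from .fitting import condition_arrays  # local import to avoid a cycle

    solver = (solver or SolverConfig()).validate()
    total = 0.0
    for cond, arrs in condition_arrays(dataset).items():
        if cond == "uninformed":
            if "uninformed" not in params_by_condition:
                raise ValueError("no model mapped to uninformed trials")
            p_up, p_dn = params_by_condition["uninformed"]
            if (p_up.ndt_mean, p_up.ndt_sd) != (p_dn.ndt_mean, p_dn.ndt_sd):
                raise ParameterError("joint model needs one shared NDT")
            batch = TrialBatch(
                arrs["clicks"], arrs["max_time"], p_up, solver,
                response_times=arrs["response_time"],
            )
            eng = ProcessEngine(batch, solver)
            cu, su, se_u = eng.crossing(p_up)
            cd, sd, se_d = eng.crossing(p_dn)
            su[:, -1] = se_u  # ensure final column is trial-end survival
            sd[:, -1] = se_d
            total += loglik_joint(
                cu, su, cd, sd, p_up, arrs["outcome_code"],
                arrs["response_time"], arrs["reported_up"], solver,
                max_times=arrs["max_time"],
            )
        else:
            if cond not in params_by_condition:
                raise ValueError(f"no model mapped to {cond} trials")
            p = params_by_condition[cond]
            batch = TrialBatch(
                arrs["clicks"], arrs["max_time"], p, solver,
                response_times=arrs["response_time"],
            )
            eng = ProcessEngine(batch, solver)
            cross, _, surv_end = eng.crossing(p)
            total += loglik_single(
                cross, surv_end, p, arrs["outcome_code"],
                arrs["response_time"], solver, max_times=arrs["max_time"],
            )
    return total
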