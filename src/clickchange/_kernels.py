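"""Numba inner loops: batched Fokker-Planck propagation and the
Euler-Maruyama observer simulation.

The propagation kernel advances the decision-variable distribution one
0.02 s bin at a time using precomputed one-step transition stencils, one
stencil set per distinct (quantized) click count.  Each stencil row i holds
the discretized exact OU one-step Gaussian for a source at grid point i,
with Brownian-bridge within-step crossing folded into the absorbed taps so
that bound crossing has continuous-time semantics.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def propagate_batch(
    p0,            # (N,) initial interior mass (sums to 1)
    q_idx,         # (n_trials, max_steps) int16 stencil index per bin, -1 pad
    n_steps,       # (n_trials,) int32 number of bins to propagate
    act_step,      # int: first bin index with active bounds
    k_free,        # (nq, N, L) deposit stencils, bounds inactive
    lo_free,       # (nq, N) int32 first destination cell of each stencil row
    k_abs,         # (nq, N, L) deposit stencils, bounds active
    lo_abs,        # (nq, N)
    a_up,          # (nq, N) mass absorbed at the upper bound per unit source
    a_dn,          # (nq, N)
    act_keep,      # (N,) fraction of each cell kept at bound activation
    act_up,        # (N,) fraction absorbed upward at activation
):
    """Propagate every trial; return per-bin crossing mass and survival.

    Returns (cross_up, cross_dn, surv, surv_end): crossing arrays are
    (n_trials, max_steps); surv[t, k] is the interior mass after bin k.
    """
    n_trials, max_steps = q_idx.shape
    N = p0.shape[0]
    L = k_free.shape[2]
    cross_up = np.zeros((n_trials, max_steps))
    cross_dn = np.zeros((n_trials, max_steps))
    surv = np.ones((n_trials, max_steps))
    surv_end = np.ones(n_trials)
    p = np.zeros(N)
    out = np.zeros(N)
    zero_a = np.zeros(N)
    # initial support of the distribution
    s0 = 0
    while s0 < N - 1 and p0[s0] == 0.0:
        s0 += 1
    s1 = N - 1
    while s1 > 0 and p0[s1] == 0.0:
        s1 -= 1
    for t in range(n_trials):
        # ping-pong between the two buffers to avoid copying
        buf_a = p
        buf_b = out
        for i in range(s0, s1 + 1):
            buf_a[i] = p0[i]
        lo_sup = s0
        hi_sup = s1
        au = 0.0
        ad = 0.0
        for k in range(n_steps[t]):
            au_prev = au
            ad_prev = ad
            if k == act_step:
                # bounds switch on: mass already beyond them is absorbed
                # (and counted as crossing mass in this bin)
                for i in range(lo_sup, hi_sup + 1):
                    w = buf_a[i]
                    if w > 0.0:
                        au += w * act_up[i]
                        ad += w * (1.0 - act_keep[i] - act_up[i])
                        buf_a[i] = w * act_keep[i]
            q = q_idx[t, k]
            au_new = au
            ad_new = ad
            active = k >= act_step
            if active:
                kq = k_abs[q]
                loq = lo_abs[q]
                auq = a_up[q]
                adq = a_dn[q]
            else:
                kq = k_free[q]
                loq = lo_free[q]
                auq = zero_a
                adq = zero_a
            new_lo = loq[lo_sup]
            new_hi = loq[hi_sup] + L - 1
            for i in range(new_lo, new_hi + 1):
                buf_b[i] = 0.0
            # statically unrolled deposit bodies: the fixed-width forms
            # vectorize, the generic loop handles any other stencil width
            if L == 8:
                for i in range(lo_sup, hi_sup + 1):
                    w = buf_a[i]
                    if w > 0.0:
                        lo = loq[i]
                        row = kq[i]
                        buf_b[lo] += w * row[0]
                        buf_b[lo + 1] += w * row[1]
                        buf_b[lo + 2] += w * row[2]
                        buf_b[lo + 3] += w * row[3]
                        buf_b[lo + 4] += w * row[4]
                        buf_b[lo + 5] += w * row[5]
                        buf_b[lo + 6] += w * row[6]
                        buf_b[lo + 7] += w * row[7]
                        au_new += w * auq[i]
                        ad_new += w * adq[i]
            elif L == 16:
                for i in range(lo_sup, hi_sup + 1):
                    w = buf_a[i]
                    if w > 0.0:
                        lo = loq[i]
                        row = kq[i]
                        buf_b[lo] += w * row[0]
                        buf_b[lo + 1] += w * row[1]
                        buf_b[lo + 2] += w * row[2]
                        buf_b[lo + 3] += w * row[3]
                        buf_b[lo + 4] += w * row[4]
                        buf_b[lo + 5] += w * row[5]
                        buf_b[lo + 6] += w * row[6]
                        buf_b[lo + 7] += w * row[7]
                        buf_b[lo + 8] += w * row[8]
                        buf_b[lo + 9] += w * row[9]
                        buf_b[lo + 10] += w * row[10]
                        buf_b[lo + 11] += w * row[11]
                        buf_b[lo + 12] += w * row[12]
                        buf_b[lo + 13] += w * row[13]
                        buf_b[lo + 14] += w * row[14]
                        buf_b[lo + 15] += w * row[15]
                        au_new += w * auq[i]
                        ad_new += w * adq[i]
            else:
                for i in range(lo_sup, hi_sup + 1):
                    w = buf_a[i]
                    if w > 0.0:
                        lo = loq[i]
                        row = kq[i]
                        for j in range(L):
                            buf_b[lo + j] += w * row[j]
                        au_new += w * auq[i]
                        ad_new += w * adq[i]
            cross_up[t, k] = au_new - au_prev
            cross_dn[t, k] = ad_new - ad_prev
            au = au_new
            ad = ad_new
            tmp = buf_a
            buf_a = buf_b
            buf_b = tmp
            lo_sup = new_lo
            hi_sup = new_hi
            surv[t, k] = 1.0 - au - ad
        surv_end[t] = 1.0 - au - ad
        # scrub the final buffer so the next trial starts clean
        for i in range(lo_sup, hi_sup + 1):
            buf_a[i] = 0.0
        if n_steps[t] < max_steps:
            for k in range(n_steps[t], max_steps):
                surv[t, k] = surv_end[t]
    return cross_up, cross_dn, surv, surv_end


@njit(cache=True)
def simulate_paths(
    drive_sub,     # (n_steps,) effective clicks per simulation substep
    n_paths,
    t_max,
    sim_dt,
    tau,
    sigma,
    bound_up,      # use +inf / -inf for an absent bound
    bound_dn,
    t_act,         # bounds inactive before this time
    noise,         # (n_paths, n_steps) standard normal draws
    bridge_u,      # (n_paths, n_steps) uniform draws for bridge crossings
):
    """Euler-Maruyama paths of one OU process on one (pre-binned) drive.

    ``drive_sub`` holds the effective click count attributed to each
    simulation substep — the model's 0.02 s input bins spread evenly over
    the finer simulation steps, matching the constant-within-bin drive the
    Fokker-Planck propagation uses.  Within-step boundary crossing is
    resolved with a Brownian-bridge test so that first-passage times have
    continuous-time semantics.  Returns (crossed, t_cross, direction):
    direction is +1 for the upper bound, -1 for the lower, 0 if never
    crossed by t_max.
    """
    n_steps = drive_sub.shape[0]
    sdt = sigma * np.sqrt(sim_dt)
    crossed = np.zeros(n_paths, dtype=np.bool_)
    t_cross = np.full(n_paths, np.nan)
    direction = np.zeros(n_paths, dtype=np.int8)
    for ip in range(n_paths):
        a = 0.0
        for k in range(n_steps):
            t1 = (k + 1) * sim_dt
            a_new = a + (drive_sub[k] / tau) - (a / tau) * sim_dt + sdt * noise[ip, k]
            if t1 > t_act:
                if a_new >= bound_up:
                    t_cross[ip] = t1
                    direction[ip] = 1
                    crossed[ip] = True
                    break
                if a_new <= bound_dn:
                    t_cross[ip] = t1
                    direction[ip] = -1
                    crossed[ip] = True
                    break
                # Brownian-bridge within-step crossing probabilities
                if sdt > 0.0:
                    gu = bound_up - a
                    gv = bound_up - a_new
                    if gu < 40.0 * sdt and gv < 40.0 * sdt:
                        if bridge_u[ip, k] < np.exp(-2.0 * gu * gv / (sdt * sdt)):
                            t_cross[ip] = t1
                            direction[ip] = 1
                            crossed[ip] = True
                            break
                    gu = a - bound_dn
                    gv = a_new - bound_dn
                    if gu < 40.0 * sdt and gv < 40.0 * sdt:
                        if bridge_u[ip, k] < np.exp(-2.0 * gu * gv / (sdt * sdt)):
                            t_cross[ip] = t1
                            direction[ip] = -1
                            crossed[ip] = True
                            break
            a = a_new
    return crossed, t_cross, direction
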