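"""Numba-compiled inner loop of the exact stochastic simulation.

The continuous-time Markov chain has four event types: resource inflow
(rate ``rho_k``), consumer death (``eta_i N_i``, with the speciation floor:
a death drawn for a species at abundance 1 leaves the state unchanged and
logs an extinction), and consumption of resource ``k`` by consumer ``i``
(total rate ``R_k C_ki N_i``), which always removes one resource unit and
with probability ``eps`` also adds one consumer.

Consumption events are selected resource-first (probability proportional to
``R_k (C N)_k``) then consumer (proportional to ``C_ki N_i``), which is
exactly equivalent to joint selection.  The per-resource weights
``cn_k = (C N)_k`` and per-category rate sums are maintained incrementally
(O(S + K) work per event) and recomputed from scratch periodically to keep
floating-point drift below resolution.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# events are encoded in the returned log as integers
EV_INFLOW = 0
EV_DEATH = 1
EV_CONS = 2  # consumption without birth
EV_BIRTH = 3  # consumption with birth

_RESYNC_EVERY = 1 << 20


@njit(cache=True)
def _searchsorted_weight(cum_w: np.ndarray, u: float) -> int:
    lo, hi = 0, cum_w.shape[0] - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if u < cum_w[mid]:
            hi = mid
        else:
            lo = mid + 1
    return lo


@njit(cache=True)
def _pick_linear(w: np.ndarray, target: float) -> int:
    """Index i with cumulative weight crossing ``target``; clamps to last."""
    acc = 0.0
    last = w.shape[0] - 1
    for i in range(last):
        acc += w[i]
        if target < acc:
            return i
    return last


@njit(cache=True)
def run_core(
    C: np.ndarray,  # (K, S) float64
    Ct: np.ndarray,  # (S, K) contiguous transpose of C
    rho: np.ndarray,  # (K,)
    eta: np.ndarray,  # (S,)
    eps: float,
    N0: np.ndarray,  # (S,) int64
    R0: np.ndarray,  # (K,) int64
    t_end: float,
    snap_times: np.ndarray,  # increasing, all <= t_end
    record_events: bool,
    seed: int,
):
    np.random.seed(seed)
    K, S = C.shape
    N = N0.copy()
    R = R0.copy()

    cn = np.zeros(K)
    for k in range(K):
        s = 0.0
        for i in range(S):
            s += C[k, i] * N[i]
        cn[k] = s
    death_w = eta * N
    cons_w = R * cn
    sum_inflow = rho.sum()
    sum_death = death_w.sum()
    sum_cons = cons_w.sum()
    cum_rho = np.cumsum(rho)

    n_snap = snap_times.shape[0]
    snapN = np.zeros((n_snap, S), dtype=np.int64)
    snapR = np.zeros((n_snap, K), dtype=np.int64)
    snap_idx = 0

    ext_cap = 1024
    ext_sp = np.empty(ext_cap, dtype=np.int64)
    ext_t = np.empty(ext_cap, dtype=np.float64)
    n_ext = 0

    if record_events:
        events = np.zeros((K, S), dtype=np.int64)
    else:
        events = np.zeros((1, 1), dtype=np.int64)

    n_birth = np.int64(0)
    n_cons = np.int64(0)
    t = 0.0
    steps = 0

    while t < t_end:
        total = sum_inflow + sum_death + sum_cons
        dt = np.random.exponential(1.0 / total)
        t_new = t + dt
        while snap_idx < n_snap and snap_times[snap_idx] <= t_new:
            for i in range(S):
                snapN[snap_idx, i] = N[i]
            for k in range(K):
                snapR[snap_idx, k] = R[k]
            snap_idx += 1
        t = t_new
        if t >= t_end:
            break

        u = np.random.random() * total
        if u < sum_inflow:
            k = _searchsorted_weight(cum_rho, u)
            R[k] += 1
            d = cn[k]
            cons_w[k] += d
            sum_cons += d
        elif u < sum_inflow + sum_death:
            i = _pick_linear(death_w, u - sum_inflow)
            if N[i] > 1:
                N[i] -= 1
                death_w[i] -= eta[i]
                sum_death -= eta[i]
                for k in range(K):
                    c = Ct[i, k]
                    cn[k] -= c
                    d = R[k] * c
                    cons_w[k] -= d
                    sum_cons -= d
            else:
                # speciation floor: abundance stays at 1, extinction logged
                if n_ext == ext_cap:
                    ext_cap *= 2
                    new_sp = np.empty(ext_cap, dtype=np.int64)
                    new_t = np.empty(ext_cap, dtype=np.float64)
                    new_sp[:n_ext] = ext_sp
                    new_t[:n_ext] = ext_t
                    ext_sp = new_sp
                    ext_t = new_t
                ext_sp[n_ext] = i
                ext_t[n_ext] = t
                n_ext += 1
        else:
            k = _pick_linear(cons_w, u - sum_inflow - sum_death)
            # consumer i with probability proportional to C_ki N_i
            target = np.random.random() * cn[k]
            acc = 0.0
            i = S - 1
            for jj in range(S - 1):
                acc += C[k, jj] * N[jj]
                if target < acc:
                    i = jj
                    break
            n_cons += 1
            if record_events:
                events[k, i] += 1
            # resource unit is always lost
            R[k] -= 1
            d = cn[k]
            cons_w[k] -= d
            sum_cons -= d
            if eps >= 1.0 or np.random.random() < eps:
                n_birth += 1
                N[i] += 1
                death_w[i] += eta[i]
                sum_death += eta[i]
                for kk in range(K):
                    c = Ct[i, kk]
                    cn[kk] += c
                    d2 = R[kk] * c
                    cons_w[kk] += d2
                    sum_cons += d2

        steps += 1
        if steps % _RESYNC_EVERY == 0:
            for k in range(K):
                s = 0.0
                for i2 in range(S):
                    s += C[k, i2] * N[i2]
                cn[k] = s
                cons_w[k] = R[k] * cn[k]
            death_w = eta * N
            sum_death = death_w.sum()
            sum_cons = cons_w.sum()

    # any snapshots scheduled at exactly t_end
    while snap_idx < n_snap:
        for i in range(S):
            snapN[snap_idx, i] = N[i]
        for k in range(K):
            snapR[snap_idx, k] = R[k]
        snap_idx += 1

    return (
        snapN,
        snapR,
        ext_sp[:n_ext].copy(),
        ext_t[:n_ext].copy(),
        events,
        N,
        R,
        n_birth,
        n_cons,
        steps,
    )
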