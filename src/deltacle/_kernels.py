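"""Numba event loops for the exact stochastic simulators.

Both kernels implement Gillespie's direct method: draw an exponential waiting
time with rate equal to the total propensity, then pick a channel with
probability proportional to its propensity.  States are recorded onto a
regular output grid (piecewise-constant sampling of the jump process).

The compartment kernel keeps the cross-subvolume sum S = sum_i R_i L_i
incrementally up to date, so the association propensity and the spatial
correction term are O(1) per event; compartment selection is a linear scan
(M is small).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["wellmixed_core", "wellmixed_events", "spatial_core"]


@njit(cache=False)
def wellmixed_core(seed, R, C, L, kon, koff, ke, kt, QR, F0, t0, t_end, grid):
    """Direct-method SSA for the five-reaction network; returns (n_grid, 3) counts."""
    np.random.seed(seed)
    n_grid = grid.size
    out = np.zeros((n_grid, 3), dtype=np.int64)
    gi = 0
    t = t0
    while True:
        a_on = kon * R * L
        a_off = koff * C
        a_e = ke * C
        a_t = kt * R
        atot = a_on + a_off + a_e + a_t + F0 + QR
        if atot <= 0.0:
            t_next = t_end + 1.0
        else:
            t_next = t + np.random.exponential(1.0 / atot)
        while gi < n_grid and grid[gi] < t_next:
            out[gi, 0] = R
            out[gi, 1] = C
            out[gi, 2] = L
            gi += 1
        if t_next > t_end or atot <= 0.0:
            break
        t = t_next
        u = np.random.random() * atot
        if u < a_on:
            R -= 1
            L -= 1
            C += 1
        elif u < a_on + a_off:
            R += 1
            L += 1
            C -= 1
        elif u < a_on + a_off + a_e:
            C -= 1
        elif u < a_on + a_off + a_e + a_t:
            R -= 1
        elif u < a_on + a_off + a_e + a_t + F0:
            L += 1
        else:
            R += 1
    return out


@njit(cache=False)
def wellmixed_events(seed, R, C, L, kon, koff, ke, kt, QR, F0, t0, t_end, max_events):
    """As :func:`wellmixed_core` but returning the raw event sequence.

    Returns (times, states, n) where the first ``n`` rows are events
    (time, R, C, L after the event); stops at ``t_end`` or ``max_events``.
    """
    np.random.seed(seed)
    times = np.zeros(max_events)
    states = np.zeros((max_events, 3), dtype=np.int64)
    n = 0
    t = t0
    while n < max_events:
        a_on = kon * R * L
        a_off = koff * C
        a_e = ke * C
        a_t = kt * R
        atot = a_on + a_off + a_e + a_t + F0 + QR
        if atot <= 0.0:
            break
        t = t + np.random.exponential(1.0 / atot)
        if t > t_end:
            break
        u = np.random.random() * atot
        if u < a_on:
            R -= 1
            L -= 1
            C += 1
        elif u < a_on + a_off:
            R += 1
            L += 1
            C -= 1
        elif u < a_on + a_off + a_e:
            C -= 1
        elif u < a_on + a_off + a_e + a_t:
            R -= 1
        elif u < a_on + a_off + a_e + a_t + F0:
            L += 1
        else:
            R += 1
        times[n] = t
        states[n, 0] = R
        states[n, 1] = C
        states[n, 2] = L
        n += 1
    return times, states, n


@njit(cache=False)
def spatial_core(seed, R, L, C, kon_local, koff, ke, kt, QR, F0, hop, t0, t_end, grid):
    """Direct-method SSA over the compartment-extended channel set.

    R, L, C are int64 per-compartment count arrays (modified in place on a
    copy made by the caller).  Channels: per-compartment association at
    ``kon_local * R_i * L_i``, global dissociation / internalisations /
    sources resolved to a compartment by occupancy (sources uniformly at
    random), and nearest-neighbour ring hops at rate ``hop`` per molecule
    per neighbour for every species.

    Returns (n_grid, 4) int64: totals R, C, L and S = sum_i R_i L_i.
    """
    np.random.seed(seed)
    M = R.size
    n_grid = grid.size
    out = np.zeros((n_grid, 4), dtype=np.int64)

    TR = np.int64(0)
    TL = np.int64(0)
    TC = np.int64(0)
    S = np.int64(0)
    for i in range(M):
        TR += R[i]
        TL += L[i]
        TC += C[i]
        S += R[i] * L[i]

    gi = 0
    t = t0
    while True:
        a_on = kon_local * S
        a_off = koff * TC
        a_e = ke * TC
        a_t = kt * TR
        a_hop = hop * 2.0 * (TR + TL + TC)
        atot = a_on + a_off + a_e + a_t + F0 + QR + a_hop
        if atot <= 0.0:
            t_next = t_end + 1.0
        else:
            t_next = t + np.random.exponential(1.0 / atot)
        while gi < n_grid and grid[gi] < t_next:
            out[gi, 0] = TR
            out[gi, 1] = TC
            out[gi, 2] = TL
            out[gi, 3] = S
            gi += 1
        if t_next > t_end or atot <= 0.0:
            break
        t = t_next
        u = np.random.random() * atot
        if u < a_on:
            # association in compartment picked with weight R_i L_i
            r = np.random.random() * S
            acc = 0.0
            i = 0
            for j in range(M):
                acc += R[j] * L[j]
                if acc > r:
                    i = j
                    break
                if R[j] * L[j] > 0:
                    i = j
            S += -R[i] - L[i] + 1
            R[i] -= 1
            L[i] -= 1
            C[i] += 1
            TR -= 1
            TL -= 1
            TC += 1
        elif u < a_on + a_off + a_e:
            # dissociation or complex internalisation: compartment ~ C_i
            r = np.random.random() * TC
            acc = 0.0
            i = 0
            for j in range(M):
                acc += C[j]
                if acc > r:
                    i = j
                    break
                if C[j] > 0:
                    i = j
            if u < a_on + a_off:
                S += R[i] + L[i] + 1
                C[i] -= 1
                R[i] += 1
                L[i] += 1
                TC -= 1
                TR += 1
                TL += 1
            else:
                C[i] -= 1
                TC -= 1
        elif u < a_on + a_off + a_e + a_t:
            # receptor internalisation: compartment ~ R_i
            r = np.random.random() * TR
            acc = 0.0
            i = 0
            for j in range(M):
                acc += R[j]
                if acc > r:
                    i = j
                    break
                if R[j] > 0:
                    i = j
            S -= L[i]
            R[i] -= 1
            TR -= 1
        elif u < a_on + a_off + a_e + a_t + F0:
            i = np.random.randint(0, M)
            S += R[i]
            L[i] += 1
            TL += 1
        elif u < a_on + a_off + a_e + a_t + F0 + QR:
            i = np.random.randint(0, M)
            S += L[i]
            R[i] += 1
            TR += 1
        else:
            # hop: species ~ total count, compartment ~ per-compartment count
            r = np.random.random() * (TR + TL + TC)
            if r < TR:
                sp = 0
                tot = TR
                r2 = r
            elif r < TR + TL:
                sp = 1
                tot = TL
                r2 = r - TR
            else:
                sp = 2
                tot = TC
                r2 = r - TR - TL
            acc = 0.0
            i = 0
            if sp == 0:
                for j in range(M):
                    acc += R[j]
                    if acc > r2:
                        i = j
                        break
                    if R[j] > 0:
                        i = j
            elif sp == 1:
                for j in range(M):
                    acc += L[j]
                    if acc > r2:
                        i = j
                        break
                    if L[j] > 0:
                        i = j
            else:
                for j in range(M):
                    acc += C[j]
                    if acc > r2:
                        i = j
                        break
                    if C[j] > 0:
                        i = j
            if np.random.random() < 0.5:
                k = (i + 1) % M
            else:
                k = (i - 1) % M
            if sp == 0:
                S += L[k] - L[i]
                R[i] -= 1
                R[k] += 1
            elif sp == 1:
                S += R[k] - R[i]
                L[i] -= 1
                L[k] += 1
            else:
                C[i] -= 1
                C[k] += 1
    return out
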