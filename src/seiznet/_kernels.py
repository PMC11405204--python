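"""Numba kernel for the conditionally-Bernoulli spike-train simulator.

The generative law is a discrete-time process at step ``dt`` (1 ms by
default): electrode ``i`` fires at step ``t`` with probability

    p_i(t) = clip( base_p[i] * gain(t) + sum_j W[j, i] * fired[j, t-1] )

where ``gain(t)`` is ``burst_gain`` while a well-global two-state Markov
burst process is in its ON state and 1 otherwise, and ``W[j, i]`` is the
directed excitation weight from electrode ``j`` onto ``i``. Probabilities
are clipped to ``1 - 1e-6``; the kernel counts clip events so the caller
can log them.

The simulation is event-driven but exact. A fire is the union of two
independent Bernoulli events — a *baseline* fire with probability
``pb = clip(base_p · gain)`` and, when coupled predecessors fired at
``t−1``, an *induced* fire with probability ``c' = (p − pb)/(1 − pb)``
where ``p = clip(pb + Σ W)`` — so that
``P(fire) = pb + c'(1 − pb) = p`` exactly. Baseline fires are sampled
per burst-state segment from the binomial count (positions uniform
without replacement, the conditional law of a Bernoulli process given
its count); induced fires are drawn only at the sparse steps following
actual activity. This is orders of magnitude faster than stepping every
electrode through every step and draws from exactly the same law.
"""

from __future__ import annotations

import numpy as np
from numba import njit

P_CLIP_MAX = 1.0 - 1e-6


@njit(cache=True)
def simulate_well_kernel(seed, n_steps, base_p, coupling, p_on, p_off, gain):
    """Simulate one well; returns (fired, burst_state, n_clipped).

    fired : (n, n_steps) boolean spike raster
    burst_state : (n_steps,) boolean latent population-burst state
    """
    np.random.seed(seed)
    n = base_p.shape[0]

    # latent burst state sequence (two-state Markov chain)
    burst = np.zeros(n_steps, dtype=np.bool_)
    state = False
    for t in range(n_steps):
        if state:
            if np.random.random() < p_off:
                state = False
        else:
            if np.random.random() < p_on:
                state = True
        burst[t] = state

    # burst segments: (start, end, is_burst)
    n_seg = 1
    for t in range(1, n_steps):
        if burst[t] != burst[t - 1]:
            n_seg += 1
    seg_start = np.empty(n_seg, dtype=np.int64)
    seg_end = np.empty(n_seg, dtype=np.int64)
    seg_burst = np.empty(n_seg, dtype=np.bool_)
    k = 0
    seg_start[0] = 0
    seg_burst[0] = burst[0] if n_steps > 0 else False
    for t in range(1, n_steps):
        if burst[t] != burst[t - 1]:
            seg_end[k] = t
            k += 1
            seg_start[k] = t
            seg_burst[k] = burst[t]
    seg_end[n_seg - 1] = n_steps

    n_clipped = 0
    fired = np.zeros((n, n_steps), dtype=np.bool_)
    step_count = np.zeros(n_steps, dtype=np.int32)

    # baseline fires, segment-wise binomial counts + uniform placement
    for i in range(n):
        for s in range(n_seg):
            L = seg_end[s] - seg_start[s]
            pb = base_p[i] * (gain if seg_burst[s] else 1.0)
            if pb > P_CLIP_MAX:
                pb = P_CLIP_MAX
                n_clipped += L
            if pb <= 0.0 or L == 0:
                continue
            kfire = np.random.binomial(L, pb)
            placed = 0
            while placed < kfire:
                t = seg_start[s] + int(np.random.random() * L)
                if t >= seg_end[s]:
                    continue
                if not fired[i, t]:
                    fired[i, t] = True
                    step_count[t] += 1
                    placed += 1

    # induced fires at steps following activity
    has_coupling = False
    for j in range(n):
        for i in range(n):
            if coupling[j, i] > 0.0:
                has_coupling = True
                break
        if has_coupling:
            break
    if has_coupling:
        # adjacency: out-neighbors of each electrode
        deg = np.zeros(n, dtype=np.int64)
        for j in range(n):
            for i in range(n):
                if coupling[j, i] > 0.0:
                    deg[j] += 1
        offs = np.zeros(n + 1, dtype=np.int64)
        for j in range(n):
            offs[j + 1] = offs[j] + deg[j]
        nbr = np.empty(offs[n], dtype=np.int64)
        wgt = np.empty(offs[n], dtype=np.float64)
        pos = offs.copy()
        for j in range(n):
            for i in range(n):
                if coupling[j, i] > 0.0:
                    nbr[pos[j]] = i
                    wgt[pos[j]] = coupling[j, i]
                    pos[j] += 1

        c = np.zeros(n, dtype=np.float64)
        touched = np.empty(n, dtype=np.int64)
        for t in range(n_steps - 1):
            if step_count[t] == 0:
                continue
            n_touch = 0
            for j in range(n):
                if fired[j, t]:
                    for a in range(offs[j], offs[j + 1]):
                        i = nbr[a]
                        if c[i] == 0.0:
                            touched[n_touch] = i
                            n_touch += 1
                        c[i] += wgt[a]
            g = gain if burst[t + 1] else 1.0
            for a in range(n_touch):
                i = touched[a]
                pb = base_p[i] * g
                if pb > P_CLIP_MAX:
                    pb = P_CLIP_MAX
                p_tot = pb + c[i]
                if p_tot > P_CLIP_MAX:
                    p_tot = P_CLIP_MAX
                    n_clipped += 1
                c[i] = 0.0
                if fired[i, t + 1]:
                    continue  # baseline fire already realized the union
                c_prime = (p_tot - pb) / (1.0 - pb)
                if np.random.random() < c_prime:
                    fired[i, t + 1] = True
                    step_count[t + 1] += 1
    return fired, burst, n_clipped
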