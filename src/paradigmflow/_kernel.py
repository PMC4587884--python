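"""Numba-compiled Euler–Maruyama engine.

This module holds the hot loop shared by trajectory simulation and the
replicate batches.  It is an implementation detail: the documented,
numpy-level step semantics live in :mod:`paradigmflow.dynamics`
(``em_step`` and friends), and the two are cross-checked in the test
suite.  The kernel draws its Gaussian variates from numba's internal
Mersenne Twister, seeded per call, so a given (parameters, seed) pair is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_kernel"]


@njit(cache=False)
def simulate_kernel(
    vcoef,  # potential coefficients, highest power first (length 5)
    gcoef,  # gradient coefficients, highest power first (length 4)
    x_barrier,
    x_arrive,
    alpha,
    omega,
    eps,
    dt,
    m,
    no_return,
    n_steps,
    x0,
    record_every,
    seed,
    stop_on_arrival,
):
    """Synchronous Euler–Maruyama integration of the community SDE.

    Per step, for every agent i:
      drift_i = (1-alpha) V'(x_i) + alpha*omega*(1/m) sum_j [V(x_j)-V(x_i)](x_j-x_i)
      x_i    <- x_i + drift_i*dt + eps*sqrt(dt)*z_i
    followed by the no-return reflection at the valley bottom (only for
    agents that have already arrived at the new paradigm) and the
    one-way latch updates.

    Returns (x, crossed, arrived, arrival_t, rec_t, rec_x, t_final, x_lo, x_hi).
    ``arrival_t`` holds inf for agents that never reached ``x_arrive``.
    With ``m == n-1`` the social sum is computed in O(n) via aggregate
    sums; otherwise m distinct peers are resampled per agent per step.
    """
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    v4, v3, v2, v1, v0 = vcoef[0], vcoef[1], vcoef[2], vcoef[3], vcoef[4]
    g3, g2, g1, g0 = gcoef[0], gcoef[1], gcoef[2], gcoef[3]

    crossed = np.empty(n, dtype=np.bool_)
    arrived = np.empty(n, dtype=np.bool_)
    arrival_t = np.empty(n)
    all_arrived = True
    for i in range(n):
        crossed[i] = x[i] > x_barrier
        arrived[i] = x[i] >= x_arrive
        arrival_t[i] = 0.0 if arrived[i] else np.inf
        if not arrived[i]:
            all_arrived = False

    if record_every > 0:
        n_rec_max = n_steps // record_every + 2
    else:
        n_rec_max = 1
    rec_t = np.empty(n_rec_max)
    rec_x = np.empty((n_rec_max, n))
    n_rec = 0
    if record_every > 0:
        rec_t[0] = 0.0
        for i in range(n):
            rec_x[0, i] = x[i]
        n_rec = 1

    x_lo = x[0]
    x_hi = x[0]
    for i in range(n):
        if x[i] < x_lo:
            x_lo = x[i]
        if x[i] > x_hi:
            x_hi = x[i]

    sq = eps * np.sqrt(dt)
    V = np.empty(n)
    drift = np.empty(n)
    peer_buf = np.empty(max(n - 1, 1), dtype=np.int64)
    use_social = alpha > 0.0 and n > 1
    full_peers = m == n - 1

    t = 0.0
    step = 0
    while step < n_steps:
        if stop_on_arrival and all_arrived:
            break

        if use_social:
            s_v = 0.0
            s_x = 0.0
            s_vx = 0.0
            for i in range(n):
                xi = x[i]
                vi = (((v4 * xi + v3) * xi + v2) * xi + v1) * xi + v0
                V[i] = vi
                s_v += vi
                s_x += xi
                s_vx += vi * xi

        for i in range(n):
            xi = x[i]
            f = ((g3 * xi + g2) * xi + g1) * xi + g0
            dr = (1.0 - alpha) * f
            if use_social:
                vi = V[i]
                if full_peers:
                    s = (
                        (s_vx - vi * xi)
                        - xi * (s_v - vi)
                        - vi * (s_x - xi)
                        + (n - 1) * vi * xi
                    )
                else:
                    # sample m distinct peers by partial Fisher-Yates
                    k = 0
                    for j in range(n):
                        if j != i:
                            peer_buf[k] = j
                            k += 1
                    s = 0.0
                    for p in range(m):
                        r = p + np.random.randint(0, n - 1 - p)
                        tmp = peer_buf[p]
                        peer_buf[p] = peer_buf[r]
                        peer_buf[r] = tmp
                        j = peer_buf[p]
                        xj = x[j]
                        vj = (((v4 * xj + v3) * xj + v2) * xj + v1) * xj + v0
                        s += (vj - vi) * (xj - xi)
                dr += alpha * omega * (s / m)
            drift[i] = dr

        t_next = t + dt
        all_arrived = True
        for i in range(n):
            xi = x[i] + drift[i] * dt
            if eps > 0.0:
                xi += sq * np.random.normal(0.0, 1.0)
            if not np.isfinite(xi):
                raise FloatingPointError(
                    "non-finite agent position: integration step too large"
                )
            if no_return and arrived[i] and xi < x_barrier:
                xi = 2.0 * x_barrier - xi  # reflect at the valley bottom
            x[i] = xi
            if xi > x_barrier:
                crossed[i] = True
            if not arrived[i] and xi >= x_arrive:
                arrived[i] = True
                arrival_t[i] = t_next
            if not arrived[i]:
                all_arrived = False
            if xi < x_lo:
                x_lo = xi
            if xi > x_hi:
                x_hi = xi

        t = t_next
        step += 1
        if record_every > 0 and step % record_every == 0:
            rec_t[n_rec] = t
            for i in range(n):
                rec_x[n_rec, i] = x[i]
            n_rec += 1

    return x, crossed, arrived, arrival_t, rec_t[:n_rec], rec_x[:n_rec], t, x_lo, x_hi
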