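"""Per-agent evolution on the PT landscape.

Each of n agents follows the Langevin-type equation

    dx_i/dt = (1 - alpha) f(x_i) + alpha * omega * g(x_i, peers) + eps * xi(t)

where f = V' is individual hill climbing, g is the peer-sampled social
influence term

    g(x_i) = (1/m) * sum_j [V(x_j) - V(x_i)] * (x_j - x_i)

(attraction toward better-performing peers, repulsion from worse ones),
and xi(t) is zero-mean Gaussian white noise of strength eps modelling
random experimentation.  alpha in [0, 1] is the weight agents place on
social versus individual information; omega rescales the social term.

Integration is synchronous Euler–Maruyama with sqrt(dt) noise scaling.
A one-way "no-return" rule reflects agents that have already crossed the
valley bottom x_barrier back into the new-paradigm basin, so migration
to the new paradigm is irreversible.  An agent counts as *arrived* once
it has ever reached x_new - arrival_delta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _kernel
from .landscape import QuarticLandscape, critical_points, gradient, potential_value

__all__ = [
    "DynamicsParams",
    "CommunityState",
    "TrajectoryRecord",
    "sample_peers",
    "social_influence",
    "drift",
    "apply_no_return",
    "em_step",
    "initial_state",
    "simulate_trajectory",
]

#: agents leaving this window trigger a diagnostic warning (the quartic is
#: self-confining for gradient ascent, so excursions beyond it indicate a
#: too-large step or pathological parameters, not a modelling regime)
_SANE_BOUNDS = (-10.0, 15.0)

#: cap on record rows * agents to avoid accidental multi-GB allocations
_MAX_RECORD_CELLS = 50_000_000


@dataclass(frozen=True)
class DynamicsParams:
    """Dynamics and stopping parameters.

    alpha : weight on social influence, in [0, 1].
    omega : social-to-individual strength ratio (default 3.14).
    epsilon : experimentation-noise strength (default 0.37).
    dt : Euler–Maruyama step (default 0.01).
    m : peers sampled per agent per step; None means all n-1 peers.
    t_max : censoring horizon in model time units.
    arrival_delta : an agent has arrived once x >= x_new - arrival_delta.
    no_return : reflect crossed agents at the valley bottom.
    jitter_sd : sd of optional Gaussian jitter on the initial positions.
    """

    alpha: float = 0.15
    omega: float = 3.14
    epsilon: float = 0.37
    dt: float = 0.01
    m: int | None = None
    t_max: float = 1e5
    arrival_delta: float = 0.5
    no_return: bool = True
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be nonnegative, got {self.epsilon}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_max <= 0:
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        if self.arrival_delta <= 0:
            raise ValueError(f"arrival_delta must be positive, got {self.arrival_delta}")
        if self.jitter_sd < 0:
            raise ValueError(f"jitter_sd must be nonnegative, got {self.jitter_sd}")
        if self.m is not None and self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m}")

    def resolve_m(self, n: int) -> int:
        """Effective peer-sample size for a community of n agents."""
        m = n - 1 if self.m is None else self.m
        if not 1 <= m <= n - 1:
            raise ValueError(f"m must satisfy 1 <= m <= n-1 = {n - 1}, got {m}")
        return m


@dataclass
class CommunityState:
    """Positions, one-way latch flags, and the simulation clock."""

    positions: np.ndarray
    crossed: np.ndarray  # agent has ever exceeded x_barrier
    arrived: np.ndarray  # agent has ever reached x_new - arrival_delta
    t: float = 0.0

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class TrajectoryRecord:
    """Sampled positions and per-agent first-arrival times of one realization."""

    sample_times: np.ndarray
    position_matrix: np.ndarray  # samples x n
    arrival_times: np.ndarray  # inf for agents that never arrived
    seed: int
    t_final: float = 0.0
    t_max: float = math.inf

    @property
    def n(self) -> int:
        return self.position_matrix.shape[1]

    @property
    def censored(self) -> bool:
        """True if any agent failed to arrive before the horizon."""
        return bool(np.any(~np.isfinite(self.arrival_times)))


def sample_peers(rng: np.random.Generator, n: int, i: int, m: int) -> np.ndarray:
    """Draw m distinct peer indices uniformly from {0..n-1} \\ {i}."""
    if not 0 <= i < n:
        raise ValueError(f"agent index {i} out of range for n={n}")
    if not 1 <= m <= n - 1:
        raise ValueError(f"m must satisfy 1 <= m <= n-1 = {n - 1}, got {m}")
    others = np.delete(np.arange(n), i)
    return rng.choice(others, size=m, replace=False)


def social_influence(
    landscape: QuarticLandscape, x_i: float, peer_positions
) -> float:
    """Mean peer pull g(x_i) = (1/m) sum_j [V(x_j) - V(x_i)](x_j - x_i)."""
    peers = np.atleast_1d(np.asarray(peer_positions, dtype=float))
    if peers.size == 0:
        raise ValueError("social influence is undefined for an empty peer set")
    dv = potential_value(landscape, peers) - potential_value(landscape, x_i)
    return float(np.mean(dv * (peers - x_i)))


def drift(
    landscape: QuarticLandscape,
    params: DynamicsParams,
    x_i: float,
    peer_positions,
) -> float:
    """Deterministic part (1-alpha) V'(x_i) + alpha*omega*g of the evolution equation.

    The social term is only evaluated when alpha > 0, so the pure
    individual-search limit does not require peers.
    """
    d = (1.0 - params.alpha) * gradient(landscape, x_i)
    if params.alpha > 0.0:
        d += params.alpha * params.omega * social_influence(landscape, x_i, peer_positions)
    return float(d)


def apply_no_return(landscape: QuarticLandscape, state: CommunityState) -> CommunityState:
    """Reflect arrived agents that would fall below the valley bottom.

    Agents that have already reached the new paradigm (arrived=True) and
    whose proposed position lies below x_barrier are mapped to
    2*x_barrier - x, so migration from the new paradigm back to the old
    one is ruled out.  Agents that have merely crossed the valley but not
    yet conquered the new optimum move freely: the social pull of the
    mass still working under the old paradigm can drag a would-be
    pioneer back, which is the conservative force responsible for the
    long shift times at intermediate alpha.  (A reflecting barrier
    triggered on mere valley crossing instead acts as a one-touch
    ratchet, collapses that conservative force, and erases the high-alpha
    regime structure entirely.)
    """
    x_b = critical_points(landscape).x_barrier
    pos = state.positions.copy()
    mask = state.arrived & (pos < x_b)
    pos[mask] = 2.0 * x_b - pos[mask]
    return replace(state, positions=pos)


def _update_latches(state: CommunityState, x_barrier: float, x_arrive: float) -> None:
    state.crossed |= state.positions > x_barrier
    state.arrived |= state.positions >= x_arrive


def initial_state(
    landscape: QuarticLandscape,
    n: int,
    params: DynamicsParams | None = None,
    rng: np.random.Generator | None = None,
) -> CommunityState:
    """All agents at the old paradigm x_old (plus optional Gaussian jitter)."""
    if n < 1:
        raise ValueError(f"community size n must be >= 1, got {n}")
    params = params or DynamicsParams()
    cp = critical_points(landscape)
    pos = np.full(n, cp.x_old)
    if params.jitter_sd > 0:
        if rng is None:
            raise ValueError("jitter_sd > 0 requires an rng")
        pos = pos + rng.normal(0.0, params.jitter_sd, size=n)
    state = CommunityState(
        positions=pos,
        crossed=np.zeros(n, dtype=bool),
        arrived=np.zeros(n, dtype=bool),
        t=0.0,
    )
    _update_latches(state, cp.x_barrier, cp.x_new - params.arrival_delta)
    return state


def em_step(
    landscape: QuarticLandscape,
    params: DynamicsParams,
    state: CommunityState,
    rng: np.random.Generator,
    noise: np.ndarray | None = None,
) -> CommunityState:
    """One synchronous Euler–Maruyama step of the whole community.

    All drifts are evaluated at the pre-step positions; every agent then
    moves by drift*dt + eps*sqrt(dt)*z_i with independent standard-normal
    z_i (drawn from ``rng`` unless an explicit ``noise`` vector is given,
    which is useful for equivariance tests).  The no-return reflection and
    latch updates are applied to the proposed positions, and the clock
    advances by dt.

    This is the readable reference implementation of the update; long
    simulations go through the compiled kernel in
    :func:`simulate_trajectory`, which implements identical semantics.
    """
    n = state.n
    m = params.resolve_m(n) if (params.alpha > 0 and n > 1) else 0
    cp = critical_points(landscape)
    x = state.positions
    drifts = np.empty(n)
    for i in range(n):
        if params.alpha > 0.0 and n > 1:
            peers = x[sample_peers(rng, n, i, m)] if m < n - 1 else np.delete(x, i)
            drifts[i] = drift(landscape, params, x[i], peers)
        else:
            drifts[i] = (1.0 - params.alpha) * gradient(landscape, x[i])
    if noise is None:
        noise = rng.standard_normal(n)
    proposed = x + drifts * params.dt + params.epsilon * math.sqrt(params.dt) * noise
    if not np.all(np.isfinite(proposed)):
        raise FloatingPointError("non-finite agent position: integration step too large")
    new = CommunityState(
        positions=proposed,
        crossed=state.crossed.copy(),
        arrived=state.arrived.copy(),
        t=state.t + params.dt,
    )
    if params.no_return:
        new = apply_no_return(landscape, new)
    _update_latches(new, cp.x_barrier, cp.x_new - params.arrival_delta)
    return new


def _kernel_seed(seed: int) -> tuple[int, np.random.Generator]:
    """Derive a 32-bit kernel seed and a jitter Generator from a user seed."""
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(2)
    return int(state[0]), np.random.Generator(np.random.PCG64(int(state[1])))


def simulate_trajectory(
    landscape: QuarticLandscape,
    params: DynamicsParams,
    n: int,
    seed: int,
    record_every: int = 100,
    x0: np.ndarray | None = None,
    stop_on_arrival: bool = True,
) -> TrajectoryRecord:
    """Simulate one community realization until full arrival or t_max.

    Agents start at x_old (or at ``x0`` if given), evolve under
    :func:`em_step` semantics via the compiled kernel, and are sampled
    every ``record_every`` steps (0 disables position recording; arrival
    times are always tracked).  Reaching t_max without full arrival is
    censoring, flagged on the returned record, not an error.
    """
    if n < 1:
        raise ValueError(f"community size n must be >= 1, got {n}")
    m = params.resolve_m(n) if n > 1 else 0
    kseed, jitter_rng = _kernel_seed(seed)
    cp = critical_points(landscape)
    if x0 is None:
        x0 = initial_state(landscape, n, params, rng=jitter_rng).positions
    else:
        x0 = np.asarray(x0, dtype=float).copy()
        if x0.shape != (n,):
            raise ValueError(f"x0 must have shape ({n},), got {x0.shape}")
    n_steps = int(math.ceil(params.t_max / params.dt))
    if record_every > 0 and (n_steps // record_every + 2) * n > _MAX_RECORD_CELLS:
        raise ValueError(
            "recording would allocate more than "
            f"{_MAX_RECORD_CELLS} cells; increase record_every or lower t_max"
        )
    # stability guard on the initial drift magnitude
    g0 = np.abs(gradient(landscape, x0))
    if np.max(g0) * params.dt >= 0.5:
        raise ValueError(
            "dt too large for the initial drift magnitude "
            f"({np.max(g0):.3g} * {params.dt} >= 0.5)"
        )
    x, crossed, arrived, arrival_t, rec_t, rec_x, t_final, x_lo, x_hi = (
        _kernel.simulate_kernel(
            landscape.potential_coeffs,
            landscape.gradient_coeffs,
            cp.x_barrier,
            cp.x_new - params.arrival_delta,
            params.alpha,
            params.omega,
            params.epsilon,
            params.dt,
            m,
            params.no_return,
            n_steps,
            x0,
            record_every,
            kseed,
            stop_on_arrival,
        )
    )
    if x_lo < _SANE_BOUNDS[0] or x_hi > _SANE_BOUNDS[1]:
        warnings.warn(
            f"agent positions left the diagnostic window {_SANE_BOUNDS} "
            f"(range [{x_lo:.3g}, {x_hi:.3g}]); check dt and noise strength",
            RuntimeWarning,
            stacklevel=2,
        )
    return TrajectoryRecord(
        sample_times=rec_t,
        position_matrix=rec_x,
        arrival_times=arrival_t,
        seed=seed,
        t_final=t_final,
        t_max=params.t_max,
    )
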