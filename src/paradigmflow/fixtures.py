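"""Registered deterministic fixtures for tests and demos.

Each fixture is a tiny, fully specified scenario: a landscape, dynamics
parameters, and the hand-computed values a correct implementation must
reproduce.  They encode the worked examples used throughout the test
suite in one place.
"""

from __future__ import annotations

from .dynamics import DynamicsParams
from .landscape import QuarticLandscape

__all__ = ["make_fixture", "FIXTURE_NAMES"]


def _default_landscape():
    """Default landscape with its published critical-point structure.

    Expected values: gamma = 0.04 = 4a exactly; roots rounding to
    -1.27, 0.5 (one decimal), 4.5; V(0) = V(1) = a*e = 2.0; V(-1) = 2.14.
    """
    return (
        QuarticLandscape(),
        DynamicsParams(),
        {
            "gamma": 0.04,
            "x_old_2dp": -1.27,
            "x_barrier_1dp": 0.5,
            "x_new_1dp": 4.5,
            "V_at_0": 2.0,
            "V_at_1": 2.0,
            "V_at_minus_1": 2.14,
        },
    )


def _two_agent_one_peer():
    """Two agents, hand-expanded social and drift terms.

    With the default landscape, an agent at x=0 observing a single peer
    at x=-1 feels g = (V(-1)-V(0))*(-1-0) = (2.14-2.0)*(-1) = -0.14; at
    alpha=1, omega=3.14 the drift is 3.14 * -0.14 = -0.4396; at alpha=0
    the drift is V'(0) = -0.12.
    """
    return (
        QuarticLandscape(),
        DynamicsParams(alpha=1.0, m=1),
        {
            "x_i": 0.0,
            "peer": -1.0,
            "social": -0.14,
            "drift_alpha1": -0.4396,
            "drift_alpha0": -0.12,
        },
    )


def _noise_free_basins():
    """Noise-free gradient ascent splits at the valley bottom.

    With epsilon=0, an agent starting left of x_barrier converges to
    x_old, one starting right of it to x_new.
    """
    return (
        QuarticLandscape(),
        DynamicsParams(alpha=0.0, epsilon=0.0, t_max=1e3),
        {
            "start_left": -0.5,
            "start_right": 2.0,
            "endpoint_left": "x_old",
            "endpoint_right": "x_new",
            "tolerance": 1e-6,
        },
    )


_REGISTRY = {
    "default-landscape": _default_landscape,
    "two-agent-one-peer": _two_agent_one_peer,
    "noise-free-basins": _noise_free_basins,
}

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def make_fixture(name: str):
    """Return (landscape, params, expected) for a registered fixture name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; registered fixtures: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return factory()
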