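"""The one-dimensional physical-technological (PT) landscape.

The landscape is an inverted double-well quartic

    V(x) = a * (-x (x + b)(x - c)(x - d) + e)

with two maxima separated by a valley: the lower maximum ``x_old`` is the
current paradigm, the higher maximum ``x_new`` the superior paradigm, and
the valley minimum ``x_barrier`` the transition cost between them.  Its
derivative is a cubic that factors as

    V'(x) = -gamma (x - x_new)(x - x_barrier)(x - x_old),   gamma = 4 a.

Agents climb V by gradient ascent, so the three roots of V' are the only
landscape features the dynamics ever see; they are always *derived* from
(a, b, c, d, e), never user-set.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuarticLandscape",
    "CriticalPoints",
    "potential_value",
    "gradient",
    "factored_gradient",
    "critical_points",
    "scaled_landscape",
]

#: numeric tolerance for root polishing and realness checks
_ROOT_TOL = 1e-10


@dataclass(frozen=True)
class QuarticLandscape:
    """Parameters of the quartic PT landscape.

    All five coefficients are positive and dimensionless.  ``a`` is the
    overall scale (it multiplies the whole potential, so it sets barrier
    heights without moving critical points), ``b``, ``c``, ``d`` are the
    offsets of the roots of the quartic product (the product vanishes at
    x in {0, -b, c, d}), and ``e`` is a vertical offset that keeps the
    potential positive over the region of interest.
    """

    a: float = 1e-2
    b: float = 2.0
    c: float = 1.0
    d: float = 6.0
    e: float = 2e2

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "e"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"landscape parameter {name!r} must be finite, got {v!r}")
            if v <= 0:
                raise ValueError(f"landscape parameter {name!r} must be positive, got {v!r}")

    @property
    def potential_coeffs(self) -> np.ndarray:
        """Degree-4 polynomial coefficients of V, highest power first."""
        a, b, c, d, e = self.a, self.b, self.c, self.d, self.e
        # -x(x+b)(x-c)(x-d) expanded: -(x^4 + (b-c-d)x^3 + (cd-bc-bd)x^2 + bcd x)
        return np.array(
            [-a, -a * (b - c - d), -a * (c * d - b * c - b * d), -a * b * c * d, a * e]
        )

    @property
    def gradient_coeffs(self) -> np.ndarray:
        """Degree-3 polynomial coefficients of V', highest power first."""
        v4, v3, v2, v1, _ = self.potential_coeffs
        return np.array([4 * v4, 3 * v3, 2 * v2, v1])

    # convenience method forms of the module-level operations
    def potential(self, x):
        return potential_value(self, x)

    def slope(self, x):
        return gradient(self, x)


@dataclass(frozen=True)
class CriticalPoints:
    """The three critical points of V and derived heights.

    ``gamma`` is the magnitude of the leading coefficient of the factored
    cubic V' (equal to 4a exactly).  ``barrier_from_old`` is the potential
    drop from the old paradigm into the valley — the escape barrier an
    agent must cross; ``gain`` is the height advantage of the new paradigm
    over the old one.
    """

    x_old: float
    x_barrier: float
    x_new: float
    gamma: float
    barrier_from_old: float
    gain: float


def _as_checked_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("position x must be finite")
    return arr


def potential_value(landscape: QuarticLandscape, x):
    """Evaluate V(x) = a(-x(x+b)(x-c)(x-d) + e), elementwise over x."""
    arr = _as_checked_array(x)
    out = np.polyval(landscape.potential_coeffs, arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def gradient(landscape: QuarticLandscape, x):
    """Evaluate the analytic derivative V'(x) (expanded cubic), elementwise."""
    arr = _as_checked_array(x)
    out = np.polyval(landscape.gradient_coeffs, arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def factored_gradient(landscape: QuarticLandscape, x):
    """Evaluate V' through its factored form -gamma(x-x_new)(x-x_barrier)(x-x_old).

    Provided as a cross-check: for any valid landscape it must agree with
    :func:`gradient` to floating tolerance.
    """
    cp = critical_points(landscape)
    arr = _as_checked_array(x)
    out = -cp.gamma * (arr - cp.x_new) * (arr - cp.x_barrier) * (arr - cp.x_old)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def critical_points(landscape: QuarticLandscape) -> CriticalPoints:
    """Locate the three critical points of V and the barrier/gain heights.

    The cubic V' = 0 is solved via the companion matrix (``numpy.roots``)
    and each root is polished with two Newton steps.  For positive
    parameters the quartic product has four real roots (0, -b, c, d), so
    V' always has three real critical points; a defensive error is raised
    if the numerics ever disagree.
    """
    coeffs = landscape.gradient_coeffs
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-8 * max(1.0, np.abs(roots).max())].real
    if real.size != 3:
        raise ValueError(
            "landscape is not a double-hill: V' must have exactly three real roots, "
            f"found {real.size}"
        )
    dcoeffs = np.polyder(coeffs)
    for _ in range(2):  # Newton polish
        real = real - np.polyval(coeffs, real) / np.polyval(dcoeffs, real)
    x_old, x_barrier, x_new = np.sort(real)
    v_old = potential_value(landscape, x_old)
    v_bar = potential_value(landscape, x_barrier)
    v_new = potential_value(landscape, x_new)
    return CriticalPoints(
        x_old=float(x_old),
        x_barrier=float(x_barrier),
        x_new=float(x_new),
        gamma=4.0 * landscape.a,
        barrier_from_old=float(v_old - v_bar),
        gain=float(v_new - v_old),
    )


def scaled_landscape(landscape: QuarticLandscape, barrier_scale: float) -> QuarticLandscape:
    """Rescale barrier and gain heights without moving the critical points.

    Multiplies ``a`` by ``barrier_scale`` and divides ``e`` by it, so the
    gradient (and hence every height difference, including the escape
    barrier) is multiplied by ``barrier_scale`` while V(0) = a*e and the
    root locations are preserved.
    """
    if not (isinstance(barrier_scale, (int, float)) and math.isfinite(barrier_scale)):
        raise ValueError(f"barrier_scale must be finite, got {barrier_scale!r}")
    if barrier_scale <= 0:
        raise ValueError(f"barrier_scale must be positive, got {barrier_scale!r}")
    return dataclasses.replace(
        landscape, a=landscape.a * barrier_scale, e=landscape.e / barrier_scale
    )
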