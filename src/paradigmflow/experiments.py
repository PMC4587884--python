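"""Replicate batches, shift-time estimation, and the alpha sweep.

A *paradigm shift* is complete when the last agent of the community has
reached the new optimum; the community shift time t_s is the maximum of
the n per-agent first-arrival times.  This module runs replicate batches
over (alpha, n) grids, summarizes mean shift times with standard errors,
detects the three-regime structure of the mean-t_s-vs-alpha curve
(decrease at low alpha, increase at intermediate alpha, decrease again
at high alpha), and provides the independent single-agent baseline: at
alpha = 0 the agents are statistically independent, so the community
time must be distributed as the max of n iid single-agent passage times.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams, TrajectoryRecord, simulate_trajectory
from .landscape import QuarticLandscape

__all__ = [
    "ShiftTime",
    "ShiftTimeResult",
    "SweepResult",
    "community_shift_time",
    "run_replicates",
    "alpha_sweep",
    "moving_average",
    "regime_summary",
    "single_agent_oracle",
    "SingleAgentOracle",
    "km_mean_shift_time",
]


@dataclass(frozen=True)
class ShiftTime:
    """A community shift time, possibly right-censored at the horizon."""

    value: float
    censored: bool


def community_shift_time(record: TrajectoryRecord) -> ShiftTime:
    """Time until the *last* agent arrives; censored if any agent never does.

    Censored results carry t_max as a lower bound, never a fabricated value.
    """
    if record.censored:
        return ShiftTime(value=float(record.t_max), censored=True)
    return ShiftTime(value=float(np.max(record.arrival_times)), censored=False)


@dataclass
class ShiftTimeResult:
    """Per-replicate community shift times for one (alpha, n) cell."""

    alpha: float
    n: int
    shift_times: np.ndarray
    censored: np.ndarray
    seeds: np.ndarray
    t_max: float

    @property
    def reps(self) -> int:
        return self.shift_times.size

    @property
    def censored_count(self) -> int:
        return int(self.censored.sum())

    def mean(self) -> float:
        """Mean t_s over uncensored replicates (nan if all censored)."""
        ok = ~self.censored
        return float(np.mean(self.shift_times[ok])) if ok.any() else math.nan

    def se(self) -> float:
        """Standard error of the uncensored mean (replicate sd / sqrt(reps))."""
        ok = ~self.censored
        k = int(ok.sum())
        if k < 2:
            return math.nan
        return float(np.std(self.shift_times[ok], ddof=1) / math.sqrt(k))


def _replicate_seeds(master_seed, reps: int) -> np.ndarray:
    """Deterministic per-replicate seeds; independent of execution order."""
    if isinstance(master_seed, np.random.SeedSequence):
        ss = master_seed
    else:
        ss = np.random.SeedSequence(int(master_seed))
    return np.array([int(child.generate_state(1)[0]) for child in ss.spawn(reps)])


def run_replicates(
    landscape: QuarticLandscape,
    params: DynamicsParams,
    n: int,
    reps: int,
    master_seed,
) -> ShiftTimeResult:
    """``reps`` independent community realizations with seeds spawned from the master.

    Identical master seeds give identical results; each replicate's stream
    depends only on its index, so results are order-independent.  A batch
    in which every replicate is censored is returned with a warning.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    seeds = _replicate_seeds(master_seed, reps)
    times = np.empty(reps)
    cens = np.empty(reps, dtype=bool)
    for r in range(reps):
        rec = simulate_trajectory(landscape, params, n, int(seeds[r]), record_every=0)
        st = community_shift_time(rec)
        times[r] = st.value
        cens[r] = st.censored
    if cens.all():
        warnings.warn(
            f"all {reps} replicates censored at t_max={params.t_max}; "
            "mean shift time is undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    return ShiftTimeResult(
        alpha=params.alpha, n=n, shift_times=times, censored=cens,
        seeds=seeds, t_max=params.t_max,
    )


def moving_average(y, window: int = 3) -> np.ndarray:
    """Centered moving average with partial windows at the edges."""
    y = np.asarray(y, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


@dataclass
class SweepResult:
    """Mean shift-time table over a full (alpha, n) factorial sweep.

    ``table`` has one row per cell, sorted by (n, alpha), with columns
    alpha, n, mean_ts, se_ts, reps, censored_count.  ``argmin_alpha``
    maps each n to the alpha minimizing the window-3 smoothed mean curve.
    """

    table: pd.DataFrame
    argmin_alpha: dict[int, float]
    master_seed: int | None = None
    smooth_window: int = 3

    def curve(self, n: int) -> pd.DataFrame:
        sub = self.table[self.table["n"] == n].sort_values("alpha")
        if sub.empty:
            raise KeyError(f"no sweep rows for n={n}")
        return sub.reset_index(drop=True)


def _smoothed_argmin(alphas: np.ndarray, means: np.ndarray, window: int = 3) -> float:
    return float(alphas[int(np.argmin(moving_average(means, window)))])


def alpha_sweep(
    landscape: QuarticLandscape,
    params_base: DynamicsParams,
    alphas,
    ns,
    reps: int,
    master_seed: int,
    smooth_window: int = 3,
) -> SweepResult:
    """Full factorial sweep of alpha x n; per-cell mean/SE of t_s.

    For each community size n the peer-sample size defaults to n-1 unless
    ``params_base.m`` fixes it.  Every cell draws its replicate seeds from
    a SeedSequence keyed on (master_seed, n-index, alpha-index), so cells
    are mutually independent and the whole sweep is reproducible.
    """
    alphas = np.sort(np.asarray(alphas, dtype=float))
    if np.any((alphas < 0) | (alphas > 1)):
        raise ValueError("alpha grid must lie within [0, 1]")
    ns = sorted(int(v) for v in ns)
    rows = []
    for ni, n in enumerate(ns):
        for ai, alpha in enumerate(alphas):
            params = dataclasses.replace(params_base, alpha=float(alpha))
            cell_ss = np.random.SeedSequence(int(master_seed), spawn_key=(ni, ai))
            res = run_replicates(landscape, params, n, reps, cell_ss)
            rows.append(
                {
                    "alpha": float(alpha),
                    "n": n,
                    "mean_ts": res.mean(),
                    "se_ts": res.se(),
                    "reps": reps,
                    "censored_count": res.censored_count,
                }
            )
    table = pd.DataFrame(rows).sort_values(["n", "alpha"]).reset_index(drop=True)
    argmin = {
        n: _smoothed_argmin(
            table[table["n"] == n]["alpha"].to_numpy(),
            table[table["n"] == n]["mean_ts"].to_numpy(),
            smooth_window,
        )
        for n in ns
    }
    return SweepResult(
        table=table, argmin_alpha=argmin,
        master_seed=int(master_seed), smooth_window=smooth_window,
    )


def _local_extrema(s: np.ndarray):
    """Interior local minima and maxima with a tie-tolerant rule.

    Index k is a local minimum if s[k] <= both neighbours and strictly
    below at least one; symmetrically for maxima.  The tolerance matters
    because the smoothed curve can hold plateaus at the edges.
    """
    minima, maxima = [], []
    for k in range(1, len(s) - 1):
        left, mid, right = s[k - 1], s[k], s[k + 1]
        if mid <= left and mid <= right and (mid < left or mid < right):
            minima.append(k)
        if mid >= left and mid >= right and (mid > left or mid > right):
            maxima.append(k)
    return minima, maxima


def regime_summary(sweep: SweepResult) -> dict[int, dict]:
    """Detect the decrease -> increase -> decrease regime structure per n.

    Operates on the window-smoothed mean curve (Monte-Carlo jitter on the
    raw means would otherwise masquerade as regime boundaries).  For each
    n, locates the first local minimum and the first subsequent local
    maximum; the pattern additionally requires no net increase into the
    minimum and no net increase after the maximum (tie-tolerant, since
    edge smoothing can flatten the first and last windows).  Absent patterns are
    reported honestly: ``status`` is "ok", "no-three-regime-structure"
    (smoothed curve monotone) or "inconclusive" (extrema present but not
    in the required order).
    """
    out: dict[int, dict] = {}
    for n in sorted(sweep.table["n"].unique()):
        curve = sweep.curve(n)
        alphas = curve["alpha"].to_numpy()
        means = curve["mean_ts"].to_numpy()
        if len(alphas) < 5:
            raise ValueError("regime detection needs at least 5 grid points")
        s = moving_average(means, sweep.smooth_window)
        minima, maxima = _local_extrema(s)
        entry = {
            "n": int(n),
            "three_regimes": False,
            "alpha_min": None,
            "alpha_max": None,
            "status": "inconclusive",
        }
        if not minima and not maxima:
            entry["status"] = "no-three-regime-structure"
        else:
            i_min = minima[0] if minima else None
            i_max = next((k for k in maxima if i_min is not None and k > i_min), None)
            if (
                i_min is not None
                and i_max is not None
                and s[i_min] <= s[0]
                and s[-1] <= s[i_max]
            ):
                entry.update(
                    three_regimes=True,
                    alpha_min=float(alphas[i_min]),
                    alpha_max=float(alphas[i_max]),
                    status="ok",
                )
        out[int(n)] = entry
    return out


@dataclass
class SingleAgentOracle:
    """Single-agent first-passage times and the implied community baseline."""

    passage_times: np.ndarray
    censored: np.ndarray
    seeds: np.ndarray
    t_max: float

    def implied_community_times(
        self, n: int, reps: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Max of n draws resampled from the uncensored passage times.

        At alpha = 0 the agents are independent, so this is the null
        distribution of the community shift time for a community of n.
        """
        ok = self.passage_times[~self.censored]
        if ok.size == 0:
            raise ValueError("no uncensored single-agent passage times to resample")
        if n == 1 and reps == ok.size:
            return ok.copy()
        draws = rng.choice(ok, size=(reps, n), replace=True)
        return draws.max(axis=1)

    def block_community_times(self, n: int) -> np.ndarray:
        """Maxima of consecutive disjoint blocks of n passage times.

        Unlike bootstrap resampling, each block max uses n *fresh*
        independent draws, so the result is an iid sample from the exact
        max-of-n distribution — the right null for distributional tests
        (resampling from a small base sample truncates the upper tail).
        Requires an uncensored oracle whose size is a multiple of n.
        """
        if self.censored.any():
            raise ValueError("block maxima require an uncensored oracle")
        if self.passage_times.size % n:
            raise ValueError(
                f"oracle size {self.passage_times.size} is not a multiple of n={n}"
            )
        return self.passage_times.reshape(-1, n).max(axis=1)


def single_agent_oracle(
    landscape: QuarticLandscape,
    params: DynamicsParams,
    reps: int,
    master_seed,
) -> SingleAgentOracle:
    """Baseline distribution of lone-agent old->new first-passage times.

    Forces alpha = 0 (no peers exist for n = 1) and runs ``reps``
    independent single-agent simulations.
    """
    params0 = dataclasses.replace(params, alpha=0.0, m=None)
    res = run_replicates(landscape, params0, 1, reps, master_seed)
    return SingleAgentOracle(
        passage_times=res.shift_times,
        censored=res.censored,
        seeds=res.seeds,
        t_max=res.t_max,
    )


def km_mean_shift_time(result: ShiftTimeResult) -> float:
    """Kaplan–Meier (restricted) mean shift time honouring censored replicates.

    Alternative to the uncensored-only mean for heavily censored cells:
    censored replicates contribute their at-risk time up to t_max instead
    of being dropped.  The estimate is restricted at t_max, so it is a
    lower bound when censoring is present.
    """
    t = np.asarray(result.shift_times, dtype=float)
    event = ~np.asarray(result.censored, dtype=bool)
    order = np.argsort(t)
    t, event = t[order], event[order]
    at_risk = len(t)
    surv = 1.0
    mean = 0.0
    prev = 0.0
    for ti, ev in zip(t, event):
        mean += surv * (ti - prev)
        prev = ti
        if ev:
            surv *= 1.0 - 1.0 / at_risk
        at_risk -= 1
    return float(mean)
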