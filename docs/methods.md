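# Methods

## Model

A community of `n` agents searches a fixed one-dimensional
"physical-technological" landscape

    V(x) = a * ( -x (x + b)(x - c)(x - d) + e ),

an inverted double well whose two maxima are paradigms: the lower local
maximum `x_old` is the current paradigm, the higher global maximum
`x_new` the superior one, and the valley minimum `x_barrier` between
them is the transition cost.  The derivative factors as
`V'(x) = -gamma (x - x_new)(x - x_barrier)(x - x_old)` with
`gamma = 4a` exactly.  With the default coefficients
(`a = 1e-2, b = 2, c = 1, d = 6, e = 2e2`) the critical points are
`x_old ≈ -1.2684`, `x_barrier ≈ 0.5266`, `x_new ≈ 4.4918`; the escape
barrier seen from the old paradigm is `V(x_old) - V(x_barrier) ≈ 0.1875`
and the gain of the new paradigm is `V(x_new) - V(x_old) ≈ 1.3827`.
Critical points are always derived from `(a..e)` by solving the cubic
`V' = 0` (companion-matrix roots, two Newton polish steps); they are
never user-set, so the potential and its factored gradient cannot drift
apart.  `scaled_landscape` multiplies `a` and divides `e` by the same
factor, which rescales every height difference (in particular the
escape barrier) while leaving the critical points and `V(0)` unchanged.

Each agent `i` evolves by the Langevin equation

    dx_i/dt = (1 - alpha) * V'(x_i)
            + alpha * omega * (1/m) * sum_j [V(x_j) - V(x_i)] (x_j - x_i)
            + epsilon * xi(t),

a convex combination of individual hill climbing and social influence,
plus Gaussian white experimentation noise.  The social term attracts an
agent toward better-performing peers and repels it from worse ones; `m`
peers are resampled uniformly (without replacement, excluding self) for
every agent at every step.  With the default `m = n - 1` the sample is
the whole community and the drift is deterministic given positions.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `alpha` | weight on social influence | 0.15 | in [0, 1]; 0 = pure individual search |
| `omega` | social/individual strength ratio | 3.14 | dimensionless |
| `epsilon` | experimentation noise strength | 0.37 | sd of noise per unit sqrt(time) |
| `dt` | Euler–Maruyama step | 0.01 | convergence-tested (see below) |
| `m` | peers sampled per agent per step | `n - 1` | must satisfy 1 ≤ m ≤ n-1 |
| `t_max` | censoring horizon | 1e5 | model-time units |
| `arrival_delta` | arrival tolerance below `x_new` | 0.5 | agent arrives at `x ≥ x_new - arrival_delta` |
| `jitter_sd` | sd of initial-position jitter | 0 | robustness checks only |
| `n` | community size | 12 / 24 / 36 | sweep default |
| replicates | per parameter cell | 200 | sweep default |

All quantities are dimensionless; "time" is the unit of the continuous
equation, not a step count.

## Integration and conventions

**Scheme.**  Synchronous Euler–Maruyama: all drifts are evaluated at
pre-step positions, then `x_i += drift*dt + epsilon*sqrt(dt)*z_i` with
independent standard-normal `z_i`.  `xi(t)` is interpreted as
unit-intensity white noise multiplied by `epsilon`; the noise amplitude
is *not* modulated by `alpha`.  A stability guard rejects `dt` if
`|drift| * dt ≥ 0.5` at initialization, and any non-finite position
aborts the run.  Halving `dt` from 0.01 to 0.005 leaves the mean
single-agent first-passage time unchanged within Monte-Carlo error
(statistical check in the test suite); the O(dt) discretization bias is
below the few-percent level that matters for any claim made here.

**Initial condition.**  All agents start exactly at `x_old`
(optionally jittered by `jitter_sd`); this resolves "in the vicinity of
the current paradigm" in the most reproducible way.

**Arrival and shift time.**  An agent has *arrived* once it has ever
reached `x_new - arrival_delta`; the community shift time `t_s` is the
largest of the `n` first-arrival times.  Runs that reach `t_max` before
full arrival are *censored*: they are reported with `t_max` as a lower
bound and a flag, never imputed.  Cell means/SEs use uncensored
replicates only, with the censored count reported alongside; a
restricted Kaplan–Meier mean (`km_mean_shift_time`) is available for
heavily censored cells.

**No-return rule.**  Migration *from the new paradigm* back to the old
one is ruled out: an agent that has arrived and whose proposed position
would fall below `x_barrier` is reflected (`x -> 2*x_barrier - x`).
The latch deliberately triggers on *arrival*, not on first crossing of
the valley bottom.  A reflecting barrier armed on mere crossing turns
the valley bottom into a one-touch ratchet: a single lucky noise
excursion becomes irreversible, the conservative pull that the mass of
old-paradigm agents exerts on a pioneer is cut off, and the
characteristic non-monotone dependence of the shift time on `alpha`
(in particular the conservative maximum at intermediate-to-high
`alpha` and the recovery toward `alpha = 1`) disappears.  Arming the
rule on arrival preserves those dynamics while still making the
completed transition irreversible; measured shift times are in any case
determined by first arrivals.  The alternative (absorption at `x_new`)
would freeze arrived agents and weaken their attractive pull on
stragglers, which contradicts the follow-the-leader mechanism, so it
was not adopted.

**Randomness.**  Every public entry point takes an integer seed.
Per-replicate streams are spawned with `numpy.random.SeedSequence`
(replicate `r` of a batch depends only on the master seed and `r`;
sweep cells additionally key on the (n, alpha) grid indices), so
results are independent of execution order and reproducible
bit-for-bit.  The long-trajectory engine is a numba kernel drawing from
numba's Mersenne Twister; the documented numpy-level reference
(`em_step` and friends) uses a PCG64 `Generator`.  The two engines are
held together by tests: deterministic paths agree to machine precision
and one-step noise distributions are statistically indistinguishable;
bitwise cross-engine equality is not a goal.

## Experiments

`run_replicates` produces per-replicate shift times for one
`(alpha, n)` cell; `alpha_sweep` runs the full factorial grid and
reports per-cell mean, SE (replicate sd / sqrt(reps); shift-time
distributions are right-skewed, so a bootstrap CI is the better choice
when precision matters), replicate and censoring counts.

**Regime detection.**  The mean-shift-time curve versus `alpha` is
smoothed with a centered 3-point moving average (partial windows at the
edges) before any feature is read off, so Monte-Carlo jitter is not
classified as structure.  `regime_summary` finds the first interior
local minimum and the first subsequent interior local maximum, using a
tie-tolerant extremum rule (`≤` both neighbours, `<` at least one), and
declares the three-regime pattern (decrease, increase, decrease) only
if the curve also net-decreases into the minimum and net-decreases
after the maximum.  Absent patterns are reported as
`no-three-regime-structure` (monotone curve) or `inconclusive`; the
pattern is never forced.  The reported optimal `alpha` is the grid
argmin of the smoothed curve.

**Independence oracle.**  At `alpha = 0` the agents are independent, so
the community shift time must be distributed as the maximum of `n` iid
single-agent first-passage times.  `single_agent_oracle` supplies the
single-agent distribution; `block_community_times` turns `k*n` fresh
draws into `k` exact iid maxima (the right null for distributional
tests — bootstrap resampling from a small base sample truncates the
upper tail of the strongly right-skewed passage-time law and produces
spurious rejections), while `implied_community_times` provides the
cheaper bootstrap version for point summaries.

## What the simulator does and does not emulate

The generator's defaults are the published parameter world (landscape
coefficients, `epsilon = 0.37`, `omega = 3.14`, `n` in {12, 24, 36}
with `m = n - 1`, 200 replicates), so green tests establish that *this*
stated world has the claimed structure: a steep drop of the mean shift
time as soon as a small social weight is introduced, an optimum at a
small positive `alpha`, a conservative maximum at intermediate-to-high
`alpha`, recovery toward `alpha = 1`, longer times for larger highly
coupled communities, and longer times for deeper valleys.  They do not
establish anything about real scientific communities: agents are
memoryless and homogeneous, the landscape is one-dimensional, fixed and
agreed upon by all agents, interaction is well-mixed (no network
structure), and the absolute time unit is internal to the model.  The
original study's own integrator is unavailable, so absolute mean times
are not comparable across implementations — only shapes, orderings and
optimum locations are.  On this implementation's fine (0.025-spaced)
grid the smoothed optimum sits at `alpha = 0.075`, slightly below the
10–15% band quoted from coarser-grained summaries; on a 0.05-spaced
grid it sits at 0.10.

## Known limitations

- Peer-sampling cadence (fresh peers every step) is a convention; with
  the default `m = n - 1` it is moot.
- The kernel's Mersenne-Twister stream is seeded per replicate from a
  32-bit word; astronomically many replicates would eventually collide
  seeds (SeedSequence makes this negligible at realistic scales).
- Censored-aware means are restricted at `t_max`; with heavy censoring
  all location summaries are lower bounds.
- `FloatingPointError` from oversized steps is raised only when a
  position actually overflows to non-finite; pair it with the `dt`
  stability guard rather than relying on it alone.
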