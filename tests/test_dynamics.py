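"""Per-agent update rule, no-return convention, and trajectory simulation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from paradigmflow.dynamics import (
    CommunityState,
    DynamicsParams,
    apply_no_return,
    drift,
    em_step,
    initial_state,
    sample_peers,
    simulate_trajectory,
    social_influence,
)
from paradigmflow.landscape import gradient


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": -0.1},
            {"alpha": 1.5},
            {"epsilon": -1.0},
            {"dt": 0.0},
            {"t_max": -1.0},
            {"arrival_delta": 0.0},
            {"m": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DynamicsParams(**kwargs)

    def test_m_defaults_to_all_peers(self):
        assert DynamicsParams().resolve_m(12) == 11
        assert DynamicsParams(m=5).resolve_m(12) == 5

    def test_m_too_large_rejected(self):
        with pytest.raises(ValueError, match="m must satisfy"):
            DynamicsParams(m=12).resolve_m(12)


class TestSamplePeers:
    def test_full_sample_is_all_other_agents(self, rng):
        peers = sample_peers(rng, 12, 3, 11)
        assert sorted(peers) == [i for i in range(12) if i != 3]

    def test_two_agents_single_peer(self, rng):
        assert list(sample_peers(rng, 2, 0, 1)) == [1]

    def test_uniform_over_peers(self):
        rng = np.random.default_rng(7)
        draws = [sample_peers(rng, 3, 0, 1)[0] for _ in range(10_000)]
        freq = np.mean(np.asarray(draws) == 1)
        assert freq == pytest.approx(0.5, abs=0.02)

    def test_oversampling_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_peers(rng, 4, 0, 4)


class TestSocialInfluence:
    def test_single_worse_peer_repels(self, landscape):
        # (V(-1) - V(0)) * (-1 - 0) = (2.14 - 2.00) * (-1) = -0.14
        assert social_influence(landscape, 0.0, [-1.0]) == pytest.approx(-0.14, abs=1e-12)

    def test_mean_over_two_peers(self, landscape):
        # V(3) = 2.90: mean of (0.90 * 3) and (-0.14) is 1.28
        assert social_influence(landscape, 0.0, [-1.0, 3.0]) == pytest.approx(1.28, abs=1e-12)

    def test_identical_peers_exert_no_pull(self, landscape):
        assert social_influence(landscape, 1.3, [1.3, 1.3, 1.3]) == 0.0

    def test_empty_peer_set_rejected(self, landscape):
        with pytest.raises(ValueError, match="empty peer set"):
            social_influence(landscape, 0.0, [])


class TestDrift:
    def test_pure_individual_search(self, landscape):
        p = DynamicsParams(alpha=0.0)
        assert drift(landscape, p, 0.0, [5.0]) == pytest.approx(-0.12, abs=1e-14)

    def test_pure_social(self, landscape):
        p = DynamicsParams(alpha=1.0)
        assert drift(landscape, p, 0.0, [-1.0]) == pytest.approx(-0.4396, abs=1e-12)

    def test_vanishes_at_critical_point_with_identical_peers(self, landscape, cp):
        p = DynamicsParams(alpha=0.4)
        assert drift(landscape, p, cp.x_old, [cp.x_old] * 3) == pytest.approx(0.0, abs=1e-9)


class TestNoReturn:
    def _state(self, positions, crossed, arrived):
        return CommunityState(
            positions=np.asarray(positions, float),
            crossed=np.asarray(crossed, bool),
            arrived=np.asarray(arrived, bool),
        )

    def test_arrived_agent_reflected_at_valley_bottom(self, landscape, cp):
        state = self._state([cp.x_barrier - 0.1], [True], [True])
        out = apply_no_return(landscape, state)
        assert out.positions[0] == pytest.approx(cp.x_barrier + 0.1)

    def test_boundary_is_a_fixed_point(self, landscape, cp):
        state = self._state([cp.x_barrier], [True], [True])
        out = apply_no_return(landscape, state)
        assert out.positions[0] == cp.x_barrier

    def test_unarrived_agents_move_freely(self, landscape, cp):
        # a pioneer that crossed the valley but has not conquered the new
        # optimum can still be dragged back by its peers
        state = self._state([cp.x_old, cp.x_barrier - 0.2], [False, True], [False, False])
        out = apply_no_return(landscape, state)
        np.testing.assert_array_equal(out.positions, state.positions)


class TestEmStep:
    def test_critical_point_is_noise_free_fixed_point(self, landscape, cp):
        p = DynamicsParams(alpha=0.0, epsilon=0.0)
        state = initial_state(landscape, 4, p)
        out = em_step(landscape, p, state, np.random.default_rng(0))
        np.testing.assert_allclose(out.positions, state.positions, atol=1e-10)
        assert out.t == pytest.approx(p.dt)

    def test_single_deterministic_step_from_origin(self, landscape):
        p = DynamicsParams(alpha=0.0, epsilon=0.0, dt=0.1)
        state = CommunityState(
            positions=np.array([0.0]),
            crossed=np.array([False]),
            arrived=np.array([False]),
        )
        out = em_step(landscape, p, state, np.random.default_rng(0))
        assert out.positions[0] == pytest.approx(-0.012, abs=1e-15)

    def test_same_rng_state_reproduces_step(self, landscape):
        p = DynamicsParams(alpha=0.3, epsilon=0.37)
        state = initial_state(landscape, 6, p)
        a = em_step(landscape, p, state, np.random.default_rng(5))
        b = em_step(landscape, p, state, np.random.default_rng(5))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_permutation_equivariance(self, landscape):
        """Relabeling agents (with identically permuted noise) permutes the update."""
        p = DynamicsParams(alpha=0.7, epsilon=0.37)  # m = n-1: drift is deterministic
        x = np.array([-1.3, -0.5, 0.8, 2.5, 4.0])
        z = np.array([0.3, -1.2, 0.1, 0.9, -0.4])
        perm = np.array([4, 2, 0, 1, 3])
        state = CommunityState(
            positions=x, crossed=x > 0.5266, arrived=np.zeros(5, bool)
        )
        state_p = CommunityState(
            positions=x[perm], crossed=(x > 0.5266)[perm], arrived=np.zeros(5, bool)
        )
        rng = np.random.default_rng(0)
        out = em_step(landscape, p, state, rng, noise=z)
        out_p = em_step(landscape, p, state_p, rng, noise=z[perm])
        np.testing.assert_allclose(out_p.positions, out.positions[perm], atol=1e-14)

    def test_latches_are_monotone(self, landscape):
        p = DynamicsParams(alpha=0.15, epsilon=0.37)
        state = initial_state(landscape, 8, p)
        rng = np.random.default_rng(3)
        for _ in range(300):
            prev_crossed = state.crossed.copy()
            prev_arrived = state.arrived.copy()
            state = em_step(landscape, p, state, rng)
            assert np.all(state.crossed >= prev_crossed)
            assert np.all(state.arrived >= prev_arrived)
            assert np.all(state.crossed >= state.arrived)  # arrived implies crossed


class TestSimulateTrajectory:
    def test_fixed_seed_is_bit_reproducible(self, landscape):
        p = DynamicsParams(alpha=0.15, t_max=1e4)
        a = simulate_trajectory(landscape, p, 6, seed=11, record_every=50)
        b = simulate_trajectory(landscape, p, 6, seed=11, record_every=50)
        np.testing.assert_array_equal(a.position_matrix, b.position_matrix)
        np.testing.assert_array_equal(a.arrival_times, b.arrival_times)
        c = simulate_trajectory(landscape, p, 6, seed=12, record_every=50)
        assert not np.array_equal(a.arrival_times, c.arrival_times)

    def test_noise_free_community_never_arrives(self, landscape):
        """Without experimentation the community stays at the old optimum."""
        p = DynamicsParams(alpha=0.0, epsilon=0.0, t_max=50.0)
        rec = simulate_trajectory(landscape, p, 5, seed=0, record_every=0)
        assert rec.censored
        assert np.all(np.isinf(rec.arrival_times))
        assert rec.t_final == pytest.approx(50.0)

    @pytest.mark.parametrize("start, endpoint", [(-0.5, "x_old"), (2.0, "x_new")])
    def test_noise_free_basin_convergence(self, landscape, cp, start, endpoint):
        p = DynamicsParams(alpha=0.0, epsilon=0.0, t_max=1e3)
        rec = simulate_trajectory(
            landscape, p, 1, seed=0, record_every=1000,
            x0=np.array([start]), stop_on_arrival=False,
        )
        final = rec.position_matrix[-1, 0]
        assert final == pytest.approx(getattr(cp, endpoint), abs=1e-6)

    def test_deterministic_ascent_matches_fine_ode(self, landscape, cp):
        """Noise-free climb time from the valley agrees with a dense ODE solve."""
        p = DynamicsParams(alpha=0.0, epsilon=0.0, dt=0.01, t_max=200.0)
        target = cp.x_new - p.arrival_delta
        rec = simulate_trajectory(landscape, p, 1, seed=0, record_every=0, x0=np.array([2.0]))
        event = lambda t, y: y[0] - target
        event.terminal = True
        event.direction = 1
        sol = solve_ivp(
            lambda t, y: [gradient(landscape, y[0])], (0, 200.0), [2.0],
            events=event, rtol=1e-10, atol=1e-12, max_step=0.5,
        )
        t_ode = sol.t_events[0][0]
        assert rec.arrival_times[0] == pytest.approx(t_ode, rel=0.01)

    def test_crossed_latch_consistent_with_recorded_positions(self, landscape, cp):
        p = DynamicsParams(alpha=0.15, t_max=1e4)
        rec = simulate_trajectory(landscape, p, 6, seed=21, record_every=20)
        assert not rec.censored
        # every arrival time is within the simulated horizon
        assert np.all(rec.arrival_times <= rec.t_final + 1e-9)
        # at the first recorded sample at/after its arrival, each agent had
        # already reached the arrival region at some earlier instant, so it
        # must have crossed the valley bottom by then at the latest
        target = cp.x_new - p.arrival_delta
        for i in range(rec.n):
            hit = rec.position_matrix[:, i] >= target
            if hit.any():
                assert rec.sample_times[np.argmax(hit)] >= rec.arrival_times[i] - 1e-9

    def test_step_size_halving_leaves_mean_passage_time_stable(self, landscape):
        """Mean single-agent first-passage time is dt-converged at dt=0.01.

        Monte-Carlo error at feasible replicate counts is itself a few
        percent, so the check is statistical: the halved-dt mean must not
        differ from the dt=0.01 mean by more than 5% beyond two standard
        errors of the difference.
        """
        from paradigmflow.experiments import run_replicates

        reps = 400
        means, ses = [], []
        for dt in (0.01, 0.005):
            p = DynamicsParams(alpha=0.0, dt=dt)
            res = run_replicates(landscape, p, 1, reps, master_seed=77)
            means.append(res.mean())
            ses.append(res.se())
        diff = abs(means[0] - means[1])
        se_diff = np.hypot(*ses)
        assert diff <= 0.05 * means[0] + 2 * se_diff

    def test_oversized_dt_rejected(self, landscape):
        p = DynamicsParams(alpha=0.0, epsilon=0.0, dt=10.0, t_max=100.0)
        with pytest.raises(ValueError, match="dt too large"):
            simulate_trajectory(landscape, p, 1, seed=0, x0=np.array([7.0]))

    def test_jittered_initial_condition(self, landscape, cp):
        p = DynamicsParams(jitter_sd=0.05)
        state = initial_state(landscape, 100, p, rng=np.random.default_rng(1))
        assert np.std(state.positions) == pytest.approx(0.05, rel=0.3)
        assert np.mean(state.positions) == pytest.approx(cp.x_old, abs=0.02)


class TestKernelMatchesReference:
    def test_deterministic_paths_identical(self, landscape, cp):
        """Compiled kernel and numpy reference agree exactly without noise."""
        from paradigmflow import _kernel

        x0 = np.array([-1.3, -1.0, 0.0, 0.6, 2.0, 4.2])
        p = DynamicsParams(alpha=0.7, epsilon=0.0, dt=0.01)
        state = CommunityState(
            positions=x0.copy(),
            crossed=x0 > cp.x_barrier,
            arrived=x0 >= cp.x_new - p.arrival_delta,
        )
        rng = np.random.default_rng(0)
        for _ in range(200):
            state = em_step(landscape, p, state, rng)
        out = _kernel.simulate_kernel(
            landscape.potential_coeffs, landscape.gradient_coeffs,
            cp.x_barrier, cp.x_new - p.arrival_delta,
            0.7, p.omega, 0.0, 0.01, 5, True, 200, x0.copy(), 0, 1, False,
        )
        np.testing.assert_allclose(state.positions, out[0], atol=1e-12)
        np.testing.assert_array_equal(state.crossed, out[1])
        np.testing.assert_array_equal(state.arrived, out[2])

    def test_one_step_noise_distribution_agrees(self, landscape, cp):
        """Single-step position distributions from both engines coincide."""
        from paradigmflow import _kernel

        x0 = np.array([-1.2, 0.0, 1.5])
        p = DynamicsParams(alpha=0.5, epsilon=0.37, dt=0.01)
        reps = 1500
        kernel_pos = np.empty(reps)
        for r in range(reps):
            out = _kernel.simulate_kernel(
                landscape.potential_coeffs, landscape.gradient_coeffs,
                cp.x_barrier, cp.x_new - p.arrival_delta,
                0.5, p.omega, 0.37, 0.01, 2, True, 1, x0.copy(), 0, r, False,
            )
            kernel_pos[r] = out[0][0]
        rng = np.random.default_rng(1)
        ref_pos = np.empty(reps)
        state0 = CommunityState(
            positions=x0, crossed=x0 > cp.x_barrier, arrived=np.zeros(3, bool)
        )
        for r in range(reps):
            ref_pos[r] = em_step(landscape, p, state0, rng).positions[0]
        assert stats.ks_2samp(kernel_pos, ref_pos).pvalue > 0.001
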