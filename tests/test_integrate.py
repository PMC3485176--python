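"""Euler-Maruyama stepping, trajectories and steady-state detection."""

import numpy as np
import pytest

from ecosim import (
    IntegratorConfig,
    Parameters,
    Trajectory,
    initial_state,
    simulate,
    step,
    time_to_steady_state,
)


class TestStep:
    def test_zero_noise_is_explicit_euler(self, params, coculture_state):
        from ecosim import drift

        p = params.replace(noise_scale=0.0)
        draws = np.full(18, 3.0)  # arbitrary draws must not matter
        out = step(coculture_state, p, 0.005, draws)
        expected = coculture_state + drift(coculture_state, p) * 0.005
        np.testing.assert_allclose(out, np.clip(expected, 0, None), rtol=1e-14)

    def test_origin_is_absorbing(self, params):
        rng = np.random.default_rng(0)
        out = step(np.zeros(9), params, 0.01, rng.standard_normal(18))
        np.testing.assert_array_equal(out, 0.0)

    def test_first_order_decay_closed_form(self, params):
        # lone AHL1 pool with binding off: one Euler step is v*(1 - k11*dt)
        p = params.replace(k9=0.0, noise_scale=0.0)
        out = step(initial_state(AHL1=1000.0), p, 0.01, np.zeros(18))
        assert out[2] == pytest.approx(1000.0 * (1 - 1.19 * 0.01))

    def test_population_below_threshold_absorbs(self, params):
        p = params.replace(noise_scale=0.0, Gc=1e-5, alpha1=0.0, alpha2=0.0)
        state = initial_state(c1=1.01)
        out = step(state, p, 0.5, np.zeros(18))  # killed well below 1 cell
        assert out[0] == 0.0


class TestSimulate:
    def test_zero_noise_path_equals_deterministic_exactly(self, params,
                                                          coculture_state,
                                                          short_config):
        p0 = params.replace(noise_scale=0.0)
        sto = simulate(coculture_state, p0, short_config, mode="stochastic")
        det = simulate(coculture_state, params, short_config, mode="deterministic")
        np.testing.assert_array_equal(sto.states, det.states)

    def test_same_seed_bitwise_identical(self, params, coculture_state,
                                         short_config):
        a = simulate(coculture_state, params, short_config)
        b = simulate(coculture_state, params, short_config)
        np.testing.assert_array_equal(a.states, b.states)
        assert a.extinct_at == b.extinct_at

    def test_no_negative_component_across_seeds(self, params, coculture_state):
        for seed in range(5):
            cfg = IntegratorConfig(t_end=10.0, record_every=20, seed=seed)
            traj = simulate(coculture_state, params, cfg)
            assert np.all(traj.states >= 0)

    def test_baseline_coculture_persists_with_bacteria_on_top(self, params,
                                                              coculture_state):
        cfg = IntegratorConfig(t_end=50.0, record_every=100)
        traj = simulate(coculture_state, params, cfg, mode="deterministic")
        c1, c2 = traj.states[-1, 0], traj.states[-1, 1]
        assert c1 > 0 and c2 > 0
        assert c2 > c1  # fast growers dominate the reactor

    def test_yeast_monoculture_collapses_under_gc(self, params):
        cfg = IntegratorConfig(t_end=50.0, record_every=100)
        traj = simulate(initial_state(c1=5e4), params, cfg, mode="deterministic")
        assert traj.states[-1, 0] == 0.0

    def test_step_size_convergence_of_deterministic_endpoint(self, params,
                                                             coculture_state):
        ends = []
        for dt in (0.005, 0.0025):
            cfg = IntegratorConfig(t_end=50.0, dt=dt, record_every=1000)
            traj = simulate(coculture_state, params, cfg, mode="deterministic")
            ends.append(traj.states[-1, :2])
        rel = np.abs(ends[1] - ends[0]) / ends[1]
        assert np.all(rel < 0.005)

    def test_ensemble_mean_approaches_deterministic_as_noise_shrinks(
            self, params, coculture_state):
        from ecosim import run_ensemble

        cfg = IntegratorConfig(t_end=20.0, record_every=100, seed=11)
        det = simulate(coculture_state, params, cfg, mode="deterministic")
        gaps = []
        for eps in (0.1, 0.01):
            summary = run_ensemble(coculture_state,
                                   params.replace(noise_scale=eps), cfg, 20)
            gap = np.abs(summary.mean[-1, :2] - det.states[-1, :2])
            gaps.append(np.max(gap / det.states[-1, :2]))
        assert gaps[1] < gaps[0]

    def test_invalid_mode_rejected(self, params, coculture_state, short_config):
        with pytest.raises(ValueError):
            simulate(coculture_state, params, short_config, mode="exact")


class TestSteadyStateDetection:
    @staticmethod
    def _traj(times, c1, c2):
        states = np.zeros((len(times), 9))
        states[:, 0] = c1
        states[:, 1] = c2
        return Trajectory(times=np.asarray(times, float), states=states,
                          seed=0, mode="deterministic", extinct_at=None)

    def test_constant_trajectory_detected_at_first_window(self):
        t = np.arange(0, 30.05, 0.05)
        traj = self._traj(t, np.full_like(t, 100.0), np.full_like(t, 200.0))
        assert time_to_steady_state(traj, window=5.0) == pytest.approx(5.0)

    def test_growing_logistic_not_steady_until_saturation(self):
        t = np.arange(0, 100.05, 0.05)
        c = 1e9 / (1 + (1e9 / 1e3 - 1) * np.exp(-0.5 * t))
        traj = self._traj(t, c, c)
        tss = time_to_steady_state(traj)
        assert tss is not None and tss > 30.0  # saturation, not the growth phase

    def test_window_longer_than_trajectory_rejected(self):
        t = np.arange(0, 4.05, 0.05)
        traj = self._traj(t, np.ones_like(t), np.ones_like(t))
        with pytest.raises(ValueError):
            time_to_steady_state(traj, window=10.0)

    def test_baseline_ensemble_reaches_steady_state_in_under_a_day(
            self, params, coculture_state):
        from ecosim import run_ensemble

        cfg = IntegratorConfig(t_end=50.0, record_every=10, seed=0)
        summary = run_ensemble(coculture_state, params, cfg, 25)
        tss = time_to_steady_state(summary)
        assert tss is not None and 10.0 <= tss <= 25.0
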