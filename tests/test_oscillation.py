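"""Fixed points, eigenvalue stability, period estimation, noise scan."""

import numpy as np
import pytest

from ecosim import (
    IntegratorConfig,
    autocorrelation_period,
    find_fixed_point,
    initial_state,
    jacobian,
    oscillation_period,
    scan_bifurcation,
    simulate,
)
from ecosim import SearchError, drift


class TestFixedPoint:
    def test_origin_is_a_fixed_point(self, params):
        fp = find_fixed_point(params, np.zeros(9))
        assert np.all(fp < 1e-6)

    def test_interior_coexistence_point_from_long_run(self, params):
        # oracle: seed from the deterministic 200 h endpoint; the fast
        # directions (total population, molecular pools) must agree with the
        # trajectory, and the point must be a genuine root of the drift
        cfg = IntegratorConfig(t_end=200.0, record_every=1000)
        traj = simulate(initial_state(c1=5e4, c2=5e4), params, cfg,
                        mode="deterministic")
        end = traj.states[-1]
        assert end[1] > end[0] > 0  # observed quasi-steady state: bacteria on top
        fp = find_fixed_point(params, end)
        assert fp[0] > 0 and fp[1] > 0
        # drift vanishes relative to the one-way fluxes through each species
        from ecosim.oscillation import _turnover
        rel = np.abs(drift(fp, params)) / np.maximum(_turnover(fp, params),
                                                     1e-30)
        assert np.max(rel) < 1e-8
        # total population pins just below carrying capacity, as observed
        assert fp[0] + fp[1] == pytest.approx(end[0] + end[1], rel=1e-3)

    def test_no_interior_point_when_killing_overwhelms(self, params):
        # unresisted killing at 1 mM Gc exceeds any possible growth rate,
        # so no coexistence root exists anywhere in the positive orthant
        p = params.replace(Gc=1e-3, alpha1=0.0, alpha2=0.0)
        with pytest.raises(SearchError):
            from ecosim.oscillation import _interior_fixed_point
            _interior_fixed_point(p, initial_state(c1=1e6, c2=1e6), tol=1e-10)


class TestJacobian:
    def test_pure_decay_diagonal_entry(self, params):
        # with binding off, AHL1 decouples: dAHL1/dt = -k11*AHL1
        p = params.replace(k9=0.0)
        J, _ = jacobian(p, initial_state(AHL1=500.0))
        assert J[2, 2] == pytest.approx(-1.19, rel=1e-6)

    def test_logistic_reduction_matches_hand_derivative(self, params):
        # bacteria-only system with killing off: dc2/dt = k2*c2*(1-c2/cmax)
        p = params.replace(Gc=0.0, k5=0.0, d=0.0)
        c2 = 3e8
        J, _ = jacobian(p, initial_state(c2=c2))
        expected = p.k2 * (1 - 2 * c2 / p.cmax)
        assert J[1, 1] == pytest.approx(expected, rel=1e-6)

    def test_damped_regime_has_negative_leading_real_part(self, params):
        p = params.replace(d=0.25)
        cfg = IntegratorConfig(t_end=500.0, record_every=1000)
        traj = simulate(initial_state(c1=5e4, c2=5e4), p, cfg,
                        mode="deterministic")
        fp = find_fixed_point(p, traj.states[-1])
        _, eig = jacobian(p, fp)
        lam = eig[np.argmax(eig.real)]
        assert lam.real < 0 and abs(lam.imag) > 0  # damped spiral


class TestPeriodEstimators:
    def test_pure_sinusoid(self):
        t = np.arange(0, 400, 0.05)
        x = np.sin(2 * np.pi * t / 17.0)
        assert oscillation_period(x, 0.05) == pytest.approx(17.0, rel=0.01)

    def test_noisy_sinusoid(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 400, 0.05)
        x = np.sin(2 * np.pi * t / 17.0) + 0.3 * rng.standard_normal(len(t))
        assert oscillation_period(x, 0.05) == pytest.approx(17.0, rel=0.01)

    def test_flat_signal_has_no_period(self):
        rng = np.random.default_rng(2)
        with pytest.raises(SearchError):
            oscillation_period(rng.standard_normal(4000), 0.05)

    def test_fft_and_autocorrelation_agree_on_attractor(self, params):
        # deterministic limit cycle at d = 0.5: two independent estimators
        p = params.replace(d=0.5)
        cfg = IntegratorConfig(t_end=1000.0, record_every=10)
        traj = simulate(initial_state(c1=5e4, c2=5e4), p, cfg,
                        mode="deterministic")
        tail = traj.species("c1")[len(traj.times) // 2:]
        dt_rec = traj.times[1] - traj.times[0]
        fft_T = oscillation_period(tail, dt_rec)
        acf_T = autocorrelation_period(tail, dt_rec)
        assert fft_T == pytest.approx(acf_T, rel=0.02)
        # both populations share the period
        tail2 = traj.species("c2")[len(traj.times) // 2:]
        assert oscillation_period(tail2, dt_rec) == pytest.approx(fft_T, rel=0.02)


@pytest.fixture(scope="module")
def coarse_scan(params):
    return scan_bifurcation(params, [0.10, 0.25, 0.50, 0.80],
                            transient_horizon=1500.0)


class TestBifurcationScan:
    def test_regime_sequence_with_d(self, coarse_scan):
        assert coarse_scan.regimes == ["damped", "damped", "sustained",
                                       "extinct"]

    def test_hopf_between_damped_and_sustained(self, coarse_scan):
        assert coarse_scan.hopf_d == pytest.approx(0.50)  # coarse grid
        assert coarse_scan.extinction_d == pytest.approx(0.80)

    def test_sustained_row_has_period_and_amplitude(self, coarse_scan):
        i = coarse_scan.regimes.index("sustained")
        assert np.isfinite(coarse_scan.periods[i])
        amp = coarse_scan.amplitudes[i]
        assert amp[0, 1] > amp[0, 0] > 0  # c1 oscillates between min < max
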