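"""Rate laws, stoichiometry and parameter handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecosim import (
    STOICHIOMETRY,
    Parameters,
    drift,
    initial_state,
    noise_matrix,
    propensities,
)
from ecosim._kernels import _NZ_COEF, _NZ_REACTION, _NZ_SPECIES
from conftest import random_states


class TestPropensities:
    def test_hand_evaluated_rates(self, params):
        # Gc killing of a single unprotected yeast cell: k3*Gc*1 = 1.2/h
        a = propensities(initial_state(c1=1), params)
        assert a[2] == pytest.approx(4e6 * 3e-7)
        # AHL2 synthesis from a full reactor of bacteria: k5*c2 = 5e3/h
        a = propensities(initial_state(c2=1e9), params)
        assert a[5] == pytest.approx(5e-6 * 1e9)

    def test_logistic_growth_vanishes_at_capacity(self, params):
        a = propensities(initial_state(c1=4e8, c2=6e8), params)
        assert a[0] == 0.0 and a[1] == 0.0
        # and stays clamped (not negative) above capacity
        a = propensities(initial_state(c1=9e8, c2=9e8), params)
        assert a[0] == 0.0 and a[1] == 0.0

    def test_no_signal_no_binding_no_induction(self, params):
        a = propensities(initial_state(c1=5e4, c2=5e4), params)
        assert a[6] == 0.0 and a[7] == 0.0  # AHL2 = 0, C2 = 0

    def test_resistance_attenuates_killing(self, params):
        unprotected = propensities(initial_state(c1=100), params)[2]
        protected = propensities(initial_state(c1=100, Res1=10), params)[2]
        assert protected == pytest.approx(unprotected / (1 + 5e4 * 10))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegative_for_random_states(self, params, seed):
        state = random_states(1, seed=seed)[0]
        assert np.all(propensities(state, params) >= 0)

    def test_rejects_negative_state(self, params):
        bad = np.zeros(9)
        bad[3] = -1.0
        with pytest.raises(ValueError):
            propensities(bad, params)


class TestStoichiometry:
    def test_binding_consumes_two_signals_per_complex(self):
        assert STOICHIOMETRY[3, 6] == -2 and STOICHIOMETRY[5, 6] == 1
        assert STOICHIOMETRY[2, 9] == -2 and STOICHIOMETRY[4, 9] == 1

    def test_induction_is_catalytic(self):
        # reactions 8/11 produce preRes1/Res2 without consuming the complex
        assert list(STOICHIOMETRY[:, 7]) == [0, 0, 0, 0, 0, 0, 1, 0, 0]
        assert list(STOICHIOMETRY[:, 10]) == [0, 0, 0, 0, 0, 0, 0, 0, 1]

    def test_remaining_columns_single_unit_entry(self):
        for j in set(range(18)) - {6, 7, 8, 9, 10}:
            col = STOICHIOMETRY[:, j]
            assert np.sum(col != 0) == 1 and np.max(np.abs(col)) == 1

    def test_kernel_sparse_form_matches_matrix(self):
        dense = np.zeros_like(STOICHIOMETRY, dtype=float)
        for i, j, v in zip(_NZ_SPECIES, _NZ_REACTION, _NZ_COEF):
            dense[i, j] += v
        np.testing.assert_array_equal(dense, STOICHIOMETRY)


class TestDrift:
    def test_origin_is_a_fixed_point(self, params):
        np.testing.assert_array_equal(drift(np.zeros(9), params), 0.0)

    def test_lone_bacterial_cell_dies_under_gc(self, params):
        # a2 - a4 = k2*(1 - 1/cmax) - k3*Gc  (net death under 0.3 uM Gc)
        dc2 = drift(initial_state(c2=1), params)[1]
        assert dc2 == pytest.approx(0.936 * (1 - 1e-9) - 1.2)

    def test_signal_decay_rate(self, params):
        # with binding disabled, free AHL1 only decays: dAHL1/dt = -k11*AHL1
        no_binding = params.replace(k9=0.0)
        d = drift(initial_state(AHL1=100), no_binding)
        assert d[2] == pytest.approx(-1.19 * 100)
        assert np.all(d[np.arange(9) != 2] == 0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_drift_equals_per_reaction_accumulation(self, params, seed):
        # independent oracle: accumulate nu_ij * a_j reaction by reaction
        state = random_states(1, seed=seed)[0]
        a = propensities(state, params)
        expected = np.zeros(9)
        for j in range(18):
            for i in range(9):
                expected[i] += STOICHIOMETRY[i, j] * a[j]
        np.testing.assert_allclose(drift(state, params), expected, rtol=1e-12)


class TestNoiseMatrix:
    def test_zero_noise_scale_gives_zero_matrix(self, params):
        p = params.replace(noise_scale=0.0)
        state = random_states(1, seed=3)[0]
        np.testing.assert_array_equal(noise_matrix(state, p), 0.0)

    def test_entries_scale_linearly_with_noise_scale(self, params):
        state = random_states(1, seed=4)[0]
        full = noise_matrix(state, params)
        reduced = noise_matrix(state, params.replace(noise_scale=0.0125))
        np.testing.assert_allclose(reduced, 0.0125 * full, rtol=1e-12)

    def test_entry_is_stoichiometry_times_sqrt_rate(self, params):
        # AHL2 loses 2 per binding event: entry = -2 * sqrt(a7)
        state = initial_state(AHL2=1e4)
        a7 = propensities(state, params)[6]
        assert noise_matrix(state, params)[3, 6] == pytest.approx(-2 * np.sqrt(a7))


class TestParameters:
    def test_effective_constants_recomputed(self, params):
        assert params.k6_eff == pytest.approx(7.5e6)
        assert params.k9_eff == pytest.approx(7.5e6)
        assert params.k3_eff == pytest.approx(1.2)
        doubled = params.replace(AHLR2_conc=1e-6)
        assert doubled.k6_eff == pytest.approx(3e7)

    def test_monoculture_survival_closed_forms(self, params):
        # net growth changes sign at Gc = k/k3 for an unprotected culture
        assert params.k1 / params.k3 == pytest.approx(5.85e-8)
        assert params.k2 / params.k3 == pytest.approx(2.34e-7)

    @pytest.mark.parametrize(
        "bad",
        [{"k1": -0.1}, {"cmax": 0.0}, {"n1": 0.5}, {"noise_scale": 1.5},
         {"Gc": float("nan")}],
    )
    def test_validation_rejects_bad_values(self, bad):
        with pytest.raises(ValueError):
            Parameters(**bad)

    def test_alpha_unit_conversion_per_compartment(self, params):
        p = params.with_alpha(25.0, unit="nM^-1")
        assert p.alpha1 == pytest.approx(25.0 / (1e-9 * params.omega1))
        assert p.alpha2 == pytest.approx(25.0 / (1e-9 * params.omega2))
        same = params.with_alpha(5e4, unit="molecules")
        assert same.alpha1 == 5e4 and same.alpha2 == 5e4

    def test_dict_round_trip(self, params):
        assert Parameters.from_dict(params.to_dict()) == params
        with pytest.raises(ValueError):
            Parameters.from_dict({"k99": 1.0})
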