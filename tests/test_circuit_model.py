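"""Unit tests for the two-compartment PC / interneuron rate dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pecircuit as pz
from pecircuit.circuit_model import (DriveVectors, NetworkState, PCParams,
                                     calcium_event,
                                     dendritic_synaptic_input, integrate,
                                     rate_derivatives, somatic_synaptic_input,
                                     total_somatic_input)
from pecircuit.connectivity import PopulationSizes
from pecircuit.errors import ConfigurationError
from pecircuit import theory

ONE = PopulationSizes(1, 1, 1, 1)


def _single_unit_weights(**overrides):
    """1-neuron-per-population weight set with given effective strengths."""
    import pecircuit.connectivity as cn
    mats = {f"w_{pw}": np.zeros((1, 1)) for pw in cn.PATHWAYS}
    masks = {pw: np.ones((1, 1), dtype=bool) for pw in cn.PATHWAYS}
    for k, v in overrides.items():
        mats[f"w_{k}"] = np.array([[float(v)]])
    return cn.WeightSet(**mats, masks=masks)


class TestSynapticInputs:
    def test_soma_is_drive_minus_pv_inhibition(self):
        # with the standard non-plastic values: 28 - 2.8 * 2 = 22.4
        x = np.array([28.0])
        out = somatic_synaptic_input(x, np.array([2.0]), np.array([[2.8]]))
        assert out == pytest.approx(22.4)
        assert somatic_synaptic_input(x, np.zeros(1), np.array([[2.8]])) == 28.0

    def test_soma_may_go_negative_before_rectification(self):
        out = somatic_synaptic_input(np.zeros(1), np.array([3.0]), np.array([[1.0]]))
        assert out[0] < 0

    def test_dendrite_combines_motor_som_and_recurrence(self):
        # 0 - 3.5*2 + 0.42*1 = -6.58
        out = dendritic_synaptic_input(np.zeros(1), np.array([2.0]),
                                       np.array([1.0]), np.array([[3.5]]),
                                       np.array([[0.42]]))
        assert out == pytest.approx(-6.58)
        assert dendritic_synaptic_input(np.zeros(1), np.zeros(1), np.zeros(1),
                                        np.zeros((1, 1)), np.zeros((1, 1))) == 0.0
        out = dendritic_synaptic_input(np.array([5.0]), np.zeros(1), np.zeros(1),
                                       np.zeros((1, 1)), np.zeros((1, 1)))
        assert out == pytest.approx(5.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ConfigurationError):
            somatic_synaptic_input(np.zeros(2), np.zeros(3), np.zeros((2, 2)))


class TestCalciumEvent:
    @pytest.mark.parametrize("I_D0, expected", [(27.9, 0.0), (29.0, 7.0), (28.0, 0.0)])
    def test_threshold_convention(self, I_D0, expected):
        # H(0) = 0: a calcium event needs strictly suprathreshold input
        pc = PCParams()
        assert calcium_event(np.array([I_D0]), pc) == pytest.approx(expected)

    def test_inclusive_convention_is_configurable(self):
        pc = PCParams(strict_calcium_threshold=False)
        assert calcium_event(np.array([28.0]), pc) == pytest.approx(7.0)


class TestTotalSomaticInput:
    def test_excess_dendritic_inhibition_cannot_reach_soma(self):
        pc = PCParams()
        out = total_somatic_input(np.array([22.4]), np.array([-6.58]),
                                  np.zeros(1), pc)
        assert out == pytest.approx(0.27 * 0.0 + 0.69 * 22.4)

    def test_all_zero(self):
        assert total_somatic_input(np.zeros(1), np.zeros(1), np.zeros(1),
                                   PCParams()) == 0.0

    def test_rectification_disabled_variant(self):
        pc = PCParams(dendritic_rectification=False)
        out = total_somatic_input(np.array([22.4]), np.array([-6.58]),
                                  np.zeros(1), pc)
        assert out == pytest.approx(0.27 * (-6.58) + 0.69 * 22.4)


class TestRateDerivatives:
    def test_isolated_vip_fixed_point(self):
        ws = _single_unit_weights()
        state = NetworkState(np.zeros(1), np.zeros(1), np.zeros(1), np.array([4.0]))
        drives = DriveVectors.from_scalars(0, 0, 0, 0, 4.0, (1, 1, 1, 1))
        d = rate_derivatives(state, ws, drives)
        assert d[3] == pytest.approx(0.0)

    def test_pc_fixed_point_above_rheobase(self):
        # I = 15, theta = 14 -> [I - theta]_+ = 1 = r -> dr/dt = 0
        ws = _single_unit_weights()
        x_E = 15.0 / (1 - 0.31)  # so that (1 - lambda_E) x_E = 15
        state = NetworkState(np.array([1.0]), np.zeros(1), np.zeros(1), np.zeros(1))
        drives = DriveVectors.from_scalars(x_E, 0, 0, 0, 0, (1, 1, 1, 1))
        d = rate_derivatives(state, ws, drives)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_subthreshold_silent_pc_is_rectified(self):
        ws = _single_unit_weights()
        drives = DriveVectors.from_scalars(10.0, 0, 0, 0, 0, (1, 1, 1, 1))
        state = NetworkState(np.zeros(1), np.zeros(1), np.zeros(1), np.zeros(1))
        d = rate_derivatives(state, ws, drives)
        assert d[0] == 0.0


class TestIntegrate:
    def test_uncoupled_rates_converge_to_drives(self):
        ws = _single_unit_weights()
        drives = DriveVectors.from_scalars(30.0, 0.0, 3.0, 1.5, 2.5, (1, 1, 1, 1))
        state, _ = integrate(NetworkState.zeros(1, 1, 1, 1), ws, drives,
                             dt=0.1, duration=2000.0)
        assert state.r_E == pytest.approx((1 - 0.31) * 30.0 - 14.0, rel=1e-6)
        assert state.r_P == pytest.approx(3.0, rel=1e-6)
        assert state.r_S == pytest.approx(1.5, rel=1e-6)
        assert state.r_V == pytest.approx(2.5, rel=1e-6)

    def test_default_network_baseline_operating_point(self, nonplastic_net):
        ws, background = nonplastic_net
        state, _ = integrate(NetworkState.zeros(*ws.sizes.as_tuple()), ws,
                             background, dt=0.1, duration=3000.0)
        assert state.r_E.mean() == pytest.approx(1.0, abs=1e-4)
        assert state.r_P.mean() == pytest.approx(2.0, abs=1e-4)
        assert state.r_S.mean() == pytest.approx(2.0, abs=1e-4)
        assert state.r_V.mean() == pytest.approx(4.0, abs=1e-4)

    def test_halving_dt_changes_steady_state_below_1e6(self, nonplastic_net):
        ws, background = nonplastic_net
        s1, _ = integrate(NetworkState.zeros(*ws.sizes.as_tuple()), ws,
                          background, dt=0.2, duration=2000.0)
        s2, _ = integrate(NetworkState.zeros(*ws.sizes.as_tuple()), ws,
                          background, dt=0.1, duration=2000.0)
        assert np.allclose(s1.r_E, s2.r_E, rtol=1e-6, atol=1e-9)

    def test_rk2_error_scales_quadratically(self):
        # transient error of a linear relaxation after a fixed time
        ws = _single_unit_weights()
        drives = DriveVectors.from_scalars(0, 0, 5.0, 0, 0, (1, 1, 1, 1))
        errs = []
        for dt in (1.0, 0.5):
            state, _ = integrate(NetworkState.zeros(1, 1, 1, 1), ws, drives,
                                 dt=dt, duration=4.0)
            exact = 5.0 * (1 - np.exp(-4.0 / 2.0))
            errs.append(abs(state.r_P[0] - exact))
        assert errs[1] < errs[0] / 3.0  # ~4x for a 2nd-order scheme

    def test_dt_outside_window_rejected_unless_overridden(self, nonplastic_net):
        ws, background = nonplastic_net
        st0 = NetworkState.zeros(*ws.sizes.as_tuple())
        with pytest.raises(ConfigurationError):
            integrate(st0, ws, background, dt=5.0, duration=10.0)
        integrate(st0, ws, background, dt=5.0, duration=10.0, allow_any_dt=True)

    def test_kernel_and_numpy_paths_agree(self, nonplastic_net):
        from pecircuit import _kernels
        if not _kernels.HAVE_NUMBA:
            pytest.skip("numba not installed; single path only")
        ws, background = nonplastic_net
        st0 = NetworkState.zeros(*ws.sizes.as_tuple())
        _, tr_np = integrate(st0, ws, background, dt=0.5, duration=300.0,
                             engine="numpy")
        _, tr_nb = integrate(st0, ws, background, dt=0.5, duration=300.0,
                             engine="auto")
        for fld in ("time", "r_E", "r_P", "r_S", "r_V", "I_E_syn",
                    "I_D_syn", "I_D0", "calcium"):
            np.testing.assert_allclose(getattr(tr_np, fld),
                                       getattr(tr_nb, fld), atol=1e-12)


class TestInvariants:
    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0, 40), st.floats(0, 10))
    def test_rates_nonnegative_everywhere(self, seed, x_E, x_I):
        """Every recorded rate of every population stays >= 0, whatever the
        drives and random connectivity."""
        rng = np.random.default_rng(seed)
        cfg = pz.InputConfiguration()
        ws = pz.default_plastic_weights(cfg, PopulationSizes(10, 4, 4, 4),
                                        rng_seed=rng.integers(2**31))
        drives = DriveVectors.from_scalars(x_E, 0.0, x_I, x_I, x_I, (10, 4, 4, 4))
        _, tr = integrate(NetworkState.zeros(10, 4, 4, 4), ws, drives,
                          dt=0.5, duration=300.0)
        for fld in ("r_E", "r_P", "r_S", "r_V"):
            assert getattr(tr, fld).min() >= 0.0

    def test_dendritic_contribution_nonnegative_with_bracket(self, nonplastic_net):
        """With the rectification active, the dendritic term entering the
        soma is [I_D_syn + c]_+ >= 0 at all recorded times."""
        ws, background = nonplastic_net
        _, tr = integrate(NetworkState.zeros(*ws.sizes.as_tuple()), ws,
                          background, dt=0.5, duration=500.0)
        assert np.all(np.maximum(tr.I_D_syn + tr.calcium, 0.0) >= 0.0)
        # and at this operating point the dendrite is rectified-silent
        assert np.all(tr.I_D_syn[-1] < 0.0)

    def test_steady_state_matches_linear_oracle(self, nonplastic_net):
        ws, background = nonplastic_net
        state, _ = integrate(NetworkState.zeros(*ws.sizes.as_tuple()), ws,
                             background, dt=0.1, duration=3000.0)
        rates, ok = theory.find_steady_state(ws, background)
        assert ok
        np.testing.assert_allclose(state.r_E, rates["r_E"], rtol=1e-6)
        np.testing.assert_allclose(state.r_V, rates["r_V"], rtol=1e-6)
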