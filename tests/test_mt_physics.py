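"""Two-pool pulsed-MT signal model: lineshapes, pulse power, steady state."""

import numpy as np
import pytest

from mpfkit.mt_physics import (MTPulse, SPGRProtocol, TwoPoolParams,
                               lineshape, mt_spgr_steady_state,
                               omega1_rms_from_pulse, r1f_from_observed,
                               saturation_rates, spgr_signal)

from oracles import (gaussian_pulse_w1rms, mt_spgr_timestepping,
                     superlorentzian_adaptive)


def _params(f=0.13, r1_obs=0.55, R=19.0, r1b=1.0, t2b=10e-6, pd=1.0):
    r1f = r1f_from_observed(r1_obs, f, R, r1b)
    return TwoPoolParams(f=f, R1F=r1f, R1B=r1b, T2F=0.022 / r1f, T2B=t2b,
                         R=R, PD=pd)


class TestLineshape:
    def test_lorentzian_on_resonance_closed_form(self):
        assert lineshape(0.0, 0.022, kind="lorentzian") == pytest.approx(
            0.022 / np.pi, rel=1e-12)

    def test_super_lorentzian_is_even(self):
        g_pos = lineshape(4500.0, 10e-6)
        g_neg = lineshape(-4500.0, 10e-6)
        assert g_pos == pytest.approx(g_neg, rel=0, abs=0)

    @pytest.mark.parametrize("delta,t2b", [(4500.0, 10e-6), (1500.0, 10e-6),
                                           (9000.0, 12e-6)])
    def test_super_lorentzian_matches_adaptive_quadrature(self, delta, t2b):
        g = float(lineshape(delta, t2b))
        assert g == pytest.approx(superlorentzian_adaptive(delta, t2b),
                                  rel=1e-4)
        assert g > 0

    def test_super_lorentzian_rejects_near_resonance(self):
        with pytest.raises(ValueError):
            lineshape(500.0, 10e-6)

    def test_quadrature_converged(self):
        g1 = float(lineshape(4500.0, 10e-6, quad_nodes=256))
        g2 = float(lineshape(4500.0, 10e-6, quad_nodes=512))
        assert abs(g1 - g2) / g2 < 1e-6


class TestPulsePower:
    def test_rectangular_closed_form(self):
        p = MTPulse(shape="rectangular", duration=0.010, effective_flip=900.0)
        assert omega1_rms_from_pulse(p) == pytest.approx(
            np.deg2rad(900.0) / 0.010, rel=1e-12)

    def test_zero_flip_gives_zero_power(self):
        p = MTPulse(shape="rectangular", duration=0.010, effective_flip=0.0)
        assert omega1_rms_from_pulse(p) == 0.0

    def test_gaussian_matches_dense_quadrature(self):
        p = MTPulse(shape="gaussian", duration=0.010, effective_flip=900.0)
        assert omega1_rms_from_pulse(p) == pytest.approx(
            gaussian_pulse_w1rms(900.0, 0.010), rel=1e-4)

    def test_gaussian_exceeds_rectangular_power(self):
        # the peaked envelope needs more RMS power for the same area
        g = omega1_rms_from_pulse(MTPulse(shape="gaussian"))
        r = omega1_rms_from_pulse(MTPulse(shape="rectangular"))
        assert g > r


class TestSaturationRates:
    def test_zero_amplitude(self):
        w_f, w_b = saturation_rates(0.0, 4500.0, 0.04, 10e-6)
        assert w_f == 0 and w_b == 0

    def test_quadratic_scaling(self):
        w_f1, w_b1 = saturation_rates(1000.0, 4500.0, 0.04, 10e-6)
        w_f2, w_b2 = saturation_rates(2000.0, 4500.0, 0.04, 10e-6)
        assert w_f2 == pytest.approx(4 * w_f1, rel=1e-12)
        assert w_b2 == pytest.approx(4 * w_b1, rel=1e-12)

    def test_protocol_values_match_direct_formula(self):
        w1 = 2049.0
        w_f, w_b = saturation_rates(w1, 4500.0, 0.04, 10e-6)
        g_f = (0.04 / np.pi) / (1 + (2 * np.pi * 4500.0 * 0.04) ** 2)
        assert w_f == pytest.approx(np.pi * w1 ** 2 * g_f, rel=1e-10)
        assert w_b == pytest.approx(
            np.pi * w1 ** 2 * superlorentzian_adaptive(4500.0, 10e-6),
            rel=1e-4)


class TestSPGRSignal:
    def test_zero_flip_zero_signal(self):
        assert spgr_signal(1.0, 0.5, 0.0, 0.016) == 0.0

    def test_full_recovery_limit(self):
        s = spgr_signal(1.0, 100 / 0.016, 16.0, 0.016)
        assert s == pytest.approx(np.sin(np.deg2rad(16.0)), rel=1e-10)

    def test_direct_evaluation(self):
        a = np.deg2rad(16.0)
        e1 = np.exp(-0.016 * 0.5)
        expected = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
        assert spgr_signal(1.0, 0.5, 16.0, 0.016) == pytest.approx(
            expected, rel=1e-12)


class TestR1FFromObserved:
    def test_uncoupled_when_f_zero(self):
        assert r1f_from_observed(0.55, 0.0, 19.0, 1.0) == pytest.approx(0.55)

    def test_uncoupled_when_no_exchange(self):
        assert r1f_from_observed(0.55, 0.13, 0.0, 1.0) == pytest.approx(0.55)

    def test_slow_eigenvalue_round_trip(self):
        f, R, r1b, r1_obs = 0.13, 19.0, 1.0, 0.55
        r1f = r1f_from_observed(r1_obs, f, R, r1b)
        k_f, k_b = R * f, R * (1 - f)
        a = np.array([[-(r1f + k_f), k_b], [k_f, -(r1b + k_b)]])
        slow = -max(np.linalg.eigvals(a))
        assert slow == pytest.approx(r1_obs, abs=1e-10)

    def test_inconsistent_constraints_error(self):
        with pytest.raises(ValueError):
            r1f_from_observed(25.0, 0.13, 19.0, 1.0)


class TestSteadyState:
    def test_single_pool_reduction(self, mt_protocol):
        """With f=0 and no saturation the two-pool fixed point is the Ernst
        signal of the free pool."""
        prot = SPGRProtocol(TR=mt_protocol.TR, flip=mt_protocol.flip,
                            mt_pulse=None)
        params = TwoPoolParams(f=0.0, R1F=0.55, R1B=1.0, T2F=0.04,
                               T2B=10e-6, R=19.0, PD=2.0)
        s = mt_spgr_steady_state(params, prot, b1_scale=0.9)
        expected = spgr_signal(2.0, 0.55, prot.flip * 0.9, prot.TR)
        assert s == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("f", [0.0, 0.05, 0.10, 0.15, 0.25])
    @pytest.mark.parametrize("r1", [0.3, 0.5, 1.0])
    def test_fixed_point_equals_iteration(self, f, r1, mt_protocol):
        params = _params(f=f, r1_obs=r1)
        closed = mt_spgr_steady_state(params, mt_protocol, b0_offset=30.0,
                                      b1_scale=0.95)
        iterated = mt_spgr_timestepping(params, mt_protocol, b0_offset=30.0,
                                        b1_scale=0.95, n_tr=2000)
        assert closed == pytest.approx(iterated, rel=1e-6)

    def test_saturation_reduces_signal(self, mt_protocol):
        params = _params()
        prot_off = SPGRProtocol(TR=mt_protocol.TR, flip=mt_protocol.flip,
                                mt_pulse=None)
        s_on = mt_spgr_steady_state(params, mt_protocol)
        s_off = mt_spgr_steady_state(params, prot_off)
        assert s_on < s_off

    def test_signal_strictly_decreasing_in_f(self, mt_protocol):
        fs = np.linspace(0.0, 0.4, 41)
        sig = [mt_spgr_steady_state(_params(f=f), mt_protocol) for f in fs]
        assert np.all(np.diff(sig) < 0)

    def test_signal_nonnegative_and_linear_in_pd(self, mt_protocol):
        s1 = mt_spgr_steady_state(_params(pd=1.0), mt_protocol)
        s3 = mt_spgr_steady_state(_params(pd=3.0), mt_protocol)
        assert s1 >= 0
        assert s3 == pytest.approx(3 * s1, rel=1e-12)

    def test_vectorized_matches_scalar(self, mt_protocol):
        fs = np.array([0.05, 0.13, 0.25])
        params = _params(f=fs)
        vec = mt_spgr_steady_state(params, mt_protocol)
        for i, f in enumerate(fs):
            assert vec[i] == pytest.approx(
                mt_spgr_steady_state(_params(f=f), mt_protocol), rel=1e-12)


class TestDomainTypes:
    def test_pulse_rejects_near_resonance_offset(self):
        with pytest.raises(ValueError):
            MTPulse(offset=500.0)

    def test_protocol_requires_tr_beyond_pulse(self):
        with pytest.raises(ValueError):
            SPGRProtocol(TR=0.005, flip=9.0, mt_pulse=MTPulse())

    def test_params_invariants(self):
        with pytest.raises(ValueError):
            TwoPoolParams(f=0.6, R1F=1.0, R1B=1.0, T2F=0.04, T2B=1e-5,
                          R=19.0).validate()
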