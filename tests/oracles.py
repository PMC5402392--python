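"""Independent reference implementations used as oracles by the test suite.

These deliberately avoid the package's vectorized code paths: matrix
exponentials come from scipy.linalg.expm on explicit (augmented) matrices,
integrals from adaptive quadrature, and steady states from long time-stepping
rather than fixed-point solves.
"""

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm

from mpfkit.mt_physics import MTPulse, SPGRProtocol, TwoPoolParams


def superlorentzian_adaptive(delta: float, t2b: float) -> float:
    """Super-Lorentzian lineshape by adaptive quadrature, split at the
    integrable singularity u = 1/sqrt(3)."""

    def integrand(u):
        x = 3.0 * u * u - 1.0
        return (t2b / abs(x)) * np.exp(-2.0 * (2 * np.pi * delta * t2b / x) ** 2)

    v1, _ = quad(integrand, 0.0, 1.0 / np.sqrt(3.0), limit=400)
    v2, _ = quad(integrand, 1.0 / np.sqrt(3.0), 1.0, limit=400)
    return np.sqrt(2.0 / np.pi) * (v1 + v2)


def gaussian_pulse_w1rms(flip_deg: float, tm: float, n: int = 200001) -> float:
    """Dense-trapezoid RMS amplitude of the truncated-Gaussian pulse."""
    t = np.linspace(0.0, tm, n)
    sigma = tm / 6.0
    env = np.exp(-0.5 * ((t - tm / 2.0) / sigma) ** 2)
    peak = np.deg2rad(flip_deg) / np.trapezoid(env, t)
    return float(np.sqrt(np.trapezoid((peak * env) ** 2, t) / tm))


def _segment_propagator(params: TwoPoolParams, w_f: float, w_b: float,
                        t: float):
    """(E, b) of the augmented 3x3 exponential for one evolution segment."""
    f, R = params.f, params.R
    k_f, k_b = R * f, R * (1.0 - f)
    a = np.array([[-(params.R1F + k_f + w_f), k_b],
                  [k_f, -(params.R1B + k_b + w_b)]])
    src = np.array([params.R1F * params.PD * (1.0 - f),
                    params.R1B * params.PD * f])
    m = np.zeros((3, 3))
    m[:2, :2] = a
    m[:2, 2] = src
    e = expm(m * t)
    return e[:2, :2], e[:2, 2]


def mt_spgr_timestepping(params: TwoPoolParams, protocol: SPGRProtocol,
                         b0_offset: float = 0.0, b1_scale: float = 1.0,
                         n_tr: int = 2000) -> float:
    """Brute-force steady state: iterate the TR cycle from thermal
    equilibrium for ``n_tr`` repetitions."""
    from mpfkit.mt_physics import lineshape, omega1_rms_from_pulse

    pulse = protocol.mt_pulse
    if pulse is not None and pulse.effective_flip > 0:
        w1 = omega1_rms_from_pulse(pulse) * b1_scale
        delta_eff = pulse.offset + b0_offset
        w_f = np.pi * w1 ** 2 * lineshape(delta_eff, params.T2F,
                                          kind="lorentzian")
        w_b = np.pi * w1 ** 2 * float(lineshape(delta_eff, params.T2B,
                                                kind="super_lorentzian"))
        t_m = pulse.duration
    else:
        w_f = w_b = 0.0
        t_m = 0.0
    e_sat, b_sat = _segment_propagator(params, w_f, w_b, t_m)
    e_free, b_free = _segment_propagator(params, 0.0, 0.0, protocol.TR - t_m)
    alpha = np.deg2rad(protocol.flip) * b1_scale
    c = np.diag([np.cos(alpha), 1.0])
    m = np.array([params.PD * (1.0 - params.f), params.PD * params.f])
    for _ in range(n_tr):
        m = e_free @ (c @ (e_sat @ m + b_sat)) + b_free
    m_ex = e_sat @ m + b_sat
    return float(np.sin(alpha) * m_ex[0])
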