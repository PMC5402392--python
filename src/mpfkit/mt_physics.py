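"""Two-pool pulsed magnetization-transfer signal model for spoiled gradient echo.

The tissue is modelled as two exchanging proton pools: a free (liquid) pool F
and a semi-solid macromolecular (bound) pool B holding a fraction ``f`` of the
total equilibrium magnetization (the macromolecular proton fraction, MPF).
Longitudinal magnetization evolves under relaxation, cross-relaxation with
rate constant ``R`` (forward rate ``R*f`` out of F, reverse ``R*(1-f)`` out of
B), and — during an off-resonance saturation pulse — pool-specific saturation
rates derived from the pulse RMS amplitude and the pools' absorption
lineshapes (Lorentzian for the liquid pool, super-Lorentzian for the
semi-solid pool).

The steady-state MT-weighted SPGR signal is obtained as the fixed point of the
affine per-TR propagator: saturation pulse of duration ``t_m`` -> instantaneous
excitation acting on the free pool only -> free relaxation-exchange for the
remainder of TR.  Ideal spoiling is assumed.  All functions broadcast over
numpy arrays so that whole volumes can be evaluated in one call.

Unit conventions: frequency offsets in Hz and flip angles in degrees at the
interface; angular frequencies (rad/s) internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "TwoPoolParams",
    "MTPulse",
    "SPGRProtocol",
    "lineshape",
    "omega1_rms_from_pulse",
    "saturation_rates",
    "spgr_signal",
    "r1f_from_observed",
    "mt_spgr_steady_state",
]

#: minimum off-resonance (Hz) at which the super-Lorentzian model is applied;
#: closer to resonance the powder-average integral diverges.
SUPER_LORENTZIAN_MIN_OFFSET_HZ = 1000.0


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class TwoPoolParams:
    """Biophysical parameters of the two-pool MT system (scalar or voxelwise).

    Attributes
    ----------
    f : macromolecular proton fraction, 0 <= f < 0.5.
    R1F, R1B : longitudinal rates of the free/bound pool, 1/s.
    T2F, T2B : transverse relaxation times of the free/bound pool, s.
    R : cross-relaxation rate constant, 1/s (k_FB = R*f, k_BF = R*(1-f)).
    PD : proton density (total equilibrium magnetization), arbitrary units.
    """

    f: float | np.ndarray
    R1F: float | np.ndarray
    R1B: float | np.ndarray
    T2F: float | np.ndarray
    T2B: float | np.ndarray
    R: float | np.ndarray
    PD: float | np.ndarray = 1.0

    def validate(self) -> None:
        f = np.asarray(self.f)
        if np.any(f < 0) or np.any(f >= 0.5):
            raise ValueError("f must satisfy 0 <= f < 0.5")
        for name in ("R1F", "R1B", "T2F", "T2B"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        if np.any(np.asarray(self.R) < 0):
            raise ValueError("R must be non-negative")
        if np.any(np.asarray(self.PD) < 0):
            raise ValueError("PD must be non-negative")


@dataclass(frozen=True)
class MTPulse:
    """Off-resonance saturation pulse described by its integrated flip angle.

    ``effective_flip`` is the time integral of omega1 expressed as an angle in
    degrees; ``offset`` is the carrier offset from water resonance in Hz.
    """

    shape: str = "gaussian"  # {"gaussian", "rectangular"}
    duration: float = 0.010  # s
    effective_flip: float = 900.0  # degrees
    offset: float = 4500.0  # Hz

    def __post_init__(self):
        if self.shape not in ("gaussian", "rectangular"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if abs(self.offset) < SUPER_LORENTZIAN_MIN_OFFSET_HZ:
            raise ValueError(
                "saturation offset must be at least "
                f"{SUPER_LORENTZIAN_MIN_OFFSET_HZ} Hz off resonance"
            )


@dataclass(frozen=True)
class SPGRProtocol:
    """Spoiled gradient-echo sequence parameters.

    ``TEs`` is only used by the dual-echo B0 mapping sequence; the magnitude
    model ignores TE decay because TE is identical across the quantitative
    sequences.
    """

    TR: float  # s
    flip: float  # degrees
    TEs: tuple = ()
    mt_pulse: Optional[MTPulse] = None
    label: str = ""

    def __post_init__(self):
        if not (0 < self.flip <= 90):
            raise ValueError("readout flip angle must be in (0, 90] degrees")
        if self.mt_pulse is not None and self.TR <= self.mt_pulse.duration:
            raise ValueError("TR must exceed the saturation pulse duration")


# --------------------------------------------------------------------------
# lineshapes
# --------------------------------------------------------------------------

# Gauss-Legendre nodes/weights on [0, 1], cached per node count.
_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_legendre_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_CACHE:
        x, w = np.polynomial.legendre.leggauss(n)
        _GL_CACHE[n] = (0.5 * (x + 1.0), 0.5 * w)
    return _GL_CACHE[n]


def lineshape(delta, t2, kind: str = "super_lorentzian", quad_nodes: int = 256):
    """Absorption lineshape value g(delta) in seconds.

    ``super_lorentzian`` powder-averages a Gaussian lineshape over fibre
    orientations,

        g(d) = sqrt(2/pi) * int_0^1 T2B/|3u^2-1| *
               exp(-2 * (2 pi d T2B / (3u^2-1))^2) du,

    evaluated by fixed Gauss-Legendre quadrature (the integrand is smooth off
    resonance; on-resonance the integral diverges, hence the offset floor).
    ``lorentzian`` is the liquid-pool closed form
    g(d) = (T2/pi) / (1 + (2 pi d T2)^2).
    """
    delta = np.asarray(delta, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("t2 must be positive")
    if kind == "lorentzian":
        return (t2 / np.pi) / (1.0 + (2.0 * np.pi * delta * t2) ** 2)
    if kind != "super_lorentzian":
        raise ValueError(f"unknown lineshape kind {kind!r}")
    if np.any(np.abs(delta) < SUPER_LORENTZIAN_MIN_OFFSET_HZ):
        raise ValueError(
            "super-Lorentzian lineshape is only evaluated for offsets "
            f">= {SUPER_LORENTZIAN_MIN_OFFSET_HZ} Hz"
        )
    u, w = _gauss_legendre_01(quad_nodes)
    out = np.zeros(np.broadcast_shapes(delta.shape, t2.shape))
    two_pi_d_t2 = 2.0 * np.pi * delta * t2
    # accumulate over nodes to keep memory at one volume per node
    for ui, wi in zip(u, w):
        x = 3.0 * ui * ui - 1.0
        out += wi * (t2 / abs(x)) * np.exp(-2.0 * (two_pi_d_t2 / x) ** 2)
    return np.sqrt(2.0 / np.pi) * out


# --------------------------------------------------------------------------
# saturation pulse power
# --------------------------------------------------------------------------

def omega1_rms_from_pulse(pulse: MTPulse, n_samples: int = 512) -> float:
    """RMS angular amplitude (rad/s) of the saturation pulse over its duration.

    The Gaussian envelope uses sigma = t_m/6 (truncated at +/-3 sigma) and is
    scaled so that the integral of omega1(t) equals the effective flip angle.
    """
    if pulse.effective_flip < 0:
        raise ValueError("effective flip must be non-negative")
    flip_rad = np.deg2rad(pulse.effective_flip)
    tm = pulse.duration
    if pulse.shape == "rectangular":
        return flip_rad / tm
    t = np.linspace(0.0, tm, n_samples)
    sigma = tm / 6.0
    envelope = np.exp(-0.5 * ((t - tm / 2.0) / sigma) ** 2)
    area = np.trapezoid(envelope, t)
    w1 = (flip_rad / area) * envelope
    return float(np.sqrt(np.trapezoid(w1 ** 2, t) / tm))


def saturation_rates(omega1_rms, delta_eff, t2f, t2b, quad_nodes: int = 256):
    """Mean saturation rates (W_F, W_B) in 1/s during the pulse.

    W_B uses the super-Lorentzian lineshape of the semi-solid pool, W_F the
    Lorentzian lineshape of the liquid pool; both scale with the square of the
    RMS pulse amplitude.
    """
    omega1_rms = np.asarray(omega1_rms, dtype=float)
    power = np.pi * omega1_rms ** 2
    w_f = power * lineshape(delta_eff, t2f, kind="lorentzian")
    w_b = power * lineshape(delta_eff, t2b, kind="super_lorentzian",
                            quad_nodes=quad_nodes)
    return w_f, w_b


# --------------------------------------------------------------------------
# single-pool SPGR (Ernst) signal
# --------------------------------------------------------------------------

def spgr_signal(pd, r1, flip, tr):
    """Ernst steady-state SPGR signal S = PD sin(a) (1-E1)/(1-E1 cos(a))."""
    if np.any(np.asarray(tr) <= 0):
        raise ValueError("TR must be positive")
    flip = np.asarray(flip, dtype=float)
    if np.any(flip < 0) or np.any(flip > 90):
        raise ValueError("flip angle must be in [0, 90] degrees")
    a = np.deg2rad(flip)
    e1 = np.exp(-np.asarray(tr, dtype=float) * np.asarray(r1, dtype=float))
    return pd * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


# --------------------------------------------------------------------------
# single-point constraint machinery
# --------------------------------------------------------------------------

def r1f_from_observed(r1_obs, f, R, r1b):
    """Free-pool R1F such that the coupled system's slow relaxation eigenvalue
    equals the observed rate ``r1_obs``.

    With k_F = R*f and k_B = R*(1-f),

        R1F = r1_obs - k_F + k_F*k_B / (r1b + k_B - r1_obs).

    The denominator must stay positive: the bound pool must relax/exchange
    faster than the observed rate for the constraint set to be consistent.
    """
    f = np.asarray(f, dtype=float)
    k_f = np.asarray(R, dtype=float) * f
    k_b = np.asarray(R, dtype=float) * (1.0 - f)
    denom = np.asarray(r1b, dtype=float) + k_b - np.asarray(r1_obs, dtype=float)
    if np.any(denom <= 0):
        raise ValueError(
            "r1b + R*(1-f) must exceed r1_obs (constraints inconsistent "
            "with the observed relaxation rate)"
        )
    return r1_obs - k_f + k_f * k_b / denom


# --------------------------------------------------------------------------
# 2x2 componentwise linear algebra (broadcast over voxels)
# --------------------------------------------------------------------------
# Matrices are component tuples (a11, a12, a21, a22); vectors (v1, v2).

def _expm2(a11, a12, a21, a22, t):
    """exp(A t) for 2x2 A with real eigenvalues, componentwise.

    Uses exp(A t) = e^{l2 t} I + phi (A - l2 I) with
    phi = (e^{l1 t} - e^{l2 t})/(l1 - l2), computed through expm1 so the
    near-degenerate limit is stable.
    """
    tr = a11 + a22
    det = a11 * a22 - a12 * a21
    disc = np.sqrt(np.maximum(tr * tr / 4.0 - det, 0.0))
    l1 = tr / 2.0 + disc
    l2 = tr / 2.0 - disc
    e2 = np.exp(l2 * t)
    x = (l1 - l2) * t
    with np.errstate(divide="ignore", invalid="ignore"):
        em1x = np.where(np.abs(x) > 1e-12, np.expm1(x) / np.where(x == 0, 1, x), 1.0)
    phi = e2 * t * em1x
    return (e2 + phi * (a11 - l2), phi * a12,
            phi * a21, e2 + phi * (a22 - l2))


def _solve2(a11, a12, a21, a22, b1, b2):
    """Solve A x = b for 2x2 A, componentwise."""
    det = a11 * a22 - a12 * a21
    return (a22 * b1 - a12 * b2) / det, (a11 * b2 - a21 * b1) / det


def _matmul2(m, n):
    (a, b, c, d), (e, f_, g, h) = m, n
    return (a * e + b * g, a * f_ + b * h, c * e + d * g, c * f_ + d * h)


def _matvec2(m, v):
    (a, b, c, d), (v1, v2) = m, v
    return a * v1 + b * v2, c * v1 + d * v2


# --------------------------------------------------------------------------
# two-pool steady state
# --------------------------------------------------------------------------

def mt_spgr_steady_state(params: TwoPoolParams, protocol: SPGRProtocol,
                         b0_offset=0.0, b1_scale=1.0,
                         quad_nodes: int = 256, validate: bool = True,
                         _w_b=None):
    """Steady-state MT-weighted SPGR signal of the two-pool system.

    The per-TR cycle is: saturation pulse (duration t_m, rates W_F/W_B at the
    B0-shifted offset, amplitude scaled by ``b1_scale``) -> instantaneous
    excitation by flip*b1_scale acting on the free pool only -> free
    relaxation-exchange for TR - t_m.  The steady state is the fixed point of
    the resulting affine propagator; the returned signal is
    sin(flip*b1_scale) * MzF immediately after the saturation pulse.

    All parameters broadcast; ``_w_b`` lets callers that sweep ``f`` at fixed
    T2B reuse the (expensive) super-Lorentzian bound-pool rate.
    """
    if validate:
        params.validate()
    b1 = np.asarray(b1_scale, dtype=float)
    if np.any(b1 <= 0):
        raise ValueError("b1_scale must be positive")

    f = np.asarray(params.f, dtype=float)
    r1f = np.asarray(params.R1F, dtype=float)
    r1b = np.asarray(params.R1B, dtype=float)
    R = np.asarray(params.R, dtype=float)
    pd = np.asarray(params.PD, dtype=float)

    k_f = R * f
    k_b = R * (1.0 - f)
    m0f = pd * (1.0 - f)
    m0b = pd * f

    # relaxation-exchange generator A and source b (dM/dt = A M + b)
    a11 = -(r1f + k_f)
    a12 = k_b
    a21 = k_f
    a22 = -(r1b + k_b)
    b1v = r1f * m0f
    b2v = r1b * m0b

    pulse = protocol.mt_pulse
    alpha = np.deg2rad(protocol.flip) * b1
    cos_a = np.cos(alpha)

    if pulse is not None and pulse.effective_flip > 0:
        t_m = pulse.duration
        w1 = omega1_rms_from_pulse(pulse) * b1
        delta_eff = pulse.offset + np.asarray(b0_offset, dtype=float)
        w_f = np.pi * w1 ** 2 * lineshape(delta_eff, params.T2F,
                                          kind="lorentzian")
        if _w_b is None:
            g_b = lineshape(delta_eff, params.T2B, kind="super_lorentzian",
                            quad_nodes=quad_nodes)
            w_b = np.pi * w1 ** 2 * g_b
        else:
            w_b = _w_b
        gs = (a11 - w_f, a12, a21, a22 - w_b)
        e_sat = _expm2(*gs, t_m)
        minf_sat = _solve2(*gs, -b1v, -b2v)
        t_free = protocol.TR - t_m
    else:
        e_sat = None
        t_free = protocol.TR

    gf = (a11, a12, a21, a22)
    e_free = _expm2(*gf, t_free)
    minf_free = (m0f, m0b)  # free evolution relaxes toward thermal equilibrium

    # compose the affine cycle M -> P M + q starting just before the pulse
    if e_sat is not None:
        # after saturation: Minf_s + Es (M - Minf_s)
        sat_q = (minf_sat[0] - _matvec2(e_sat, minf_sat)[0],
                 minf_sat[1] - _matvec2(e_sat, minf_sat)[1])
        p1, q1 = e_sat, sat_q
    else:
        one = np.ones(np.broadcast_shapes(np.shape(a11), np.shape(cos_a)))
        p1, q1 = (one, one * 0.0, one * 0.0, one), (0.0, 0.0)

    # excitation (free pool only): C = diag(cos alpha, 1)
    c_mat = (cos_a + 0.0 * a11, 0.0 * a11, 0.0 * a11, 1.0 + 0.0 * a11)
    p2 = _matmul2(c_mat, p1)
    q2 = _matvec2(c_mat, q1)

    p3 = _matmul2(e_free, p2)
    ef_q2 = _matvec2(e_free, q2)
    ef_minf = _matvec2(e_free, minf_free)
    q3 = (ef_q2[0] + minf_free[0] - ef_minf[0],
          ef_q2[1] + minf_free[1] - ef_minf[1])

    # fixed point of M = P3 M + q3
    i_m_p = (1.0 - p3[0], -p3[1], -p3[2], 1.0 - p3[3])
    det = i_m_p[0] * i_m_p[3] - i_m_p[1] * i_m_p[2]
    if np.any(np.abs(det) < 1e-300):
        raise FloatingPointError("singular steady-state fixed point")
    mss = _solve2(*i_m_p, q3[0], q3[1])

    # magnetization at excitation = after the saturation segment
    m_ex = (_matvec2(p1, mss)[0] + q1[0])
    signal = np.sin(alpha) * m_ex
    return signal if signal.ndim else float(signal)
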