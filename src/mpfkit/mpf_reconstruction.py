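"""Single-point synthetic-reference MPF reconstruction.

The macromolecular proton fraction is recovered voxelwise from a single
MT-weighted SPGR image normalized by a *synthetic* reference — the Ernst
signal the MT sequence would give with zero saturation power, computed from
the VFA-fitted R1 and PD.  The normalized ratio is inverted through the
two-pool matrix model with the remaining two-pool parameters fixed by the
standard single-point constraint set; B0 shifts the effective saturation
offset and B1 rescales both readout and saturation flip angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .field_relaxometry import QuantMaps, vfa_r1_pd
from .mt_physics import (SPGRProtocol, TwoPoolParams, lineshape,
                         mt_spgr_steady_state, omega1_rms_from_pulse,
                         r1f_from_observed, spgr_signal)

__all__ = [
    "SinglePointConstraints",
    "synthetic_reference",
    "model_ratio",
    "solve_mpf",
    "solve_mpf_voxel",
    "reconstruct_mpf_map",
]

log = logging.getLogger(__name__)

F_MAX = 0.45  # upper end of the physically sensible MPF search bracket


@dataclass(frozen=True)
class SinglePointConstraints:
    """Fixed two-pool parameters of the single-point method.

    Only the MPF is fitted; cross-relaxation rate ``R``, bound-pool T2,
    the T2F*R1F product, and bound-pool R1 are held at literature values
    (all overridable through the run configuration).
    """

    R: float = 19.0          # 1/s
    T2B: float = 10e-6       # s
    T2F_R1F_product: float = 0.022
    R1B: float = 1.0         # 1/s

    def __post_init__(self):
        for name in ("R", "T2B", "T2F_R1F_product", "R1B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def params_for(self, f, r1_obs, pd=1.0) -> TwoPoolParams:
        """Assemble the full two-pool parameter set at candidate MPF ``f``
        given the observed (slow-eigenvalue) relaxation rate."""
        r1f = r1f_from_observed(r1_obs, f, self.R, self.R1B)
        return TwoPoolParams(f=f, R1F=r1f, R1B=self.R1B,
                             T2F=self.T2F_R1F_product / r1f,
                             T2B=self.T2B, R=self.R, PD=pd)


def synthetic_reference(r1, pd, mt_protocol: SPGRProtocol, b1_scale=1.0):
    """Synthetic (zero-saturation-power) reference: the Ernst signal of the
    MT sequence's TR and B1-corrected flip angle."""
    flip = mt_protocol.flip * np.asarray(b1_scale, dtype=float)
    with np.errstate(invalid="ignore"):
        return spgr_signal(pd, r1, flip, mt_protocol.TR)


def _clamped_params(constraints: SinglePointConstraints, f, r1_obs,
                    r1f_floor: float = 1e-3) -> TwoPoolParams:
    """Constraint assembly tolerant of noisy observed R1: the eigenvalue
    relation can push R1F (or its denominator) non-positive at large
    candidate f on noise voxels, which are clamped instead of raised so the
    vectorized bracket scan can proceed (such voxels end up flagged invalid
    by the bracket test)."""
    f = np.asarray(f, dtype=float)
    k_f = constraints.R * f
    k_b = constraints.R * (1.0 - f)
    denom = np.maximum(constraints.R1B + k_b - np.asarray(r1_obs, float),
                       r1f_floor)
    r1f = np.maximum(r1_obs - k_f + k_f * k_b / denom, r1f_floor)
    return TwoPoolParams(f=f, R1F=r1f, R1B=constraints.R1B,
                         T2F=constraints.T2F_R1F_product / r1f,
                         T2B=constraints.T2B, R=constraints.R, PD=1.0)


def model_ratio(f, r1_obs, b0_offset, b1_scale,
                constraints: SinglePointConstraints,
                mt_protocol: SPGRProtocol, _w_b=None):
    """Two-pool MT-weighted signal normalized by the synthetic reference, as
    predicted by the constrained model at candidate MPF ``f``."""
    params = _clamped_params(constraints, f, r1_obs)
    s_mt = mt_spgr_steady_state(params, mt_protocol, b0_offset=b0_offset,
                                b1_scale=b1_scale, validate=False, _w_b=_w_b)
    s_ref = synthetic_reference(r1_obs, 1.0, mt_protocol, b1_scale)
    return s_mt / s_ref


def _bound_pool_rate(b0_offset, b1_scale, constraints, mt_protocol,
                     quad_nodes=256):
    """Precompute the bound-pool saturation rate W_B, which is independent of
    the candidate MPF (T2B is a constraint)."""
    pulse = mt_protocol.mt_pulse
    w1 = omega1_rms_from_pulse(pulse) * np.asarray(b1_scale, dtype=float)
    delta_eff = pulse.offset + np.asarray(b0_offset, dtype=float)
    g_b = lineshape(delta_eff, constraints.T2B, kind="super_lorentzian",
                    quad_nodes=quad_nodes)
    return np.pi * w1 ** 2 * g_b


def solve_mpf(ratio, r1_obs, b0_offset=0.0, b1_scale=1.0,
              constraints: SinglePointConstraints | None = None,
              mt_protocol: SPGRProtocol | None = None,
              f_tol: float = 1e-6, n_secant: int = 3):
    """Vectorized single-point MPF inversion.

    The model ratio is strictly decreasing in ``f`` at pulsed-MT protocol
    settings, so the root of model_ratio(f) = ratio is bracketed on
    [0, F_MAX] and located by bisection, polished by a few secant steps.
    Voxels whose ratio falls outside [model_ratio(F_MAX), model_ratio(0)]
    are returned as NaN with ``valid`` False.

    Returns ``(f, valid)``.
    """
    if constraints is None:
        constraints = SinglePointConstraints()
    if mt_protocol is None:
        from .config import default_protocols
        mt_protocol = default_protocols()["mt_w"]
    ratio = np.asarray(ratio, dtype=float)
    shape = np.broadcast_shapes(ratio.shape, np.shape(r1_obs),
                                np.shape(b0_offset), np.shape(b1_scale))
    ratio = np.broadcast_to(ratio, shape).copy()
    r1_obs = np.broadcast_to(np.asarray(r1_obs, dtype=float), shape)
    b0 = np.broadcast_to(np.asarray(b0_offset, dtype=float), shape)
    b1 = np.broadcast_to(np.asarray(b1_scale, dtype=float), shape)

    finite = (np.isfinite(ratio) & np.isfinite(r1_obs) & np.isfinite(b0)
              & np.isfinite(b1) & (ratio > 0) & (r1_obs > 0) & (b1 > 0))
    f_out = np.full(shape, np.nan)
    if not np.any(finite):
        return f_out, finite

    rat = ratio[finite]
    r1v = r1_obs[finite]
    b0v = b0[finite]
    b1v = b1[finite]
    w_b = _bound_pool_rate(b0v, b1v, constraints, mt_protocol)

    def eval_ratio(fv):
        return model_ratio(fv, r1v, b0v, b1v, constraints, mt_protocol,
                           _w_b=w_b)

    lo = np.zeros(rat.shape)
    hi = np.full(rat.shape, F_MAX)
    r_lo = eval_ratio(lo)
    r_hi = eval_ratio(hi)
    bracketed = (rat <= r_lo) & (rat >= r_hi)

    n_bisect = max(8, int(np.ceil(np.log2(F_MAX / f_tol))) - 2)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        r_mid = eval_ratio(mid)
        go_up = r_mid > rat  # ratio decreases with f
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
        r_lo = np.where(go_up, r_mid, r_lo)
        r_hi = np.where(go_up, r_hi, r_mid)
    f_est = 0.5 * (lo + hi)
    # secant polish on the bracket endpoints
    for _ in range(n_secant):
        denom = r_hi - r_lo
        step_ok = np.abs(denom) > 0
        f_new = np.where(step_ok,
                         lo + (rat - r_lo) * (hi - lo) / np.where(step_ok,
                                                                  denom, 1.0),
                         f_est)
        f_new = np.clip(f_new, lo, hi)
        f_est = np.where(bracketed, f_new, f_est)
        r_new = eval_ratio(f_est)
        go_up = r_new > rat
        lo = np.where(go_up, f_est, lo)
        hi = np.where(go_up, hi, f_est)
        r_lo = np.where(go_up, r_new, r_lo)
        r_hi = np.where(go_up, r_hi, r_new)

    f_est = np.where(bracketed, f_est, np.nan)
    f_out[finite] = f_est
    valid = np.zeros(shape, dtype=bool)
    valid[finite] = bracketed
    return f_out, valid


def solve_mpf_voxel(ratio: float, r1_obs: float, b0_offset: float = 0.0,
                    b1_scale: float = 1.0,
                    constraints: SinglePointConstraints | None = None,
                    mt_protocol: SPGRProtocol | None = None) -> float:
    """Scalar single-point inversion; returns NaN when the ratio is not
    bracketed by the model over f in [0, F_MAX]."""
    if not (0 < ratio <= 1.5):
        return float("nan")
    f, valid = solve_mpf(np.asarray([ratio]), r1_obs, b0_offset, b1_scale,
                         constraints, mt_protocol)
    return float(f[0])


def reconstruct_mpf_map(mt_w, t1_w, pd_w, b0_map=None, b1_map=None,
                        constraints: SinglePointConstraints | None = None,
                        protocols: dict | None = None,
                        mask=None, noise_sigma: float | None = None) -> QuantMaps:
    """Full single-point synthetic-reference pipeline on co-registered volumes.

    Runs the VFA R1/PD fit on the T1-/PD-weighted pair, forms the synthetic
    reference at the MT sequence settings, and inverts the normalized
    MT-weighted signal voxelwise.  ``mask`` restricts the fit; when absent, a
    signal-threshold mask keeps voxels whose PD-weighted signal exceeds five
    times the background noise floor (``noise_sigma``, Gaussian channel SD; 0
    or None keeps every positive-signal voxel).  MPF is reported in percent.
    """
    from .config import default_protocols
    if protocols is None:
        protocols = default_protocols()
    if constraints is None:
        constraints = SinglePointConstraints()
    mt_w = np.asarray(mt_w, dtype=float)
    t1_w = np.asarray(t1_w, dtype=float)
    pd_w = np.asarray(pd_w, dtype=float)
    if not (mt_w.shape == t1_w.shape == pd_w.shape):
        raise ValueError("source volumes must share one grid")
    b0 = np.zeros(mt_w.shape) if b0_map is None else np.asarray(b0_map, float)
    b1 = np.ones(mt_w.shape) if b1_map is None else np.asarray(b1_map, float)
    if b0.shape != mt_w.shape or b1.shape != mt_w.shape:
        raise ValueError("field maps must share the source grid "
                         "(upsample_field first)")

    if mask is None:
        floor = 5.0 * (noise_sigma or 0.0)
        mask = pd_w > max(floor, np.finfo(float).tiny)
    else:
        mask = np.asarray(mask, dtype=bool)

    t1w_prot = protocols["t1_w"]
    pdw_prot = protocols["pd_w"]
    mt_prot = protocols["mt_w"]

    r1 = np.full(mt_w.shape, np.nan)
    pd = np.full(mt_w.shape, np.nan)
    r1_m, pd_m, vfa_valid = vfa_r1_pd(t1_w[mask], pd_w[mask],
                                      t1w_prot.flip, pdw_prot.flip,
                                      t1w_prot.TR, b1[mask])
    r1[mask] = r1_m
    pd[mask] = pd_m

    s_ref = synthetic_reference(r1, pd, mt_prot, b1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask & (s_ref > 0), mt_w / s_ref, np.nan)

    f = np.full(mt_w.shape, np.nan)
    valid = np.zeros(mt_w.shape, dtype=bool)
    f[mask], valid[mask] = solve_mpf(ratio[mask], r1[mask], b0[mask],
                                     b1[mask], constraints, mt_prot)

    n_mask = int(mask.sum())
    n_invalid = n_mask - int(valid.sum())
    frac = n_invalid / max(n_mask, 1)
    log.info("single-point fit: %d/%d masked voxels invalid (%.1f%%); "
             "constraints R=%g T2B=%g T2F*R1F=%g R1B=%g",
             n_invalid, n_mask, 100 * frac, constraints.R, constraints.T2B,
             constraints.T2F_R1F_product, constraints.R1B)
    if frac > 0.5:
        log.warning("more than half of the masked voxels failed the "
                    "single-point fit")
    return QuantMaps(r1=r1, pd=pd, mpf=100.0 * f, mask=valid)
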