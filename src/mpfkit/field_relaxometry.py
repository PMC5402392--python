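"""B1 mapping (dual-TR AFI), B0 mapping (dual-TE phase difference), and
variable-flip-angle (VFA/DESPOT1) R1 and proton-density estimation.

These field and relaxometry maps feed the single-point MPF solver: the AFI
map rescales nominal flip angles and saturation power, the B0 map shifts the
effective saturation offset, and the VFA fit provides the observed R1 and PD
used to build the synthetic reference image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FieldMaps",
    "QuantMaps",
    "afi_b1",
    "afi_steady_state",
    "dual_te_b0",
    "vfa_r1_pd",
    "upsample_field",
    "fill_nearest",
    "estimate_field_maps",
]


@dataclass
class FieldMaps:
    """Voxelwise B0 offset (Hz), B1 scale (actual/nominal flip) and validity."""

    b0_offset: np.ndarray
    b1_scale: np.ndarray
    mask: np.ndarray

    def validate(self) -> None:
        if np.any(self.b1_scale[self.mask] <= 0):
            raise ValueError("b1_scale must be positive where valid")


@dataclass
class QuantMaps:
    """Reconstructed quantitative maps: R1 (1/s), PD (a.u.), MPF (percent)."""

    r1: np.ndarray
    pd: np.ndarray
    mpf: np.ndarray
    mask: np.ndarray


def afi_steady_state(r1, pd, flip, tr1, tr2):
    """Forward model: ideally spoiled dual-TR AFI steady-state signal pair.

    Interleaving one excitation per TR1 and one per TR2 gives

        S1 = PD sin(a) (1 - E2 + (1 - E1) E2 cos(a)) / (1 - E1 E2 cos^2 a)
        S2 = PD sin(a) (1 - E1 + (1 - E2) E1 cos(a)) / (1 - E1 E2 cos^2 a)

    with E_i = exp(-TR_i * R1).  This is the exact pulsed steady state; the
    closed-form AFI inversion below is its short-TR approximation.
    """
    a = np.deg2rad(np.asarray(flip, dtype=float))
    e1 = np.exp(-tr1 * np.asarray(r1, dtype=float))
    e2 = np.exp(-tr2 * np.asarray(r1, dtype=float))
    denom = 1.0 - e1 * e2 * np.cos(a) ** 2
    s1 = pd * np.sin(a) * (1.0 - e2 + (1.0 - e1) * e2 * np.cos(a)) / denom
    s2 = pd * np.sin(a) * (1.0 - e1 + (1.0 - e2) * e1 * np.cos(a)) / denom
    return s1, s2


def afi_b1(s1, s2, tr1, tr2, nominal_flip):
    """B1 scale from the dual-TR AFI signal pair.

    With r = S2/S1 and n = TR2/TR1, the actual flip angle satisfies
    cos(a) ~= (r n - 1)/(n - r); the B1 scale is a_actual / a_nominal.
    Voxels where the argument leaves [-1, 1] (or S1 <= 0) are flagged invalid.

    Returns ``(b1_scale, valid)``.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    n = tr2 / tr1
    if n <= 1:
        raise ValueError("AFI requires TR2 > TR1")
    valid = s1 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, s2 / np.where(valid, s1, 1.0), np.nan)
        arg = (r * n - 1.0) / (n - r)
    valid &= np.isfinite(arg) & (arg >= -1.0) & (arg <= 1.0) & (r < n)
    b1 = np.full(np.shape(arg), np.nan)
    b1[valid] = np.degrees(np.arccos(arg[valid])) / nominal_flip
    valid &= np.nan_to_num(b1, nan=-1.0) > 0
    if b1.ndim == 0:
        return float(b1), bool(valid)
    return b1, valid


def afi_b1_exact(s1, s2, tr1, tr2, nominal_flip, r1):
    """Exact AFI inversion given the longitudinal rate.

    The closed-form AFI formula is a short-TR approximation; once R1 is
    known (e.g. from a first-pass VFA fit) the exact two-TR steady state can
    be inverted for cos(a):

        cos a = [r (1-E2) - (1-E1)] / [(1-E2) E1 - r (1-E1) E2],

    with r = S2/S1 and E_i = exp(-TR_i R1).  Used as a refinement pass to
    remove the approximation bias.  Returns ``(b1_scale, valid)``.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    valid = (s1 > 0) & np.isfinite(r1) & (r1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, s2 / np.where(valid, s1, 1.0), np.nan)
        e1 = np.exp(-tr1 * r1)
        e2 = np.exp(-tr2 * r1)
        arg = ((r * (1.0 - e2) - (1.0 - e1))
               / ((1.0 - e2) * e1 - r * (1.0 - e1) * e2))
    valid &= np.isfinite(arg) & (arg >= -1.0) & (arg <= 1.0)
    b1 = np.full(np.shape(arg), np.nan)
    b1[valid] = np.degrees(np.arccos(arg[valid])) / nominal_flip
    valid &= np.nan_to_num(b1, nan=-1.0) > 0
    if b1.ndim == 0:
        return float(b1), bool(valid)
    return b1, valid


def dual_te_b0(phase1, phase2, te1, te2):
    """B0 offset in Hz from a dual-TE GRE phase pair.

    The phase difference is wrapped to the principal interval (-pi, pi], so
    the representable offset range is +/- 1/(2 dTE); larger true offsets alias
    back into this window (1.7 ms echo spacing -> +/-294.1 Hz).
    """
    if te2 <= te1:
        raise ValueError("te2 must exceed te1")
    dphi = np.asarray(phase2, dtype=float) - np.asarray(phase1, dtype=float)
    wrapped = np.pi - np.mod(np.pi - dphi, 2.0 * np.pi)  # (-pi, pi]
    out = wrapped / (2.0 * np.pi * (te2 - te1))
    return out if np.ndim(out) else float(out)


def vfa_r1_pd(s_t1w, s_pdw, flip1, flip2, tr, b1_scale=1.0):
    """Two-point variable-flip-angle estimation of R1 and PD.

    Linearizes the Ernst equation: the line through the points
    (S_i/tan a_i, S_i/sin a_i) has slope E1 = exp(-TR*R1) and intercept
    PD (1 - E1), where a_i are the B1-corrected flip angles.  Exact on
    noiseless Ernst signals.

    Returns ``(r1, pd, valid)``.
    """
    s1 = np.asarray(s_t1w, dtype=float)
    s2 = np.asarray(s_pdw, dtype=float)
    b1 = np.asarray(b1_scale, dtype=float)
    a1 = np.deg2rad(flip1) * b1
    a2 = np.deg2rad(flip2) * b1
    valid = (s1 > 0) & (s2 > 0) & np.isfinite(s1) & np.isfinite(s2)
    valid &= np.abs(a1 - a2) > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        x1, y1 = s1 / np.tan(a1), s1 / np.sin(a1)
        x2, y2 = s2 / np.tan(a2), s2 / np.sin(a2)
        slope = (y2 - y1) / (x2 - x1)
        intercept = y1 - slope * x1
    valid &= np.isfinite(slope) & (slope > 0) & (slope < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(valid, -np.log(np.where(valid, slope, 0.5)) / tr, np.nan)
        pd = np.where(valid, intercept / (1.0 - np.where(valid, slope, 0.5)),
                      np.nan)
    valid &= np.nan_to_num(r1, nan=-1.0) > 0
    r1 = np.where(valid, r1, np.nan)
    pd = np.where(valid, pd, np.nan)
    if np.ndim(r1) == 0:
        if not valid:
            raise ValueError("degenerate VFA pair (equal corrected angles or "
                             "non-physical slope)")
        return float(r1), float(pd), bool(valid)
    return r1, pd, valid


def upsample_field(volume, target_shape, order: int = 3):
    """Resample a low-resolution field map onto the target grid (cell-centered
    cubic-spline interpolation by default, which reproduces the smooth
    low-order fields B0/B1 exhibit; pass ``order=1`` for trilinear)."""
    volume = np.asarray(volume, dtype=float)
    zoom = [t / s for t, s in zip(target_shape, volume.shape)]
    return ndimage.zoom(volume, zoom, order=order, mode="nearest",
                        grid_mode=True)


def deaverage_blocks(volume, factor: int = 2, axes=(0, 1)):
    """Second-order correction from voxel-averaged to voxel-center values.

    A coarse acquisition averages the field over each voxel (here: ``factor``
    fine samples per in-plane axis), observing a smooth field f as
    f + var * f''/2 with var the sample-position variance.  Subtracting the
    discrete coarse-grid Laplacian times (factor^2-1)/(24 factor^2) removes
    that box-average bias exactly for quadratic fields.
    """
    volume = np.asarray(volume, dtype=float)
    weight = (factor ** 2 - 1.0) / (24.0 * factor ** 2)
    corr = np.zeros_like(volume)
    for ax in axes:
        fwd = np.roll(volume, -1, axis=ax)
        bwd = np.roll(volume, 1, axis=ax)
        # replicate boundary: zero second difference at the edges
        sl_lo = [slice(None)] * volume.ndim
        sl_hi = [slice(None)] * volume.ndim
        sl_lo[ax] = 0
        sl_hi[ax] = -1
        lap = fwd + bwd - 2.0 * volume
        lap[tuple(sl_lo)] = 0.0
        lap[tuple(sl_hi)] = 0.0
        corr += weight * lap
    return volume - corr


def fill_nearest(volume, valid):
    """Replace invalid voxels by their nearest valid neighbour's value.

    Field maps are meaningless where there is no signal (outside the object);
    filling before interpolation keeps background values from bleeding into
    the object edge when the maps are upsampled to the target grid.
    """
    volume = np.asarray(volume, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if valid.all():
        return volume.copy()
    if not valid.any():
        raise ValueError("no valid voxels to fill from")
    idx = ndimage.distance_transform_edt(~valid, return_distances=False,
                                         return_indices=True)
    return volume[tuple(idx)]


def estimate_field_maps(afi1, afi2, phase1, phase2, target_shape,
                        afi_tr1, afi_tr2, afi_flip, te1, te2,
                        signal=None, signal_threshold: float = 0.0) -> FieldMaps:
    """AFI B1 + dual-TE B0 estimation with masking, nearest-valid filling and
    trilinear upsampling onto the reconstruction grid.

    ``signal`` (e.g. the first AFI magnitude) and ``signal_threshold`` define
    where the maps are trusted; elsewhere they are filled from the nearest
    trusted voxel before interpolation.
    """
    b1_lo, b1_valid = afi_b1(afi1, afi2, afi_tr1, afi_tr2, afi_flip)
    b0_lo = dual_te_b0(phase1, phase2, te1, te2)
    trust = b1_valid
    if signal is not None:
        trust = trust & (np.asarray(signal) > signal_threshold)
    factor = max(1, int(round(target_shape[0] / np.shape(afi1)[0])))
    b1_filled = deaverage_blocks(fill_nearest(np.where(b1_valid, b1_lo,
                                                       np.nan), trust),
                                 factor=factor)
    b0_filled = deaverage_blocks(fill_nearest(b0_lo, trust), factor=factor)
    b1 = upsample_field(b1_filled, target_shape)
    b0 = upsample_field(b0_filled, target_shape)
    mask = upsample_field(trust.astype(float), target_shape) > 0.5
    return FieldMaps(b0_offset=b0, b1_scale=b1, mask=mask)
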