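"""Digital mouse-brain-like phantom: labeled geometry, per-structure two-pool
parameters, five-sequence acquisition simulation with smooth B0/B1 fields and
Rician noise, and synthetic LFB-stained RGB sections.

The phantom stands in for the study animals.  Six anatomical structures
(corpus callosum, anterior commissure, internal capsule, thalamus,
caudoputamen, cortex) are laid out as schematic ellipses/shells in a coronal
plane and extruded across slices; each carries a group-level MPF (percent)
drawn from published control/cuprizone summary statistics, an assumed T1 and
relative proton density, and two-pool parameters assembled to be consistent
with the single-point constraint set (so the observed R1 equals 1/T1 by
construction).  Synthetic histology renders the myelin truth into the red
channel of an RGB section through a linear MPF<->optical-density calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .field_relaxometry import FieldMaps, afi_steady_state
from .mpf_reconstruction import SinglePointConstraints
from .mt_physics import (SPGRProtocol, TwoPoolParams, mt_spgr_steady_state,
                         spgr_signal)

__all__ = [
    "StructureDef",
    "PhantomSpec",
    "Phantom",
    "Acquisition",
    "STRUCTURE_TABLE",
    "GROUP_MPF",
    "GROUP_LFB_OD",
    "LFB_CALIBRATION",
    "structures_for_group",
    "make_phantom",
    "simulate_acquisition",
    "render_lfb_sections",
    "sample_animal_spec",
]

# ---------------------------------------------------------------------------
# study conditions: per-structure group summaries (mean, SD; n=7 per group)
# ---------------------------------------------------------------------------

#: MPF (%) group summaries, (control, cuprizone) as (mean, sd)
GROUP_MPF = {
    "corpus_callosum": ((13.15, 0.73), (9.65, 0.95)),
    "anterior_commissure": ((11.93, 0.74), (10.78, 0.77)),
    "internal_capsule": ((12.74, 0.67), (11.75, 0.69)),
    "thalamus": ((10.01, 0.44), (9.41, 0.51)),
    "caudoputamen": ((8.54, 0.25), (8.10, 0.33)),
    "cortex": ((8.13, 0.22), (7.67, 0.27)),
}

#: LFB optical density (%) group summaries, (control, cuprizone)
GROUP_LFB_OD = {
    "corpus_callosum": ((49.14, 3.23), (29.35, 4.27)),
    "anterior_commissure": ((46.09, 7.61), (37.48, 4.01)),
    "internal_capsule": ((52.54, 8.43), (39.92, 5.87)),
    "thalamus": ((25.76, 3.69), (20.59, 4.90)),
    "caudoputamen": ((30.68, 6.21), (18.64, 5.09)),
    "cortex": ((16.46, 3.40), (12.21, 3.30)),
}

#: linear calibration MPF = slope * OD + intercept tying the MRI and
#: histology stages together (pooled structure-averaged regression).
LFB_CALIBRATION = {"slope": 0.135, "intercept": 5.941}

#: assumed relaxation/density per tissue class at 11.7 T (not part of the
#: published summaries; flagged as assumptions in the ground-truth CSV)
_TISSUE_DEFAULTS = {"wm": (1.6, 0.85), "gm": (1.9, 1.00)}

_STRUCTURE_TISSUE = {
    "corpus_callosum": "wm",
    "anterior_commissure": "wm",
    "internal_capsule": "wm",
    "thalamus": "gm",
    "caudoputamen": "gm",
    "cortex": "gm",
}

OTHER_TISSUE_LABEL = 7  # unlabeled brain filler (GM-like), excluded from ROIs


@dataclass(frozen=True)
class StructureDef:
    label: int
    name: str
    mpf_percent: float
    t1_s: float
    pd_rel: float


def structures_for_group(group: str = "control") -> list[StructureDef]:
    """Structure set with group-mean MPF values."""
    col = {"control": 0, "cuprizone": 1}[group]
    out = []
    for i, (name, groups) in enumerate(GROUP_MPF.items(), start=1):
        t1, pd = _TISSUE_DEFAULTS[_STRUCTURE_TISSUE[name]]
        out.append(StructureDef(label=i, name=name,
                                mpf_percent=groups[col][0], t1_s=t1,
                                pd_rel=pd))
    return out


STRUCTURE_TABLE = structures_for_group("control")

# polynomial field models: coefficients for the basis
# [1, u, v, w, u^2, v^2, w^2, u*v, u*w, v*w] on normalized [-1,1] coords
_DEFAULT_B1_POLY = (1.0, 0.02, -0.03, 0.01, -0.08, -0.06, 0.03, 0.01, 0.0, 0.0)
_DEFAULT_B0_POLY = (10.0, 25.0, -15.0, 5.0, -45.0, -30.0, 12.0, 8.0, 0.0, 0.0)


@dataclass
class PhantomSpec:
    """Construction recipe for one synthetic animal."""

    structures: list = field(default_factory=structures_for_group)
    shape: tuple = (96, 96, 24)
    voxel_size_mm: tuple = (0.1, 0.1, 0.5)
    b1_poly: tuple = _DEFAULT_B1_POLY
    b0_poly: tuple = _DEFAULT_B0_POLY
    jitter_sd_percent: float = 0.0  # within-structure MPF jitter (pp)
    seed: int = 0
    param_mode: str = "constrained"  # or "independent" (R1F = R1B = 1/T1)
    other_t1_s: float = 1.9
    other_pd_rel: float = 0.95
    other_mpf_percent: float = 7.0

    def validate(self) -> None:
        labels = [s.label for s in self.structures]
        if len(set(labels)) != len(labels):
            raise ValueError("structure labels must be unique")
        for s in self.structures:
            if not (0 <= s.mpf_percent <= 50):
                raise ValueError(f"{s.name}: mpf_percent outside [0, 50]")
        if self.jitter_sd_percent < 0:
            raise ValueError("jitter SD must be non-negative")
        if self.param_mode not in ("constrained", "independent"):
            raise ValueError("param_mode must be constrained|independent")


@dataclass
class Phantom:
    spec: PhantomSpec
    labels: np.ndarray  # int8 volume; 0 = background
    params: TwoPoolParams  # voxelwise volumes
    r1_obs: np.ndarray  # observed (slow-eigenvalue) R1, 1/s
    fields: FieldMaps  # smooth B0/B1 truth on the full grid

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def structure_mask(self, name: str) -> np.ndarray:
        for s in self.spec.structures:
            if s.name == name:
                return self.labels == s.label
        raise KeyError(name)

    def structure_mean_mpf(self) -> dict[str, float]:
        f = np.asarray(self.params.f)
        return {s.name: float(100.0 * f[self.labels == s.label].mean())
                for s in self.spec.structures}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipse(u, v, cu, cv, ru, rv):
    return ((u - cu) / ru) ** 2 + ((v - cv) / rv) ** 2 <= 1.0


def _build_labels(shape: tuple) -> np.ndarray:
    nx, ny, nz = shape
    u = np.linspace(-1, 1, nx)[:, None]
    v = np.linspace(-1, 1, ny)[None, :]
    brain = _ellipse(u, v, 0.0, 0.0, 0.85, 0.75)
    shell_inner = _ellipse(u, v, 0.0, 0.0, 0.65, 0.55)
    cc_inner = _ellipse(u, v, 0.0, 0.0, 0.55, 0.45)
    plane = np.zeros((nx, ny), dtype=np.int8)
    masks = {
        6: brain & ~shell_inner,                      # cortex shell
        1: shell_inner & ~cc_inner,                   # corpus callosum ring
        2: (_ellipse(u, v, -0.10, 0.30, 0.05, 0.045)  # anterior commissure
            | _ellipse(u, v, 0.10, 0.30, 0.05, 0.045)),
        3: (_ellipse(u, v, -0.26, -0.08, 0.07, 0.06)  # internal capsule
            | _ellipse(u, v, 0.26, -0.08, 0.07, 0.06)),
        4: _ellipse(u, v, 0.0, -0.18, 0.18, 0.12),    # thalamus
        5: (_ellipse(u, v, -0.32, 0.16, 0.12, 0.11)   # caudoputamen
            | _ellipse(u, v, 0.32, 0.16, 0.12, 0.11)),
    }
    for label, m in masks.items():
        overlap = (plane > 0) & m
        if np.any(overlap):
            raise ValueError(f"structure geometry overlaps at label {label}")
        plane[m] = label
    plane[brain & (plane == 0)] = OTHER_TISSUE_LABEL
    labels = np.zeros(shape, dtype=np.int8)
    z0, z1 = max(1, nz // 6), nz - max(1, nz // 6)
    labels[:, :, :] = 0
    # brain tissue spans all slices; named structures the central slab
    filler = np.where(plane > 0, OTHER_TISSUE_LABEL, 0).astype(np.int8)
    for k in range(nz):
        labels[:, :, k] = plane if z0 <= k < z1 else filler
    return labels


def _poly_field(coeffs, shape):
    nx, ny, nz = shape
    u = np.linspace(-1, 1, nx)[:, None, None]
    v = np.linspace(-1, 1, ny)[None, :, None]
    w = np.linspace(-1, 1, nz)[None, None, :]
    basis = (1.0, u, v, w, u * u, v * v, w * w, u * v, u * w, v * w)
    out = np.zeros(shape)
    for c, b in zip(coeffs, basis):
        out = out + c * b
    return out


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec | None = None,
                 constraints: SinglePointConstraints | None = None) -> Phantom:
    """Build the labeled phantom with voxelwise two-pool parameters.

    In the default ``constrained`` mode the per-voxel parameters are
    assembled through the same constraint set the single-point solver uses
    (R1B, R, T2B fixed; R1F from the eigenvalue relation at the target
    observed R1 = 1/T1; T2F from the T2F*R1F product), so the digital ground
    truth is model-consistent and reconstruction errors measure the pipeline,
    not model mismatch.  ``independent`` mode instead sets R1F = R1B = 1/T1
    for model-mismatch studies.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    constraints = constraints or SinglePointConstraints()
    labels = _build_labels(spec.shape)
    rng = np.random.default_rng(spec.seed)

    f = np.zeros(spec.shape)
    t1 = np.full(spec.shape, spec.other_t1_s)
    pd = np.zeros(spec.shape)
    rows = list(spec.structures) + [
        StructureDef(OTHER_TISSUE_LABEL, "other_tissue",
                     spec.other_mpf_percent, spec.other_t1_s,
                     spec.other_pd_rel)]
    for s in rows:
        m = labels == s.label
        f_s = np.full(int(m.sum()), s.mpf_percent / 100.0)
        if spec.jitter_sd_percent > 0:
            f_s = f_s + rng.normal(0.0, spec.jitter_sd_percent / 100.0,
                                   size=f_s.size)
            f_s = np.clip(f_s, 0.0, 0.45)
        f[m] = f_s
        t1[m] = s.t1_s
        pd[m] = s.pd_rel

    r1_obs = 1.0 / t1
    if spec.param_mode == "constrained":
        params = constraints.params_for(f, r1_obs, pd=pd)
    else:
        params = TwoPoolParams(f=f, R1F=r1_obs, R1B=r1_obs,
                               T2F=constraints.T2F_R1F_product / r1_obs,
                               T2B=constraints.T2B, R=constraints.R, PD=pd)

    fields = FieldMaps(b0_offset=_poly_field(spec.b0_poly, spec.shape),
                       b1_scale=_poly_field(spec.b1_poly, spec.shape),
                       mask=labels > 0)
    fields.validate()
    return Phantom(spec=spec, labels=labels, params=params, r1_obs=r1_obs,
                   fields=fields)


def sample_animal_spec(group: str, rng: np.random.Generator,
                       base: PhantomSpec | None = None) -> PhantomSpec:
    """Draw one synthetic animal: per-structure MPF from the group's
    between-animal normal distribution (clipped to the physical range)."""
    base = base or PhantomSpec(structures=structures_for_group(group))
    col = {"control": 0, "cuprizone": 1}[group]
    structures = []
    for s in structures_for_group(group):
        mean, sd = GROUP_MPF[s.name][col]
        mpf = float(np.clip(rng.normal(mean, sd), 0.5, 49.5))
        structures.append(replace(s, mpf_percent=mpf))
    return replace(base, structures=structures,
                   seed=int(rng.integers(2 ** 31)))


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------

@dataclass
class Acquisition:
    """Simulated source data for one session.

    ``volumes`` holds magnitude images ('mt_w', 't1_w', 'pd_w' on the full
    grid; 'afi1', 'afi2', 'b0_mag1', 'b0_mag2' on the low-resolution field
    grid) and phase images in radians ('b0_phase1', 'b0_phase2').
    """

    volumes: dict
    sigma: float
    seed: int
    field_shape: tuple
    shape: tuple


def _rician(rng, signal, sigma):
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    n1 = rng.normal(0.0, sigma, np.shape(signal))
    n2 = rng.normal(0.0, sigma, np.shape(signal))
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def _downsample(vol, factor):
    """In-plane block average: a low-resolution acquisition integrates the
    signal over larger voxels spanning the same field of view (cell-centered,
    so trilinear upsampling is alignment-consistent)."""
    nx, ny, nz = vol.shape
    if nx % factor or ny % factor:
        raise ValueError("grid not divisible by the field downsample factor")
    return vol.reshape(nx // factor, factor, ny // factor, factor,
                       nz).mean(axis=(1, 3))


def simulate_acquisition(phantom: Phantom, protocols: dict | None = None,
                         sigma: float = 0.0,
                         sigma_fraction: float | None = None,
                         seed: int = 0, field_downsample: int = 2,
                         afi_tr2: float = 0.065) -> Acquisition:
    """Simulate the five-sequence session on the phantom.

    MT-weighted data come from the full two-pool matrix model with the local
    B0/B1; the no-saturation readouts (T1w/PDw, AFI, B0-GRE) are simulated as
    ideally spoiled steady states at the observed (slow-eigenvalue) R1 — the
    mono-exponential recovery those sequences probe.  Magnitudes receive
    Rician noise (two independent Gaussian channels of SD ``sigma``); the
    phase pair is computed from noisy quadratures so its phase noise is
    SNR-consistent.  ``sigma_fraction``, if given, sets sigma to that
    fraction of the mean noiseless corpus-callosum (WM) MT-weighted signal.
    """
    if protocols is None:
        from .config import default_protocols
        protocols = default_protocols()
    rng = np.random.default_rng(seed)
    p = phantom.params
    b0, b1 = phantom.fields.b0_offset, phantom.fields.b1_scale
    mt_prot, t1_prot, pd_prot = (protocols["mt_w"], protocols["t1_w"],
                                 protocols["pd_w"])
    b0_prot, afi_prot = protocols["b0"], protocols["afi"]

    mt_clean = mt_spgr_steady_state(p, mt_prot, b0_offset=b0, b1_scale=b1,
                                    validate=False)
    pd_vol = np.asarray(p.PD)
    t1w_clean = spgr_signal(pd_vol, phantom.r1_obs, t1_prot.flip * b1,
                            t1_prot.TR)
    pdw_clean = spgr_signal(pd_vol, phantom.r1_obs, pd_prot.flip * b1,
                            pd_prot.TR)

    if sigma_fraction is not None:
        wm = phantom.labels == 1
        sigma = float(sigma_fraction * mt_clean[wm].mean())

    ds = field_downsample
    r1_lo = _downsample(phantom.r1_obs, ds)
    pd_lo = _downsample(pd_vol, ds)
    b0_lo = _downsample(b0, ds)
    b1_lo = _downsample(b1, ds)

    afi1, afi2 = afi_steady_state(r1_lo, pd_lo, afi_prot.flip * b1_lo,
                                  afi_prot.TR, afi_tr2)
    gre_mag = spgr_signal(pd_lo, r1_lo, b0_prot.flip * b1_lo, b0_prot.TR)
    te1, te2 = b0_prot.TEs
    phase0 = 0.3  # arbitrary common receiver phase
    volumes = {}
    for key, te in (("b0_1", te1), ("b0_2", te2)):
        phase = phase0 + 2.0 * np.pi * b0_lo * te
        re = gre_mag * np.cos(phase) + rng.normal(0, sigma, gre_mag.shape)
        im = gre_mag * np.sin(phase) + rng.normal(0, sigma, gre_mag.shape)
        volumes[f"{key.replace('b0_', 'b0_mag')}"] = np.hypot(re, im)
        volumes[f"{key.replace('b0_', 'b0_phase')}"] = np.arctan2(im, re)

    volumes["mt_w"] = _rician(rng, mt_clean, sigma)
    volumes["t1_w"] = _rician(rng, t1w_clean, sigma)
    volumes["pd_w"] = _rician(rng, pdw_clean, sigma)
    volumes["afi1"] = _rician(rng, afi1, sigma)
    volumes["afi2"] = _rician(rng, afi2, sigma)
    return Acquisition(volumes=volumes, sigma=sigma, seed=seed,
                       field_shape=r1_lo.shape, shape=phantom.spec.shape)


# ---------------------------------------------------------------------------
# synthetic histology
# ---------------------------------------------------------------------------

def mpf_to_od(mpf_percent, calibration=None):
    """Invert the linear MPF = slope*OD + intercept calibration, clipping the
    optical density to [0, 100]%."""
    cal = calibration or LFB_CALIBRATION
    if cal["slope"] <= 0:
        raise ValueError("calibration slope must be positive")
    od = (np.asarray(mpf_percent, dtype=float) - cal["intercept"]) / cal["slope"]
    return np.clip(od, 0.0, 100.0)


def render_lfb_sections(mpf_slice_percent, calibration=None,
                        background_intensity: float = 240.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        n_sections: int = 3,
                        tissue_mask=None) -> list[np.ndarray]:
    """Render adjacent LFB-stained RGB sections from an MPF truth slice.

    The red channel encodes optical density, red = I_B * (1 - OD/100) plus
    seeded pixel noise; outside the tissue the section takes the background
    intensity.  Blue/green are styled for a plausible LFB appearance and are
    not used by quantification.  Three adjacent sections per location mirror
    the sampling scheme of the histology protocol.
    """
    if not (0 < background_intensity <= 255):
        raise ValueError("background intensity must be in (0, 255]")
    mpf = np.asarray(mpf_slice_percent, dtype=float)
    if tissue_mask is None:
        tissue_mask = mpf > 0
    od = np.where(tissue_mask, mpf_to_od(mpf, calibration), 0.0)
    rng = np.random.default_rng(seed)
    sections = []
    for _ in range(n_sections):
        red = background_intensity * (1.0 - od / 100.0)
        if noise_sd > 0:
            red = red + rng.normal(0.0, noise_sd, red.shape)
        blue = background_intensity * (1.0 - 0.25 * od / 100.0)
        green = background_intensity * (1.0 - 0.65 * od / 100.0)
        rgb = np.stack([red, green, blue], axis=-1)
        sections.append(np.clip(np.rint(rgb), 0, 255).astype(np.uint8))
    return sections
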