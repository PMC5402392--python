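"""End-to-end pipeline stages binding simulation, reconstruction, histology
quantification and statistics into reproducible runs on synthetic cohorts."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import histology
from .config import RunConfig
from .field_relaxometry import estimate_field_maps
from .mpf_reconstruction import reconstruct_mpf_map
from .phantom import (LFB_CALIBRATION, Phantom, PhantomSpec, make_phantom,
                      render_lfb_sections, sample_animal_spec,
                      simulate_acquisition, structures_for_group)
from .stats import (ancova_compare_lines, bland_altman, compare_groups,
                    fisher_compare_correlations, pearson_regression)

__all__ = [
    "reconstruct_from_acquisition",
    "BREGMA_LOCATIONS",
    "measure_animal",
    "simulate_cohort",
    "analyze_table",
    "repeatability_study",
    "report_markdown",
]

log = logging.getLogger(__name__)

#: anatomical section locations (mm from bregma) -> fraction of the slice axis
BREGMA_LOCATIONS = {"-1.58": 1 / 3, "+0.74": 2 / 3}

#: which structures are measured at which location (corpus callosum and
#: cortex appear at both; the smaller structures at one each, following the
#: standard ROI scheme -> 8 measurements per animal)
STRUCTURE_LOCATIONS = {
    "corpus_callosum": ("-1.58", "+0.74"),
    "cortex": ("-1.58", "+0.74"),
    "anterior_commissure": ("+0.74",),
    "caudoputamen": ("+0.74",),
    "internal_capsule": ("-1.58",),
    "thalamus": ("-1.58",),
}


def reconstruct_from_acquisition(acq, cfg: RunConfig | None = None,
                                 refine_b1: bool = True):
    """Field-map estimation + single-point reconstruction on simulated data.

    By default the B1 map is refined once: the closed-form AFI inversion is
    a short-TR approximation, so after a first-pass VFA fit of R1 the AFI
    ratio is re-inverted exactly (``afi_b1_exact``), removing the
    approximation bias from the MPF map.
    """
    from .field_relaxometry import (afi_b1_exact, deaverage_blocks,
                                    fill_nearest, upsample_field, vfa_r1_pd)
    cfg = cfg or RunConfig()
    v = acq.volumes
    prot = cfg.protocols
    te1, te2 = prot["b0"].TEs
    threshold = 5.0 * acq.sigma
    fields = estimate_field_maps(
        v["afi1"], v["afi2"], v["b0_phase1"], v["b0_phase2"], acq.shape,
        prot["afi"].TR, cfg.afi_tr2, prot["afi"].flip, te1, te2,
        signal=v["afi1"], signal_threshold=threshold)
    b1 = fields.b1_scale
    if refine_b1:
        sig_mask = v["pd_w"] > max(threshold, np.finfo(float).tiny)
        r1 = np.full(acq.shape, np.nan)
        r1[sig_mask], _, _ = vfa_r1_pd(
            v["t1_w"][sig_mask], v["pd_w"][sig_mask], prot["t1_w"].flip,
            prot["pd_w"].flip, prot["t1_w"].TR, b1[sig_mask])
        ds = acq.shape[0] // acq.field_shape[0]
        nx, ny, nz = acq.shape
        r1_blocks = r1.reshape(nx // ds, ds, ny // ds, ds, nz)
        cnt = np.isfinite(r1_blocks).sum(axis=(1, 3))
        r1_lo = np.where(cnt > 0,
                         np.nansum(r1_blocks, axis=(1, 3))
                         / np.maximum(cnt, 1), np.nan)
        trust = np.isfinite(r1_lo) & (v["afi1"] > threshold)
        if trust.any():
            r1_lo = fill_nearest(np.where(np.isfinite(r1_lo), r1_lo, 0.5),
                                 np.isfinite(r1_lo))
            b1_lo, ok = afi_b1_exact(v["afi1"], v["afi2"], prot["afi"].TR,
                                     cfg.afi_tr2, prot["afi"].flip, r1_lo)
            trust &= ok
            if trust.any():
                b1 = upsample_field(deaverage_blocks(fill_nearest(
                    np.where(ok, b1_lo, np.nan), trust), factor=ds),
                    acq.shape)
    return reconstruct_mpf_map(v["mt_w"], v["t1_w"], v["pd_w"],
                               fields.b0_offset, b1,
                               constraints=cfg.constraints,
                               protocols=prot, noise_sigma=acq.sigma)


def _location_slices(nz: int) -> dict[str, list[int]]:
    out = {}
    for name, frac in BREGMA_LOCATIONS.items():
        z = int(round(frac * nz))
        out[name] = [z - 1, z, z + 1]
    return out


def measure_animal(phantom: Phantom, quant_maps, animal_id: str, group: str,
                   histology_noise_sd: float = 2.0,
                   background_intensity: float = 240.0,
                   seed: int = 0) -> pd.DataFrame:
    """Per-structure MPF and LFB-OD measurements for one synthetic animal.

    MPF is averaged over the structure mask on three adjacent slices at each
    of two anatomical locations; histology renders three adjacent LFB
    sections per location from the myelin truth and re-quantifies them with
    ROI masks taken from the label image and four off-tissue background ROIs.
    """
    rows = []
    nz = phantom.spec.shape[2]
    loc_slices = _location_slices(nz)
    f_vol = np.asarray(phantom.params.f)
    for loc, zs in loc_slices.items():
        for s in phantom.spec.structures:
            if loc not in STRUCTURE_LOCATIONS.get(s.name, (loc,)):
                continue
            m = phantom.labels == s.label
            sel = m[:, :, zs]
            vals = quant_maps.mpf[:, :, zs][sel]
            rows.append(dict(animal_id=animal_id, group=group,
                             structure=s.name, bregma_location=loc,
                             section_index=-1, roi_index=0,
                             measure="mpf_percent",
                             value=float(np.nanmean(vals))))
        # histology: three adjacent sections rendered at the central slice
        z_mid = zs[1]
        mpf_slice = 100.0 * f_vol[:, :, z_mid]
        tissue = phantom.labels[:, :, z_mid] > 0
        sections = render_lfb_sections(mpf_slice,
                                       background_intensity=background_intensity,
                                       noise_sd=histology_noise_sd,
                                       seed=seed + zs[1], tissue_mask=tissue)
        h, w = tissue.shape
        bg_rois = []
        for cu, cv in ((0, 0), (0, w - 10), (h - 10, 0), (h - 10, w - 10)):
            roi = np.zeros((h, w), dtype=bool)
            roi[cu:cu + 10, cv:cv + 10] = True
            bg_rois.append(roi)
        struct_rois = {s.name: phantom.labels[:, :, z_mid] == s.label
                       for s in phantom.spec.structures
                       if loc in STRUCTURE_LOCATIONS.get(s.name, (loc,))}
        for si, img in enumerate(sections):
            od = histology.quantify_section(img, struct_rois, bg_rois,
                                            tissue_mask=tissue)
            for name, val in od.items():
                rows.append(dict(animal_id=animal_id, group=group,
                                 structure=name, bregma_location=loc,
                                 section_index=si, roi_index=0,
                                 measure="lfb_od_percent", value=val))
    return pd.DataFrame(rows)


def simulate_cohort(seed: int = 0, n_per_group: int = 7,
                    cfg: RunConfig | None = None,
                    base_spec: PhantomSpec | None = None,
                    histology_noise_sd: float = 2.0) -> pd.DataFrame:
    """Two-group synthetic study: sample animals, acquire, reconstruct and
    measure; returns the raw tidy ROI table (pre-aggregation)."""
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(seed)
    tables = []
    for group in ("control", "cuprizone"):
        for i in range(n_per_group):
            spec = sample_animal_spec(group, rng, base=base_spec)
            ph = make_phantom(spec, constraints=cfg.constraints)
            acq = simulate_acquisition(
                ph, protocols=cfg.protocols,
                sigma_fraction=cfg.noise_sigma_fraction,
                seed=int(rng.integers(2 ** 31)), afi_tr2=cfg.afi_tr2)
            qm = reconstruct_from_acquisition(acq, cfg)
            animal_id = f"{group[:4]}_{i:02d}"
            tables.append(measure_animal(ph, qm, animal_id, group,
                                         histology_noise_sd=histology_noise_sd,
                                         seed=int(rng.integers(2 ** 31))))
            log.info("measured animal %s", animal_id)
    return pd.concat(tables, ignore_index=True)


def _regression_block(agg: pd.DataFrame) -> dict:
    """Table of r/r^2/slope/intercept for MPF on LFB OD: structure-averaged
    and per-animal samples, pooled and per group."""
    wide = agg.pivot_table(index=["animal_id", "group", "structure"],
                           columns="measure", values="value").reset_index()
    out = {}
    # structure-averaged: mean over animals per structure (and group)
    for sample, sel in (("pooled", wide),
                        ("control", wide[wide.group == "control"]),
                        ("cuprizone", wide[wide.group == "cuprizone"])):
        sm = sel.groupby(["structure"] if sample != "pooled"
                         else ["structure", "group"], observed=True)[
            ["lfb_od_percent", "mpf_percent"]].mean()
        res = pearson_regression(sm["lfb_od_percent"], sm["mpf_percent"])
        out[f"structure_averaged/{sample}"] = res.to_dict()
        res_i = pearson_regression(sel["lfb_od_percent"], sel["mpf_percent"])
        out[f"individual/{sample}"] = res_i.to_dict()
    return out


def analyze_table(raw: pd.DataFrame) -> dict:
    """Full statistical report on a tidy ROI table: group comparison,
    regression block, Fisher r-to-z and ANCOVA group equality tests."""
    agg = histology.aggregate_measurements(raw)
    report = {"group_comparison": {}}
    for measure in ("mpf_percent", "lfb_od_percent"):
        report["group_comparison"][measure] = compare_groups(
            agg, measure=measure).to_dict()
    reg = _regression_block(agg)
    report["regression"] = reg
    rc = reg["structure_averaged/control"]
    rz = reg["structure_averaged/cuprizone"]
    z, p = fisher_compare_correlations(rc["r"], rc["n"], rz["r"], rz["n"])
    report["correlation_comparison"] = {"z": z, "p": p}
    wide = (agg.pivot_table(index=["animal_id", "group", "structure"],
                            columns="measure", values="value").reset_index())
    sm = wide.groupby(["structure", "group"], observed=True)[
        ["lfb_od_percent", "mpf_percent"]].mean().reset_index()
    report["ancova"] = ancova_compare_lines(sm["lfb_od_percent"],
                                            sm["mpf_percent"], sm["group"])
    return report


def repeatability_study(seed: int = 0, n_subjects: int = 7,
                        cfg: RunConfig | None = None,
                        base_spec: PhantomSpec | None = None) -> dict:
    """Scan-rescan simulation: each subject is scanned twice with independent
    noise; Bland-Altman agreement and within-subject CoV per structure."""
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(seed)
    names = [s.name for s in structures_for_group("control")]
    means = {n: ([], []) for n in names}
    for _ in range(n_subjects):
        spec = sample_animal_spec("control", rng, base=base_spec)
        ph = make_phantom(spec, constraints=cfg.constraints)
        for rep in range(2):
            acq = simulate_acquisition(
                ph, protocols=cfg.protocols,
                sigma_fraction=cfg.noise_sigma_fraction,
                seed=int(rng.integers(2 ** 31)), afi_tr2=cfg.afi_tr2)
            qm = reconstruct_from_acquisition(acq, cfg)
            for n in names:
                means[n][rep].append(float(np.nanmean(qm.mpf[
                    ph.structure_mask(n)])))
    return {n: bland_altman(np.array(m1), np.array(m2)).to_dict()
            for n, (m1, m2) in means.items()}


def report_markdown(report: dict) -> str:
    """Render the analysis report as a Markdown summary."""
    lines = ["# MPF-histology validation report", ""]
    for measure, gc in report["group_comparison"].items():
        lines += [f"## Group comparison ({measure})",
                  f"Wilks' Lambda = {gc['wilks_lambda']:.3f}, "
                  f"F = {gc['manova_f']:.2f}, p = {gc['manova_p']:.4g}", "",
                  "| Structure | t | p | Cohen's d |", "|---|---|---|---|"]
        for name, r in gc["per_structure"].items():
            lines.append(f"| {name} | {r['t']:.2f} | {r['p']:.4g} "
                         f"| {r['d']:.2f} |")
        lines.append("")
    lines += ["## Regression of MPF on LFB optical density", "",
              "| Sample | r | r^2 | n | slope | intercept |",
              "|---|---|---|---|---|---|"]
    for key, r in report["regression"].items():
        lines.append(f"| {key} | {r['r']:.3f} | {r['r2']:.3f} | {r['n']} "
                     f"| {r['slope']:.3f} | {r['intercept']:.3f} |")
    cc = report["correlation_comparison"]
    lines += ["", f"Fisher r-to-z (control vs cuprizone, structure-averaged): "
                  f"z = {cc['z']:.2f}, p = {cc['p']:.2f}",
              f"ANCOVA: p_slope = {report['ancova']['p_slope_diff']:.2f}, "
              f"p_intercept = {report['ancova']['p_intercept_diff']:.2f}", ""]
    if "repeatability" in report:
        lines += ["## Scan-rescan repeatability", "",
                  "| Structure | bias | LoA | p(bias) | CoV % | Levene p |",
                  "|---|---|---|---|---|---|"]
        for name, r in report["repeatability"].items():
            lines.append(
                f"| {name} | {r['bias']:+.3f} | [{r['loa_lower']:+.3f}, "
                f"{r['loa_upper']:+.3f}] | {r['p_bias']:.2f} "
                f"| {r['within_subject_cov']:.2f} | {r['levene_p']:.2f} |")
        lines.append("")
    return "\n".join(lines)
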