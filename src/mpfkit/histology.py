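"""Luxol-Fast-Blue optical-density quantification from RGB section images.

Myelin density on an LFB-stained section is read out of the *red* channel:
stronger blue staining absorbs more red light, so the red intensity drops
with myelin content.  Each ROI's mean red intensity I_R is normalized by a
background correction factor I_B (the mean of four off-tissue ROIs on the
same photograph) and converted to an optical density in percent,

    OD = 100 * (1 - I_R / I_B),

which increases with myelin content and is invariant to global illumination
scaling.  Per-ROI values from three adjacent sections at each anatomical
location are averaged per structure to build the tidy measurement table the
statistics stage consumes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "red_channel_mean",
    "background_factor",
    "lfb_od",
    "quantify_section",
    "aggregate_measurements",
    "ROI_TABLE_COLUMNS",
]

log = logging.getLogger(__name__)

#: tidy per-measurement schema shared by the MRI and histology readouts
ROI_TABLE_COLUMNS = ["animal_id", "group", "structure", "bregma_location",
                     "section_index", "roi_index", "measure", "value"]


def red_channel_mean(rgb_image, roi_mask) -> float:
    """Arithmetic mean of the red channel over the ROI pixels (float)."""
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("ROI mask does not match the image grid")
    if not mask.any():
        raise ValueError("empty ROI")
    return float(img[..., 0][mask].mean(dtype=float))


def background_factor(rgb_image, background_rois, tissue_mask=None) -> float:
    """Background correction factor I_B: mean of the background ROI means.

    ``background_rois`` is a sequence of boolean masks placed outside the
    tissue; a ROI overlapping ``tissue_mask`` (if given) triggers a warning
    but is still used.
    """
    if len(background_rois) == 0:
        raise ValueError("at least one background ROI is required")
    means = []
    for i, roi in enumerate(background_rois):
        roi = np.asarray(roi, dtype=bool)
        if tissue_mask is not None and np.any(roi & np.asarray(tissue_mask)):
            log.warning("background ROI %d overlaps the tissue mask", i)
        means.append(red_channel_mean(rgb_image, roi))
    return float(np.mean(means))


def lfb_od(i_r: float, i_b: float) -> float:
    """LFB optical density in percent: 100 * (1 - I_R/I_B)."""
    if i_b <= 0:
        raise ValueError("background intensity must be positive")
    od = 100.0 * (1.0 - i_r / i_b)
    if od < 0:
        log.warning("ROI brighter than background (I_R=%.2f > I_B=%.2f): "
                    "negative optical density %.2f%%", i_r, i_b, od)
    return float(od)


def quantify_section(rgb_image, structure_rois: dict, background_rois,
                     tissue_mask=None) -> dict[str, float]:
    """Per-structure LFB optical density (%) for one section photograph.

    ``structure_rois`` maps names to either one mask or a list of masks (the
    ROI values are averaged per structure after OD conversion).
    """
    i_b = background_factor(rgb_image, background_rois, tissue_mask)
    out = {}
    for name, rois in structure_rois.items():
        if isinstance(rois, np.ndarray):
            rois = [rois]
        ods = [lfb_od(red_channel_mean(rgb_image, roi), i_b) for roi in rois]
        out[name] = float(np.mean(ods))
    return out


def aggregate_measurements(raw: pd.DataFrame, expected_sections: int | None = None
                           ) -> pd.DataFrame:
    """Collapse raw per-ROI values to one value per animal x structure x
    measure.

    The mean is taken over ROIs within a section, sections within a location,
    and locations — i.e. over everything except the identifying keys.
    Missing sections only produce a warning; the average runs over whatever
    is available.
    """
    missing = [c for c in ("animal_id", "group", "structure", "measure",
                           "value") if c not in raw.columns]
    if missing:
        raise ValueError(f"raw table lacks required columns: {missing}")
    if expected_sections is not None and "section_index" in raw.columns:
        counts = (raw.groupby(["animal_id", "structure", "measure",
                               "bregma_location"])["section_index"].nunique())
        short = counts[counts < expected_sections]
        if len(short):
            log.warning("%d animal/structure/location cells have fewer than "
                        "%d sections; averaging available ones",
                        len(short), expected_sections)
    grouped = (raw.groupby(["animal_id", "group", "structure", "measure"],
                           as_index=False, observed=True)["value"].mean())
    return grouped
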