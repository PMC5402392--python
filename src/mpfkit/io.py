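"""File I/O: NIfTI-1 volumes (float32, voxel geometry in the affine), 8-bit
PNG section images, and tidy CSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

__all__ = ["save_volume", "load_volume", "check_same_grid", "save_png",
           "load_png"]


def save_volume(data, path, voxel_size_mm=(1.0, 1.0, 1.0), dtype=np.float32):
    """Write a 3D volume as NIfTI-1 with the voxel size on the affine
    diagonal (RAS, origin at the corner)."""
    data = np.asarray(data)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(voxel_size_mm)
    nib.save(img, str(path))


def load_volume(path):
    """Read a NIfTI volume; returns (data, voxel_size_mm, affine)."""
    img = nib.load(str(path))
    return (np.asarray(img.dataobj), tuple(float(z) for z in
                                           img.header.get_zooms()[:3]),
            img.affine)


def check_same_grid(*volumes):
    """Raise when co-analyzed volumes do not share one grid."""
    shapes = {np.shape(v) for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"volumes are on different grids: {sorted(shapes)}")


def save_png(rgb, path):
    Image.fromarray(np.asarray(rgb, dtype=np.uint8)).save(str(path))


def load_png(path):
    return np.asarray(Image.open(str(path)).convert("RGB"))
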