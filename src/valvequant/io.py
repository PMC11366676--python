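"""Readers and writers for the pipeline's on-disk formats.

NIfTI for CT volumes (signed 16-bit HU) and ROI masks (unsigned 8-bit),
PNG for slide rasters, CSV (comma, UTF-8, header row, "." decimal) for
measurement tables, JSON for ground truth and reports.  Volume/mask
congruence is enforced on shape and affine (within 1e-4): silent
resampling would corrupt volume quantification.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .ct import CTVolume, ROIMask, TissueQuantification
from .histology import SlideImage

AFFINE_TOL = 1e-4

__all__ = [
    "write_volume",
    "write_mask",
    "read_volume_and_mask",
    "write_slide",
    "read_slide",
    "write_table",
    "read_table",
    "write_json",
    "quantification_row",
    "sha256_file",
]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write HU intensities as int16 NIfTI (values rounded to whole HU)."""
    data = np.rint(np.asarray(volume.intensities)).astype(np.int16)
    img = nib.Nifti1Image(data, _affine(volume.voxel_spacing))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def write_mask(mask: ROIMask, spacing: tuple[float, float, float], path: str | Path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(spacing))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume_and_mask(
    volume_path: str | Path, mask_path: str | Path, reader: str = "reader1"
) -> tuple[CTVolume, ROIMask]:
    """Load a congruent NIfTI volume/mask pair.

    The mask is binarized at > 0.  Shape or affine disagreement (beyond
    1e-4) and non-finite voxels are errors.
    """
    vimg = nib.load(str(volume_path))
    mimg = nib.load(str(mask_path))
    vdata = np.asarray(vimg.dataobj).astype(float)
    mdata = np.asarray(mimg.dataobj)
    if vdata.shape != mdata.shape:
        raise ValueError(
            f"volume {vdata.shape} and mask {mdata.shape} grids are not congruent"
        )
    if not np.allclose(vimg.affine, mimg.affine, atol=AFFINE_TOL):
        raise ValueError("volume and mask affines differ beyond tolerance")
    if not np.all(np.isfinite(vdata)):
        raise ValueError(f"non-finite voxels in {volume_path}")
    spacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
    return (
        CTVolume(intensities=vdata, voxel_spacing=spacing),
        ROIMask(mask=mdata > 0, reader=reader),
    )


def write_slide(slide: SlideImage, path: str | Path) -> None:
    Image.fromarray(slide.rgb, mode="RGB").save(str(path), format="PNG")


def read_slide(path: str | Path, cusp_id: int = 1, slice_id: int = 1) -> SlideImage:
    with Image.open(str(path)) as im:
        rgb = np.asarray(im.convert("RGB"))
    return SlideImage(rgb=rgb, cusp_id=cusp_id, slice_id=slice_id)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(str(path), index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), encoding="utf-8")


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def quantification_row(
    q: TissueQuantification, volume_id: str, reader: str, seed: int, param_hash: str
) -> dict:
    """One report row per (volume, mask, reader), with provenance columns."""
    return {
        "volume_id": volume_id,
        "reader": reader,
        "v_fibrotic_cm3": q.v_fibrotic,
        "v_calcific_cm3": q.v_calcific,
        "v_fibrocalcific_cm3": q.v_fibrocalcific,
        "v_blood_cm3": q.v_blood,
        "v_excluded_cm3": q.v_excluded,
        "fibrotic_pct": q.fibrotic_pct,
        "calcific_pct": q.calcific_pct,
        "fibrocalcific_ratio": q.fibrocalcific_ratio,
        "composition_defined": q.composition_defined,
        "ratio_defined": q.ratio_defined,
        "seed": seed,
        "param_hash": param_hash,
    }


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
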