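"""Reading and writing the pipeline's file formats.

Slice images travel as TIFF or PNG (single-frame DICOM is also readable);
masks as single-channel 0/255 PNG; ROI polygons as JSON vertex lists;
cohorts as a manifest CSV pointing at per-patient image files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .phantom import CohortCase
from .preprocessing import SliceImage
from .segmentation import ROIPolygon


def read_image(path: str | Path, phase: str, patient_id: str = "") -> SliceImage:
    """Read a 2D grayscale slice from TIFF/PNG or single-frame DICOM."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        import pydicom

        ds = pydicom.dcmread(path)
        grid = ds.pixel_array.astype(float)
    elif path.suffix.lower() in (".tif", ".tiff"):
        grid = tifffile.imread(path).astype(float)
    else:
        grid = np.asarray(iio.imread(path), dtype=float)
    if grid.ndim == 3:  # collapse an RGB read of a grayscale export
        grid = grid.mean(axis=2)
    return SliceImage(grid=grid, phase=phase, patient_id=patient_id or path.stem)


def write_image(path: str | Path, image: SliceImage) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.grid.astype(np.float32))
    else:
        arr = image.grid
        lo, hi = arr.min(), arr.max()
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_roi(path: str | Path, roi: ROIPolygon) -> None:
    Path(path).write_text(json.dumps([[float(r), float(c)] for r, c in roi.vertices]))


def read_roi(path: str | Path) -> ROIPolygon:
    return ROIPolygon(np.asarray(json.loads(Path(path).read_text()), dtype=float))


def write_cohort(cases: List[CohortCase], outdir: str | Path) -> Path:
    """Persist a cohort as per-patient TIFF pairs plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        pre_path = outdir / f"{case.patient_id}_pre.tif"
        post_path = outdir / f"{case.patient_id}_post.tif"
        roi_path = outdir / f"{case.patient_id}_roi.json"
        write_image(pre_path, case.pre)
        write_image(post_path, case.post)
        write_roi(roi_path, case.seed_roi)
        rows.append(
            {
                "patient_id": case.patient_id,
                "label": case.label,
                "pre": pre_path.name,
                "post": post_path.name,
                "roi": roi_path.name,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | Path) -> List[CohortCase]:
    """Load a cohort from a manifest CSV (no ground-truth masks available)."""
    manifest = Path(manifest)
    base = manifest.parent
    cases = []
    for row in pd.read_csv(manifest).itertuples():
        pre = read_image(base / row.pre, "pre", row.patient_id)
        post = read_image(base / row.post, "post", row.patient_id)
        roi = read_roi(base / row.roi)
        cases.append(
            CohortCase(
                patient_id=row.patient_id,
                pre=pre,
                post=post,
                true_mask=None,
                seed_roi=roi,
                label=row.label,
            )
        )
    return cases
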