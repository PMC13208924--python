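"""Reading and writing ROI rasters, manifests and feature tables.

Images are 16-bit grayscale PNG; masks are 8-bit {0, 255} PNG.  Manifests,
feature tables and results tables are plain CSV.  Clinical single-frame
DICOM slices can optionally be ingested read-only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import FEATURE_NAMES, ROIImage, SubjectRecord

MANIFEST_COLUMNS = [
    "subject_id", "group", "sex", "age", "side", "image_path", "mask_path",
]
FEATURE_TABLE_COLUMNS = ["subject_id", "group", "sex", "age", "side"] + list(
    FEATURE_NAMES
)


# ---------------------------------------------------------------------------
# rasters


def write_roi_pair(roi: ROIImage, image_path: str | Path, mask_path: str | Path) -> None:
    """Write one ROI as a 16-bit image PNG plus an 8-bit {0,255} mask PNG."""
    iio.imwrite(Path(image_path), roi.pixels.astype(np.uint16))
    iio.imwrite(Path(mask_path), (roi.mask.astype(np.uint8) * 255))


def read_roi_pair(
    image_path: str | Path, mask_path: str | Path, side: str = "left"
) -> ROIImage:
    """Read an image/mask raster pair back into an :class:`ROIImage`."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        pixels = np.asarray(iio.imread(image_path))
    except Exception as exc:
        raise ValueError(f"unreadable image format: {image_path}: {exc}") from exc
    try:
        mask_raw = np.asarray(iio.imread(mask_path))
    except Exception as exc:
        raise ValueError(f"unreadable mask format: {mask_path}: {exc}") from exc
    if pixels.ndim != 2 or mask_raw.ndim != 2:
        raise ValueError("image and mask must be single-channel 2D rasters")
    if mask_raw.shape != pixels.shape:
        raise ValueError(
            f"mask shape {mask_raw.shape} does not match image shape {pixels.shape}"
        )
    return ROIImage(
        pixels=pixels.astype(np.int64), mask=mask_raw > 0, side=side
    )


# ---------------------------------------------------------------------------
# DICOM (optional, read-only)


def read_medical_slice(path: str | Path, window: str = "none") -> np.ndarray:
    """Read one single-frame DICOM slice as a 2D integer grid.

    ``window="rescale"`` applies the stored rescale slope/intercept (when
    present) before rounding to integers; ``"none"`` returns stored values.
    """
    import pydicom

    if window not in ("none", "rescale"):
        raise ValueError("window must be 'none' or 'rescale'")
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        raise ValueError(f"unreadable DICOM file {path}: {exc}") from exc
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise ValueError("multi-frame DICOM slices are not supported")
    if "PixelData" not in ds:
        raise ValueError(f"DICOM file {path} has no pixel data element")
    try:
        arr = ds.pixel_array.astype(np.float64)
    except Exception as exc:
        raise ValueError(f"unsupported DICOM pixel encoding in {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError("expected a single 2D frame")
    if window == "rescale":
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
    return np.rint(arr).astype(np.int64)


# ---------------------------------------------------------------------------
# manifest / cohort


def write_cohort(
    subjects: Iterable[SubjectRecord], out_dir: str | Path
) -> pd.DataFrame:
    """Write every ROI raster pair under ``out_dir`` and return the manifest.

    The manifest (also written as ``manifest.csv``) carries paths relative
    to ``out_dir`` so the cohort directory is relocatable.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in subjects:
        for side in ("left", "right"):
            roi = rec.roi(side)
            image_rel = f"images/{rec.subject_id}_{side}.png"
            mask_rel = f"images/{rec.subject_id}_{side}_mask.png"
            write_roi_pair(roi, out_dir / image_rel, out_dir / mask_rel)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "sex": rec.sex,
                    "age": rec.age,
                    "side": side,
                    "image_path": image_rel,
                    "mask_path": mask_rel,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load a cohort manifest, checking uniqueness and file existence."""
    path = Path(path)
    manifest = pd.read_csv(path)
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    dup = manifest.duplicated(subset=["subject_id", "side"])
    if dup.any():
        pair = manifest.loc[dup.idxmax(), ["subject_id", "side"]].tolist()
        raise ValueError(f"duplicate (subject_id, side) pair in manifest: {pair}")
    base = path.parent
    for col in ("image_path", "mask_path"):
        for rel in manifest[col]:
            if not (base / rel).exists():
                raise FileNotFoundError(f"manifest references missing file: {rel}")
    return manifest


def load_cohort_rois(
    manifest: pd.DataFrame, base_dir: str | Path
) -> list[tuple[pd.Series, ROIImage]]:
    """Resolve every manifest row to its ROIImage."""
    base = Path(base_dir)
    out = []
    for _, row in manifest.iterrows():
        roi = read_roi_pair(
            base / row["image_path"], base / row["mask_path"], side=row["side"]
        )
        out.append((row, roi))
    return out


# ---------------------------------------------------------------------------
# feature table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-(subject, side) feature table as CSV.

    Enforces the complete-case contract: every expected column present and
    no missing cells.  Floats round-trip at full precision.
    """
    missing_cols = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table missing columns: {missing_cols}")
    table = table[FEATURE_TABLE_COLUMNS]
    na = table.isna()
    if na.any().any():
        col = na.any()[na.any()].index[0]
        row = int(na[col].idxmax())
        raise ValueError(f"missing cell in feature table: row {row}, column {col!r}")
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Load a feature table, enforcing the complete-case contract."""
    table = pd.read_csv(path)
    missing_cols = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table missing columns: {missing_cols}")
    na = table.isna()
    if na.any().any():
        col = na.any()[na.any()].index[0]
        row = int(na[col].idxmax())
        raise ValueError(f"missing cell in feature table: row {row}, column {col!r}")
    return table
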