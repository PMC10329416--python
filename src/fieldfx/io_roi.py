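"""Image and ROI-manifest I/O.

Reads grayscale radiographs (PNG/TIFF 8/16-bit, monochrome DICOM), crops
validated 128x128 region-of-interest patches, and loads the cohort ROI
manifest (CSV with columns patient_id, modality, region, x, y; coordinates
are 0-based, half-open, x = column, y = row).

Region labels follow the tumor / near / far protocol: A = tumor, B = near,
C and D = far.  C and D are pooled onto one ordinal "far" level because the
study design treats them as a single region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ROI_SIZE = 128
VALID_REGIONS = ("A", "B", "C", "D")
VALID_MODALITIES = ("mammo", "specimen")

#: ordinal encoding used by the rank-correlation tests: 0=tumor, 1=near, 2=far
REGION_ORDINAL = {"A": 0, "B": 1, "C": 2, "D": 2}

MANIFEST_COLUMNS = ("patient_id", "modality", "region", "x", "y")

__all__ = [
    "ROIPatch",
    "REGION_ORDINAL",
    "read_image",
    "write_image",
    "extract_roi",
    "load_manifest",
    "load_cohort_rois",
]


@dataclass(frozen=True)
class ROIPatch:
    """A 128x128 gray-level patch with provenance."""

    pixels: np.ndarray
    bit_depth: int
    patient_id: str = ""
    modality: str = "mammo"
    region: str = "A"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (ROI_SIZE, ROI_SIZE):
            raise ValueError(f"ROI must be {ROI_SIZE}x{ROI_SIZE}, got {px.shape}")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ValueError(f"gray values out of [0, {2**self.bit_depth - 1}]")
        if self.region not in VALID_REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {VALID_REGIONS}")
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def ordinal(self) -> int:
        return REGION_ORDINAL[self.region]


def read_image(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a grayscale image; returns (2D int array, inferred bit depth).

    PNG/TIFF bit depth is taken from the container dtype; DICOM from
    BitsStored.  Color images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        if getattr(ds, "SamplesPerPixel", 1) != 1:
            raise ValueError(f"grayscale required: {path} is not monochrome")
        arr = ds.pixel_array
        bit_depth = int(ds.BitsStored)
    elif suffix in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"grayscale required: {path} has shape {arr.shape}")
        bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    else:
        raise ValueError(f"unsupported image format {suffix!r} (expected PNG, TIFF or DICOM)")
    if arr.ndim != 2:
        raise ValueError(f"grayscale required: {path} has shape {arr.shape}")
    return np.asarray(arr).astype(np.int64), bit_depth


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a 2D integer image as 16-bit PNG/TIFF (lossless)."""
    import imageio.v3 as iio

    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("only 2D grayscale images are written")
    iio.imwrite(Path(path), img.astype(np.uint16))


def extract_roi(
    image: np.ndarray,
    x: int,
    y: int,
    size: int = ROI_SIZE,
    *,
    bit_depth: int = 12,
    patient_id: str = "",
    modality: str = "mammo",
    region: str = "A",
) -> ROIPatch:
    """Pure crop ``image[y:y+size, x:x+size]``; out-of-bounds ROIs are rejected
    (no padding -- patches that do not fit are excluded, not invented)."""
    img = np.asarray(image)
    h, w = img.shape
    if x < 0 or y < 0 or x + size > w or y + size > h:
        raise ValueError(
            f"ROI ({x},{y}) size {size} does not fit inside {w}x{h} image"
        )
    return ROIPatch(
        pixels=img[y : y + size, x : x + size].copy(),
        bit_depth=bit_depth,
        patient_id=patient_id,
        modality=modality,
        region=region,
    )


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate the ROI manifest CSV.

    One row per placed ROI.  Duplicate (patient_id, modality, region) keys
    and unknown region/modality labels are rejected.  Missing rows (an ROI
    that could not be placed for a patient) are legal -- all downstream
    statistics tolerate unbalanced region counts.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required column(s): {missing}")
    bad_regions = sorted(set(df["region"]) - set(VALID_REGIONS))
    if bad_regions:
        raise ValueError(f"unknown region label(s) {bad_regions}; expected {VALID_REGIONS}")
    bad_mod = sorted(set(df["modality"]) - set(VALID_MODALITIES))
    if bad_mod:
        raise ValueError(f"unknown modality label(s) {bad_mod}; expected {VALID_MODALITIES}")
    dup = df.duplicated(subset=["patient_id", "modality", "region"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["patient_id", "modality", "region"]].drop_duplicates()
        raise ValueError(f"duplicate manifest key(s):\n{keys.to_string(index=False)}")
    return df[list(MANIFEST_COLUMNS)].copy()


def load_cohort_rois(manifest: pd.DataFrame | str | Path, image_dir: str | Path) -> list[ROIPatch]:
    """Materialize every manifest row as an ROIPatch.

    Images are expected at ``<image_dir>/<patient_id>_<modality>.png`` (or
    .tif/.tiff/.dcm); each image is read once.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = load_manifest(manifest)
    image_dir = Path(image_dir)
    cache: dict[tuple[str, str], tuple[np.ndarray, int]] = {}
    patches = []
    for row in manifest.itertuples(index=False):
        key = (row.patient_id, row.modality)
        if key not in cache:
            for ext in (".png", ".tif", ".tiff", ".dcm"):
                p = image_dir / f"{row.patient_id}_{row.modality}{ext}"
                if p.exists():
                    cache[key] = read_image(p)
                    break
            else:
                raise FileNotFoundError(
                    f"no image for patient {row.patient_id} modality {row.modality} in {image_dir}"
                )
        img, depth = cache[key]
        patches.append(
            extract_roi(img, int(row.x), int(row.y), bit_depth=depth,
                        patient_id=row.patient_id, modality=row.modality, region=row.region)
        )
    return patches
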