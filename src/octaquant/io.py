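"""File I/O: 8-bit grayscale images, binary masks, ROI JSON, cohort CSV.

PNG/TIFF round-trips of 8-bit grayscale data are lossless.  16-bit TIFF
input is accepted and rescaled to 8-bit (max-normalised) with a logged
note; RGB input is rejected.  Cohort CSVs are validated against the
canonical schema with explicit column errors.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import CalibratedImage, PolygonROI, read_roi_json, write_roi_json  # noqa: F401
from .stats import validate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "read_image", "write_image", "read_mask", "write_mask",
    "read_cohort", "write_cohort",
]


def read_image(path: str | Path, extent_mm: tuple[float, float] | float) -> CalibratedImage:
    """Read a grayscale PNG/TIFF as a calibrated 8-bit image.

    ``extent_mm`` is the physical (width, height); a scalar means square.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(f"{path}: expected a grayscale image, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        logger.info("%s: 16-bit input rescaled to 8-bit", path)
        peak = max(int(arr.max()), 1)
        arr = np.rint(arr.astype(np.float64) * 255.0 / peak).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16")
    if np.isscalar(extent_mm):
        extent_mm = (float(extent_mm), float(extent_mm))
    return CalibratedImage(pixels=arr, extent_mm=tuple(extent_mm))


def write_image(path: str | Path, image: CalibratedImage | np.ndarray) -> None:
    arr = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    iio.imwrite(path, arr.astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 8-bit PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be 2-D grayscale")
    return arr > 127


def read_cohort(path: str | Path, metrics: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read and schema-check a cohort CSV (one row per eye)."""
    df = pd.read_csv(path)
    try:
        validate_cohort(df, metrics=metrics)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return df


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)
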