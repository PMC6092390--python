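"""Niblack binarization, skeletonization, vessel density and length density.

En-face angiograms are binarized with a Niblack auto local threshold:
a pixel is vessel (bright foreground) iff

    I(x, y) > mean_w(x, y) + k * sd_w(x, y) - c

where the mean and standard deviation are taken over the (2r+1)^2 window
centred on the pixel, with reflective (symmetric) boundary padding.  The
dark-foreground polarity, used for choroidal lumens, flips the comparison:
I < mean - k * sd + c.

Vessel density is the foreground percentage of the analysed region.
Vessel length density reduces vessels to 1-px-wide skeleton lines
(Zhang-Suen thinning) and reports skeleton length per scan area in mm^-1,
counting skeleton pixels times the pixel pitch — the plain pixel-counting
estimate, which under-measures diagonal runs by up to sqrt(2) (documented;
it mirrors how such measurements are made in practice with ImageJ).

The local statistics are computed with exact integer integral images: for
8-bit input every window sum and sum of squares is an exactly-representable
integer, so the fast path is bit-identical to a naive per-pixel loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.morphology import skeletonize as _skimage_skeletonize

from .geometry import CalibratedImage, PolygonROI

__all__ = [
    "NiblackParams",
    "VesselQuantResult",
    "niblack_binarize",
    "vessel_density",
    "skeletonize_mask",
    "vessel_length_density",
    "quantify_enface",
    "rasterize_polygon",
]

Polarity = Literal["bright", "dark"]


@dataclass(frozen=True)
class NiblackParams:
    """Niblack auto-local-threshold parameters.

    window_radius_px : half-width r of the (2r+1) x (2r+1) window.
    k : weight on the local standard deviation (0.2 is the common
        auto-local-threshold convention; larger k -> stricter foreground).
    offset_c : additive intensity offset subtracted from the threshold.
    polarity : "bright" selects pixels above the local threshold (vessels
        on en-face angiograms), "dark" selects pixels below it (choroidal
        lumens on B-scans).
    """

    window_radius_px: int = 15
    k: float = 0.2
    offset_c: float = 0.0
    polarity: Polarity = "bright"

    def __post_init__(self) -> None:
        if self.window_radius_px < 1:
            raise ValueError(f"window_radius_px must be >= 1, got {self.window_radius_px}")
        if self.polarity not in ("bright", "dark"):
            raise ValueError(f"polarity must be 'bright' or 'dark', got {self.polarity!r}")


@dataclass(frozen=True)
class VesselQuantResult:
    """Binarization + skeleton metrics for one en-face angiogram."""

    mask: np.ndarray
    skeleton: np.ndarray
    vessel_density_pct: float
    vessel_length_density_mm_inv: float
    params: NiblackParams
    provenance: dict = field(default_factory=dict)


def _window_mean_sd(pixels: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean and population SD with symmetric boundary padding.

    Integral-image implementation.  Window sums of integer-valued images
    are exact in float64 (they stay far below 2**53), so mean and SD match
    a direct per-pixel loop bit-for-bit as long as the loop uses the same
    `sum/n` and `sumsq/n - mean^2` formulas.
    """
    h, w = pixels.shape
    side = 2 * radius + 1
    if side > min(h, w):
        raise ValueError(
            f"Niblack window side {side} exceeds the smallest image side {min(h, w)}"
        )
    padded = np.pad(pixels.astype(np.float64), radius, mode="symmetric")
    n = float(side * side)

    def window_sums(arr: np.ndarray) -> np.ndarray:
        integ = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
        np.cumsum(arr, axis=0, out=integ[1:, 1:])
        np.cumsum(integ[1:, 1:], axis=1, out=integ[1:, 1:])
        return (
            integ[side:, side:] - integ[:-side, side:]
            - integ[side:, :-side] + integ[:-side, :-side]
        )

    s1 = window_sums(padded)
    s2 = window_sums(padded * padded)
    mean = s1 / n
    var = s2 / n - mean * mean
    np.maximum(var, 0.0, out=var)
    return mean, np.sqrt(var)


def niblack_binarize(image: CalibratedImage | np.ndarray, params: NiblackParams) -> np.ndarray:
    """Binarize with the Niblack local threshold; returns a boolean mask.

    Foreground is strict: a constant image yields an empty mask for either
    polarity (local SD is zero and the strict inequality fails at c = 0).
    """
    pixels = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    mean, sd = _window_mean_sd(pixels, params.window_radius_px)
    px = pixels.astype(np.float64)
    if params.polarity == "bright":
        return px > mean + params.k * sd - params.offset_c
    return px < mean - params.k * sd + params.offset_c


def rasterize_polygon(roi: PolygonROI | _ShapelyPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside the polygon.

    Pixel centres sit at integer coordinates (x = column, y = row); a pixel
    belongs to the region iff its centre is strictly inside (even-odd rule
    for simple polygons; boundary points excluded).
    """
    poly = roi.to_shapely() if isinstance(roi, PolygonROI) else roi
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(int(np.floor(minx)), 0)
    x1 = min(int(np.ceil(maxx)) + 1, w)
    y0 = max(int(np.floor(miny)), 0)
    y1 = min(int(np.ceil(maxy)) + 1, h)
    mask = np.zeros(shape, dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    mask[y0:y1, x0:x1] = contains_xy(poly, xs.ravel(), ys.ravel()).reshape(xs.shape)
    return mask


def vessel_density(mask: np.ndarray, region: PolygonROI | np.ndarray | None = None) -> float:
    """Percentage of region pixels classified foreground.

    ``region`` may be a polygon ROI, a boolean mask, or None for the whole
    image (the default analysis region is the full 3 x 3 mm scan).
    """
    mask = np.asarray(mask, dtype=bool)
    if region is None:
        sel = np.ones(mask.shape, dtype=bool)
    elif isinstance(region, PolygonROI):
        sel = rasterize_polygon(region, mask.shape)
    else:
        sel = np.asarray(region, dtype=bool)
        if sel.shape != mask.shape:
            raise ValueError("region mask shape does not match the vessel mask")
    total = int(sel.sum())
    if total == 0:
        raise ValueError("empty analysis region")
    return 100.0 * int(mask[sel].sum()) / total


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to 8-connected 1-px-wide centrelines (Zhang-Suen)."""
    return _skimage_skeletonize(np.asarray(mask, dtype=bool))


def vessel_length_density(skeleton: np.ndarray, image: CalibratedImage) -> float:
    """Skeleton length per scan area in mm^-1.

    Length = skeleton pixel count x pixel pitch (mm); area = physical scan
    area (mm^2).  Equivalently (skeleton pixel fraction) / pixel pitch.
    """
    if image.area_mm2 <= 0:
        raise ValueError("image has zero physical area")
    px_mm = 1.0 / image.scale_x  # square pixels assumed for length
    n = int(np.asarray(skeleton, dtype=bool).sum())
    return n * px_mm / image.area_mm2


def quantify_enface(image: CalibratedImage, params: NiblackParams | None = None,
                    region: PolygonROI | np.ndarray | None = None) -> VesselQuantResult:
    """Full en-face pipeline: binarize -> density -> skeletonize -> VLD."""
    params = params or NiblackParams()
    mask = niblack_binarize(image, params)
    density = vessel_density(mask, region)
    skeleton = skeletonize_mask(mask)
    vld = vessel_length_density(skeleton, image)
    return VesselQuantResult(
        mask=mask,
        skeleton=skeleton,
        vessel_density_pct=density,
        vessel_length_density_mm_inv=vld,
        params=params,
        provenance={
            "window_radius_px": params.window_radius_px,
            "k": params.k,
            "offset_c": params.offset_c,
            "polarity": params.polarity,
            "mask_pixels": int(mask.sum()),
            "skeleton_pixels": int(skeleton.sum()),
            "total_pixels": int(mask.size),
            "extent_mm": list(image.extent_mm),
        },
    )
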