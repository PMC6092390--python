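"""Choroidal vascularity index (CVI) on a subfoveal B-scan window.

The CVI protocol: trace the total choroidal area (TCA) as a polygon on the
foveal B-scan, restrict it to a 1,500-um-wide subfoveal window (750 um on
either side of the fovea), binarize the 8-bit scan with a Niblack local
threshold in dark-foreground polarity so the hyporeflective vessel lumina
become foreground, intersect the dark-pixel mask with the rasterized TCA
(the protocol's ROI "AND"), and report

    CVI (%) = 100 * luminal area / total choroidal area

as a pixel-count ratio.  A higher CVI means a more vascular (less stromal)
choroid; healthy eyes sit near 69% and the index falls with diabetic
retinopathy severity.

The fovea's lateral position is an input, not detected: the foveal raster
scan is selected manually on the device.  The lateral um/px calibration is
device-specific and must always be supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon, box as _box
from shapely.geometry import MultiPolygon as _MultiPolygon

from .geometry import CalibratedImage, PolygonROI
from .vessel import NiblackParams, niblack_binarize, rasterize_polygon

__all__ = ["SubfovealWindow", "CVIResult", "clip_to_window", "luminal_mask", "compute_cvi"]


@dataclass(frozen=True)
class SubfovealWindow:
    """Lateral analysis window centred on the fovea.

    half_width_um defaults to 750 um, giving the standard 1,500-um-wide
    subfoveal window.  The derived column range is [x_lo, x_hi).
    """

    fovea_x_px: float
    lateral_scale_um_per_px: float
    half_width_um: float = 750.0

    def __post_init__(self) -> None:
        if self.lateral_scale_um_per_px <= 0:
            raise ValueError("lateral_scale_um_per_px must be positive")
        if self.half_width_um <= 0:
            raise ValueError("half_width_um must be positive")

    @property
    def half_width_px(self) -> float:
        return self.half_width_um / self.lateral_scale_um_per_px

    def column_range(self, n_cols: int | None = None) -> tuple[int, int]:
        """Integer column range [x_lo, x_hi), optionally clipped to the image."""
        x_lo = int(math.ceil(self.fovea_x_px - self.half_width_px))
        x_hi = int(math.floor(self.fovea_x_px + self.half_width_px)) + 1
        if n_cols is not None:
            x_lo, x_hi = max(x_lo, 0), min(x_hi, n_cols)
        if x_hi <= x_lo:
            raise ValueError("subfoveal window lies outside the image columns")
        return x_lo, x_hi


@dataclass(frozen=True)
class CVIResult:
    """Pixel counts and areas for one subfoveal CVI measurement."""

    tca_px: int
    la_px: int
    cvi_pct: float
    tca_mm2: float | None = None
    la_mm2: float | None = None


def clip_to_window(tca: PolygonROI, window: SubfovealWindow,
                   n_cols: int | None = None) -> PolygonROI:
    """Clip the TCA polygon to the subfoveal column band.

    The clip box spans [x_lo - 0.5, x_hi - 0.5) so that rasterizing the
    clipped polygon by pixel centres selects exactly the columns in
    [x_lo, x_hi).  If clipping splits the polygon, the largest piece is
    kept (the subfoveal choroid band is in practice a single region).
    """
    x_lo, x_hi = window.column_range(n_cols)
    poly = tca.to_shapely()
    ys = [v for _, v in poly.exterior.coords]
    band = _box(x_lo - 0.5, min(ys) - 1.0, x_hi - 0.5, max(ys) + 1.0)
    clipped = poly.intersection(band)
    if isinstance(clipped, _MultiPolygon):
        clipped = max(clipped.geoms, key=lambda g: g.area)
    if not isinstance(clipped, _ShapelyPolygon) or clipped.area <= 0:
        raise ValueError("TCA polygon does not overlap the subfoveal window")
    return PolygonROI(vertices=np.asarray(clipped.exterior.coords[:-1], dtype=float),
                      layer=tca.layer, image=tca.image)


def luminal_mask(image: CalibratedImage, tca: PolygonROI,
                 params: NiblackParams | None = None) -> np.ndarray:
    """Dark-pixel (lumen) mask restricted to the rasterized TCA polygon.

    This is the protocol's "AND" of the colour-thresholded dark area with
    the traced choroid ROI.  ``params`` must use dark-foreground polarity.
    """
    params = params or NiblackParams(polarity="dark")
    if params.polarity != "dark":
        raise ValueError("luminal segmentation requires dark-foreground polarity")
    tca_raster = rasterize_polygon(tca, image.shape)
    if not tca_raster.any():
        raise ValueError("rasterized TCA polygon is empty")
    dark = niblack_binarize(image, params)
    return dark & tca_raster


def compute_cvi(image: CalibratedImage, tca: PolygonROI, window: SubfovealWindow,
                params: NiblackParams | None = None) -> CVIResult:
    """CVI for one B-scan: clip TCA to the window, segment lumens, count.

    Areas in mm^2 are attached when the image calibration allows (they are
    informational; the CVI itself is scale-free).
    """
    clipped = clip_to_window(tca, window, n_cols=image.shape[1])
    la = luminal_mask(image, clipped, params)
    tca_raster = rasterize_polygon(clipped, image.shape)
    tca_px = int(tca_raster.sum())
    la_px = int(la.sum())
    px_area_mm2 = (1.0 / image.scale_x) * (1.0 / image.scale_y)
    return CVIResult(
        tca_px=tca_px,
        la_px=la_px,
        cvi_pct=100.0 * la_px / tca_px,
        tca_mm2=tca_px * px_area_mm2,
        la_mm2=la_px * px_area_mm2,
    )
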