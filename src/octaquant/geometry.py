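"""Physical calibration and FAZ morphometry from traced polygon ROIs.

En-face OCT angiography scans cover a known physical field (nominally
3 mm x 3 mm rendered at 320 x 320 px, i.e. 106.67 px/mm).  The foveal
avascular zone (FAZ) is traced manually along the innermost capillaries
as a polygon; its area (mm^2), perimeter (mm) and circularity index

    circularity = 4 * pi * area / perimeter**2

are the morphometric read-outs.  The circularity index is the classic
isoperimetric quotient: 1 for a circle, smaller for irregular contours.

Polygons are treated as geometric objects with continuous (sub-pixel)
vertex coordinates, matching the semantics of manual tracing tools;
measurements therefore admit exact closed-form checks.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "CalibratedImage",
    "PolygonROI",
    "FAZMetrics",
    "pixels_per_mm",
    "polygon_area",
    "polygon_perimeter",
    "circularity_index",
    "faz_metrics",
    "read_roi_json",
    "write_roi_json",
    "read_roi_csv",
]


def pixels_per_mm(image_px: int, extent_mm: float) -> float:
    """Image scale in pixels per millimetre.

    A 320-px scan over 3 mm gives 106.666... px/mm (reported as 106.67 at
    two decimals); the full-precision value is always used internally.
    """
    if image_px < 1:
        raise ValueError(f"image_px must be >= 1, got {image_px}")
    if extent_mm <= 0:
        raise ValueError(f"extent_mm must be > 0, got {extent_mm}")
    return image_px / extent_mm


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D grayscale pixel grid with a known physical extent.

    Parameters
    ----------
    pixels
        2-D array of intensities, conventionally 8-bit (0-255).
    extent_mm
        Physical (width, height) of the field in millimetres.  Square-pixel
        scans (the common case: 3 x 3 mm at 320 x 320 px, aspect ratio 1.0)
        have equal per-axis scales; anisotropic extents are supported.
    """

    pixels: np.ndarray
    extent_mm: tuple[float, float]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)
        w, h = self.extent_mm
        if w <= 0 or h <= 0:
            raise ValueError(f"extent_mm must be positive, got {self.extent_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def scale_x(self) -> float:
        """Pixels per mm along image columns."""
        return pixels_per_mm(self.pixels.shape[1], self.extent_mm[0])

    @property
    def scale_y(self) -> float:
        """Pixels per mm along image rows."""
        return pixels_per_mm(self.pixels.shape[0], self.extent_mm[1])

    @property
    def pixel_size_mm(self) -> tuple[float, float]:
        return 1.0 / self.scale_x, 1.0 / self.scale_y

    @property
    def area_mm2(self) -> float:
        return self.extent_mm[0] * self.extent_mm[1]


@dataclass(frozen=True)
class PolygonROI:
    """Closed polygon in pixel coordinates (x = column, y = row).

    Vertices are ordered and continuous-valued (sub-pixel tracing is
    allowed); the last vertex connects implicitly back to the first.
    """

    vertices: np.ndarray
    layer: str | None = None
    image: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"vertices must be an (n, 2) array, got shape {v.shape}")
        if v.shape[0] < 3:
            raise ValueError(f"a polygon needs >= 3 vertices, got {v.shape[0]}")
        object.__setattr__(self, "vertices", v)

    def to_shapely(self, scale_x: float = 1.0, scale_y: float = 1.0) -> _ShapelyPolygon:
        """Shapely polygon with coordinates divided by the given scales."""
        v = self.vertices / np.array([scale_x, scale_y])
        return _ShapelyPolygon(v)

    def check_within(self, image: CalibratedImage) -> None:
        h, w = image.shape
        v = self.vertices
        if (v[:, 0] < -0.5).any() or (v[:, 0] > w - 0.5).any() \
                or (v[:, 1] < -0.5).any() or (v[:, 1] > h - 0.5).any():
            raise ValueError("ROI vertices fall outside the image bounds")


@dataclass(frozen=True)
class FAZMetrics:
    """FAZ area (mm^2), perimeter (mm) and circularity index (unitless)."""

    area_mm2: float
    perimeter_mm: float
    circularity: float


def _check_polygon(roi: PolygonROI, scale_x: float, scale_y: float) -> _ShapelyPolygon:
    if scale_x <= 0 or scale_y <= 0:
        raise ValueError("scale must be positive")
    poly = roi.to_shapely(scale_x, scale_y)
    if poly.area == 0.0:
        raise ValueError("degenerate (zero-area) polygon")
    return poly


def polygon_area(roi: PolygonROI, scale: float, scale_y: float | None = None) -> float:
    """Enclosed area in mm^2 (shoelace on vertices, orientation-independent).

    ``scale`` is in px/mm; for anisotropic pixels pass ``scale_y`` separately
    (area then uses scale_x * scale_y).
    """
    return _check_polygon(roi, scale, scale if scale_y is None else scale_y).area


def polygon_perimeter(roi: PolygonROI, scale: float, scale_y: float | None = None) -> float:
    """Perimeter in mm: straight segments between vertices, closing edge included."""
    return _check_polygon(roi, scale, scale if scale_y is None else scale_y).length


def circularity_index(area_mm2: float, perimeter_mm: float) -> float:
    """Isoperimetric circularity 4*pi*A/P^2; 1 for a circle, no clipping."""
    if area_mm2 <= 0:
        raise ValueError(f"area must be > 0, got {area_mm2}")
    if perimeter_mm <= 0:
        raise ValueError(f"perimeter must be > 0, got {perimeter_mm}")
    return 4.0 * math.pi * area_mm2 / perimeter_mm**2


def faz_metrics(roi: PolygonROI, image: CalibratedImage) -> FAZMetrics:
    """FAZ morphometry bundle for a traced ROI on a calibrated scan.

    The circularity is computed from the exact (unrounded) area and
    perimeter; round only when reporting.
    """
    roi.check_within(image)
    poly = _check_polygon(roi, image.scale_x, image.scale_y)
    return FAZMetrics(
        area_mm2=poly.area,
        perimeter_mm=poly.length,
        circularity=circularity_index(poly.area, poly.length),
    )


# --- ROI serialization ----------------------------------------------------
# JSON schema: {"image": name, "layer": "SCP"|"DCP", "vertices": [[x, y], ...]}
# ImageJ's binary .roi format is out of scope; export vertex lists instead.

def write_roi_json(roi: PolygonROI, path: str | Path) -> None:
    payload = {
        "image": roi.image,
        "layer": roi.layer,
        "vertices": [[float(x), float(y)] for x, y in roi.vertices],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi_json(path: str | Path) -> PolygonROI:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed ROI JSON in {path}: {exc}") from exc
    if "vertices" not in payload:
        raise ValueError(f"ROI JSON {path} is missing the 'vertices' field")
    return PolygonROI(
        vertices=np.asarray(payload["vertices"], dtype=float),
        layer=payload.get("layer"),
        image=payload.get("image"),
    )


def read_roi_csv(path: str | Path) -> PolygonROI:
    """Read a two-column (x, y) vertex list with an optional header row."""
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for i, rec in enumerate(csv.reader(fh)):
            if not rec:
                continue
            try:
                rows.append((float(rec[0]), float(rec[1])))
            except ValueError:
                if i == 0:  # tolerate a header line
                    continue
                raise ValueError(f"{path}, line {i + 1}: expected two numbers, got {rec!r}")
    return PolygonROI(vertices=np.asarray(rows, dtype=float))
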