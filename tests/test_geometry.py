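"""FAZ morphometry: calibration, polygon measurements, circularity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octaquant import (
    CalibratedImage,
    PolygonROI,
    circularity_index,
    faz_metrics,
    pixels_per_mm,
    polygon_area,
    polygon_perimeter,
)
from octaquant.geometry import read_roi_csv, read_roi_json, write_roi_json


def regular_polygon(n: int, radius_px: float, cx: float = 0.0, cy: float = 0.0) -> PolygonROI:
    theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return PolygonROI(np.column_stack([cx + radius_px * np.cos(theta),
                                       cy + radius_px * np.sin(theta)]))


class TestScale:
    @pytest.mark.parametrize("px,mm,expected", [
        (320, 3, 106.67),   # standard 3x3 mm scan reported at 2 dp
        (100, 1, 100.0),
        (512, 6, 85.33),
    ])
    def test_reported_scale(self, px, mm, expected):
        assert round(pixels_per_mm(px, mm), 2) == expected

    def test_full_precision_kept(self):
        assert pixels_per_mm(320, 3) == 320 / 3

    def test_invalid(self):
        with pytest.raises(ValueError):
            pixels_per_mm(320, 0)
        with pytest.raises(ValueError):
            pixels_per_mm(0, 3)


class TestPolygonMeasures:
    scale = 320 / 3  # px/mm

    def unit_square(self):
        s = self.scale
        return PolygonROI(np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=float))

    def test_unit_square_area_perimeter(self):
        roi = self.unit_square()
        assert polygon_area(roi, self.scale) == pytest.approx(1.0)
        assert polygon_perimeter(roi, self.scale) == pytest.approx(4.0)

    def test_circle_area_closed_form(self):
        # radius chosen so pi r^2 = 0.40 mm^2 (a healthy-range FAZ)
        r_mm = math.sqrt(0.40 / math.pi)
        roi = regular_polygon(256, r_mm * self.scale, cx=160, cy=160)
        assert polygon_area(roi, self.scale) == pytest.approx(0.40, rel=5e-3)
        assert polygon_perimeter(roi, self.scale) == pytest.approx(2 * math.pi * r_mm, rel=1e-3)

    def test_orientation_invariance(self):
        roi = self.unit_square()
        rev = PolygonROI(roi.vertices[::-1])
        assert polygon_area(rev, self.scale) == polygon_area(roi, self.scale)

    def test_repeated_vertex_harmless(self):
        roi = self.unit_square()
        v = np.vstack([roi.vertices[:2], roi.vertices[1:2], roi.vertices[2:]])
        assert polygon_perimeter(PolygonROI(v), self.scale) == pytest.approx(4.0)

    def test_degenerate_polygon_rejected(self):
        collinear = PolygonROI(np.array([[0, 0], [1, 1], [2, 2]], dtype=float))
        with pytest.raises(ValueError):
            polygon_area(collinear, self.scale)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            PolygonROI(np.array([[0, 0], [1, 1]], dtype=float))


class TestCircularity:
    def test_isoperimetric_equality_for_circle(self):
        assert circularity_index(math.pi, 2 * math.pi) == pytest.approx(1.0)

    @pytest.mark.parametrize("area,perim,expected", [
        (0.52, 2.87, 0.79),  # healthy deep-plexus group means
        (0.41, 3.05, 0.55),  # mild-NPDR superficial-plexus group means
    ])
    def test_reference_group_means(self, area, perim, expected):
        assert round(circularity_index(area, perim), 2) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            circularity_index(0.0, 1.0)
        with pytest.raises(ValueError):
            circularity_index(1.0, -1.0)


class TestFazMetrics:
    def image(self):
        return CalibratedImage(np.zeros((320, 320), dtype=np.uint8), (3.0, 3.0))

    def test_square_roi_closed_form(self):
        s = 320 / 3
        roi = PolygonROI(np.array([[10, 10], [10 + s, 10], [10 + s, 10 + s], [10, 10 + s]]))
        m = faz_metrics(roi, self.image())
        assert m.area_mm2 == pytest.approx(1.0)
        assert m.perimeter_mm == pytest.approx(4.0)
        assert m.circularity == pytest.approx(math.pi / 4)

    def test_circle_approaches_unity(self):
        roi = regular_polygon(256, 40.0, cx=160, cy=160)
        assert faz_metrics(roi, self.image()).circularity >= 0.99

    def test_ellipse_matches_ramanujan_oracle(self):
        # 4:1 axis ratio; Ramanujan's perimeter approximation as the oracle
        a_mm, b_mm = 0.8, 0.2
        scale = 320 / 3
        theta = np.linspace(0, 2 * math.pi, 2048, endpoint=False)
        roi = PolygonROI(np.column_stack([160 + a_mm * scale * np.cos(theta),
                                          160 + b_mm * scale * np.sin(theta)]))
        h = ((a_mm - b_mm) / (a_mm + b_mm)) ** 2
        perim = math.pi * (a_mm + b_mm) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        expected = circularity_index(math.pi * a_mm * b_mm, perim)
        m = faz_metrics(roi, self.image())
        # closed form for a 4:1 ellipse: 4*pi^2*ab / P_Ramanujan^2 ~ 0.536
        assert m.circularity == pytest.approx(expected, rel=1e-3)

    def test_roi_outside_image_rejected(self):
        roi = regular_polygon(16, 40.0, cx=315, cy=160)
        with pytest.raises(ValueError):
            faz_metrics(roi, self.image())

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        base = regular_polygon(64, 50.0, cx=160, cy=160)
        jitter = PolygonROI(base.vertices + rng.normal(0, 2, base.vertices.shape))
        m1 = faz_metrics(jitter, self.image())
        factor = 2.5
        scaled_img = CalibratedImage(np.zeros((800, 800), dtype=np.uint8), (3.0, 3.0))
        scaled_roi = PolygonROI(jitter.vertices * factor)
        m2 = faz_metrics(scaled_roi, scaled_img)
        # 800/320 = 2.5: same physical polygon on a denser grid
        assert m2.area_mm2 == pytest.approx(m1.area_mm2, rel=1e-9)
        assert m2.perimeter_mm == pytest.approx(m1.perimeter_mm, rel=1e-9)
        assert m2.circularity == pytest.approx(m1.circularity, rel=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_isoperimetric_bound_random_convex_polygons(seed):
    """No simple polygon beats the circle: circularity <= 1 + eps."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 40))
    theta = np.sort(rng.uniform(0, 2 * math.pi, n))
    if len(np.unique(theta)) < 3:
        return
    radius = rng.uniform(5.0, 200.0)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    roi = PolygonROI(pts + 250.0)
    try:
        area = polygon_area(roi, 100.0)
        perim = polygon_perimeter(roi, 100.0)
    except ValueError:
        return  # degenerate draw
    assert circularity_index(area, perim) <= 1.01


def test_monotone_irregularity_of_fourier_contours():
    """Circularity is non-increasing in the radial perturbation amplitude."""
    theta = np.linspace(0, 2 * math.pi, 512, endpoint=False)
    vals = []
    for amp in np.linspace(0.0, 0.12, 7):
        r = 0.357 + amp * np.cos(3 * theta) + 0.5 * amp * np.cos(5 * theta + 1.0)
        roi = PolygonROI(np.column_stack([160 + 106.67 * r * np.cos(theta),
                                          160 + 106.67 * r * np.sin(theta)]))
        vals.append(circularity_index(polygon_area(roi, 106.67),
                                      polygon_perimeter(roi, 106.67)))
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


def test_roi_serialization_round_trips(tmp_path):
    roi = PolygonROI(np.array([[1.25, 2.5], [10.0, 3.75], [5.5, 12.125]]),
                     layer="SCP", image="eye1")
    p = tmp_path / "roi.json"
    write_roi_json(roi, p)
    back = read_roi_json(p)
    assert np.array_equal(back.vertices, roi.vertices)
    assert back.layer == "SCP" and back.image == "eye1"

    csv_path = tmp_path / "roi.csv"
    csv_path.write_text("x,y\n1.25,2.5\n10.0,3.75\n5.5,12.125\n")
    assert np.array_equal(read_roi_csv(csv_path).vertices, roi.vertices)

    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(ValueError):
        read_roi_json(bad)
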