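"""Tests for the serrated-contour border-irregularity module."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from dermfeat import border
from dermfeat.border import DegenerateGeometryError, EllipseFit


def _polyline_length(points: np.ndarray, step: int = 4) -> float:
    """Perimeter of a closed contour measured on a subsampled polyline
    (raw 8-connected chain length overestimates smooth curves)."""
    sub = points[::step]
    return float(np.sum(np.hypot(*(np.roll(sub, -1, axis=0) - sub).T)))


class TestExtractContour:
    def test_three_by_three_square(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        contour = border.extract_contour(mask)
        assert len(contour) == 8
        expected = {(1, 1), (2, 1), (3, 1), (3, 2), (3, 3), (2, 3), (1, 3),
                    (1, 2)}
        assert {tuple(p) for p in contour.astype(int)} == expected

    def test_largest_component_kept(self, make_disk):
        mask = make_disk(80, 20, center=(40, 40))
        mask[5:7, 5:10] = 1  # small second component
        contour = border.extract_contour(mask)
        assert np.hypot(contour[:, 0] - 40, contour[:, 1] - 40).max() < 25

    def test_disk_perimeter(self, make_disk):
        contour = border.extract_contour(make_disk(128, 50))
        length = _polyline_length(contour)
        assert abs(length - 2 * math.pi * 50) / (2 * math.pi * 50) <= 0.05

    def test_counter_clockwise(self, make_disk):
        contour = border.extract_contour(make_disk(64, 20))
        x, y = contour[:, 0], contour[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed > 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            border.extract_contour(np.zeros((10, 10), dtype=np.uint8))


class TestFitEllipse:
    @staticmethod
    def _sample(a, b, rot_deg=0.0, center=(100.0, 80.0), n=200):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = a * np.cos(t)
        y = b * np.sin(t)
        r = math.radians(rot_deg)
        pts = np.column_stack([x * math.cos(r) - y * math.sin(r) + center[0],
                               x * math.sin(r) + y * math.cos(r) + center[1]])
        return pts

    def test_axis_aligned_recovery(self):
        fit = border.fit_ellipse(self._sample(40, 20))
        assert abs(fit.semi_axes[0] - 40) / 40 <= 0.02
        assert abs(fit.semi_axes[1] - 20) / 20 <= 0.02

    def test_circle_recovery(self):
        fit = border.fit_ellipse(self._sample(30, 30))
        assert abs(fit.semi_axes[0] - 30) / 30 <= 0.02
        assert abs(fit.semi_axes[1] - 30) / 30 <= 0.02

    def test_rotation_recovery(self):
        fit = border.fit_ellipse(self._sample(40, 20, rot_deg=30))
        err = abs((fit.rotation - 30 + 90) % 180 - 90)
        assert err <= 3.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            border.fit_ellipse(np.array([[0, 0], [1, 0], [2, 0], [3, 1]]))

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            border.fit_ellipse(pts)


class TestIntersections:
    def test_contour_on_ellipse_degenerate(self):
        pts = TestFitEllipse._sample(40, 25, n=300)
        fit = border.fit_ellipse(pts)
        inter = border.intersections(pts, fit)
        assert inter.fraction_on_ellipse >= 0.9

    def test_four_lobe_star_has_eight_runs(self, make_star):
        mask = make_star(256, 70, 0.25, frequency=4)
        contour = border.extract_contour(mask)
        fit = border.fit_ellipse(contour)
        inter = border.intersections(contour, fit)
        assert inter.n_runs == 8

    def test_single_point_mean_angle(self):
        fit = EllipseFit(center=(0.0, 0.0), semi_axes=(10.0, 10.0),
                         rotation=0.0)
        t = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        pts = np.column_stack([20 * np.cos(t), 20 * np.sin(t)])
        k = int(round(45 / 4))  # the sample at 45 degrees
        pts[k] = [10 * math.cos(math.radians(45)),
                  10 * math.sin(math.radians(45))]
        inter = border.intersections(pts, fit)
        assert inter.n_runs == 1
        assert abs(inter.mean_angle - 45.0) < 1e-6

    def test_no_intersection_raises(self):
        fit = EllipseFit(center=(0.0, 0.0), semi_axes=(5.0, 5.0),
                         rotation=0.0)
        t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts = np.column_stack([30 * np.cos(t), 30 * np.sin(t)])
        with pytest.raises(DegenerateGeometryError):
            border.intersections(pts, fit)


class TestSerratedContour:
    def test_star_vertices_on_contour(self, make_star):
        mask = make_star(256, 70, 0.25, frequency=5)
        contour = border.extract_contour(mask)
        fit = border.fit_ellipse(contour)
        serr = border.serrated_contour(contour, fit.center, 20.0)
        for p in serr:
            d = np.hypot(contour[:, 0] - p[0], contour[:, 1] - p[1]).min()
            assert d <= 1.0

    def test_step_bounds(self, make_disk):
        contour = border.extract_contour(make_disk(64, 20))
        with pytest.raises(ValueError):
            border.serrated_contour(contour, (31.5, 31.5), 0.0)
        with pytest.raises(ValueError):
            border.serrated_contour(contour, (31.5, 31.5), 121.0)


class TestPolygonArea:
    def test_square(self):
        pts = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float)
        assert border.polygon_area(pts) == pytest.approx(4.0)

    def test_triangle(self):
        pts = np.array([[0, 0], [4, 0], [0, 3]], dtype=float)
        assert border.polygon_area(pts) == pytest.approx(6.0)

    def test_decagon_matches_fan_oracle(self):
        rng = np.random.default_rng(0)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 10))
        rad = rng.uniform(5, 15, 10)
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        v0 = pts[0]
        fan = 0.5 * abs(sum(
            np.cross(pts[i] - v0, pts[i + 1] - v0)
            for i in range(1, len(pts) - 1)))
        assert border.polygon_area(pts) == pytest.approx(fan, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            border.polygon_area(np.array([[0, 0], [1, 1]], dtype=float))


class TestAreaDifference:
    def test_identity_zero(self):
        pts = np.array([[0, 0], [3, 0], [3, 3], [0, 3]], dtype=float)
        assert border.area_difference(pts, pts) == pytest.approx(0.0)

    def test_disk_square_closed_form(self, make_disk):
        r = 80
        mask = make_disk(200, r)
        contour = border.extract_contour(mask)
        fit = border.fit_ellipse(contour)
        serr = border.serrated_contour(contour, fit.center, 90.0)
        delta = border.area_difference(contour, serr)
        expected = math.pi * r ** 2 - 2 * r ** 2
        assert abs(delta - expected) / expected <= 0.02

    def test_translation_invariance(self):
        c = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], dtype=float)
        s = np.array([[1, 1], [3, 1], [3, 3], [1, 3]], dtype=float)
        d1 = border.area_difference(c, s)
        d2 = border.area_difference(c + [17, -5], s + [17, -5])
        assert d1 == pytest.approx(d2)


class TestAuxShapeFeatures:
    def test_disk_convex_smooth(self, make_disk):
        feats = border.aux_shape_features(make_disk(128, 40))
        assert feats["circularity"] >= 0.95
        assert feats["solidity"] >= 0.98

    def test_line_fractal_dimension(self):
        mask = np.zeros((128, 128), dtype=np.uint8)
        mask[64, 10:118] = 1
        fd = border.fractal_dimension(mask)
        assert 0.9 <= fd <= 1.1

    def test_star_rougher_than_disk(self, make_disk, make_star):
        disk = border.aux_shape_features(make_disk(192, 60))
        # fine, high-frequency serration raises the box-counting dimension
        # (large smooth lobes would not: they are shape, not roughness)
        star = border.aux_shape_features(make_star(192, 60, 0.15,
                                                   frequency=16))
        assert star["fractal_dimension"] > disk["fractal_dimension"]
        assert (1 - star["solidity"]) > (1 - disk["solidity"])

    def test_zernike_vector_shape(self, make_disk):
        z = border.zernike_magnitudes(make_disk(64, 20))
        assert z.ndim == 1 and len(z) > 10
        assert np.all(np.isfinite(z))


class TestComputeBorderFeatures:
    def test_smooth_ellipse_small_relative_delta(self, make_disk):
        feats = border.compute_border_features(make_disk(160, 55))
        assert abs(feats.delta_area) / feats.area_contour < 0.05

    def test_translation_and_rotation_invariance(self, make_star):
        base = make_star(256, 60, 0.25, frequency=5, center=(127.5, 127.5))
        shifted = make_star(256, 60, 0.25, frequency=5, center=(110.5, 132.5))
        d0 = border.compute_border_features(base).delta_area
        d1 = border.compute_border_features(shifted).delta_area
        d2 = border.compute_border_features(np.rot90(base)).delta_area
        assert abs(d1 - d0) / abs(d0) <= 0.02
        assert abs(d2 - d0) / abs(d0) <= 0.02


class TestClassifyBorders:
    def _table(self, make_disk, make_star):
        masks, truth = [], []
        rng = np.random.default_rng(0)
        for i in range(12):
            r = float(rng.uniform(35, 45))
            masks.append(make_disk(128, r))
            truth.append(0)
            masks.append(make_star(128, r, 0.3, frequency=4,
                                   phase=float(rng.uniform(0, np.pi))))
            truth.append(1)
        return border.border_feature_table(masks), np.array(truth)

    def test_separable_clustering(self, make_disk, make_star):
        table, truth = self._table(make_disk, make_star)
        with np.errstate(all="ignore"):
            labels = border.classify_borders(table, seed=0)
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)
        # irregular cluster = the stars (larger |delta_area|)
        expected = np.where(truth == 1, "irregular", "regular")
        assert np.array_equal(labels, expected)

    def test_permutation_invariance(self, make_disk, make_star):
        table, _ = self._table(make_disk, make_star)
        perm = np.random.default_rng(1).permutation(len(table))
        with np.errstate(all="ignore"):
            base = border.classify_borders(table, seed=0)
            shuffled = border.classify_borders(table.iloc[perm], seed=0)
        assert np.array_equal(shuffled, base[perm])

    def test_identical_rows_rejected(self):
        table = pd.DataFrame(np.ones((6, 4)),
                             columns=["delta_area", "a", "b", "c"])
        with pytest.raises(ValueError):
            border.classify_borders(table, seed=0)

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame(np.random.default_rng(0).random((3, 4)),
                             columns=["delta_area", "a", "b", "c"])
        with pytest.raises(ValueError):
            border.classify_borders(table, seed=0)
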