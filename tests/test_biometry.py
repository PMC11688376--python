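"""Unit and property tests for the mask -> (DM, Dm, GW) biometry chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacmetry.biometry import (
    GW_FLOOR_WEEKS,
    PixelSpacing,
    convex_hull,
    estimate_gw,
    extract_largest_component,
    measure_diameters,
    min_area_rect,
    run_biometry,
    trace_boundary,
)
from sacmetry.synth import SacParams, generate_sac

from conftest import boundary_oracle, random_blob, sweep_min_area


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

class TestLargestComponent:
    def test_keeps_largest_of_two_blobs(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[2:12, 2:7] = 1          # 50 px
        mask[15:17, 15:20] = 1       # 10 px
        out = extract_largest_component(mask)
        assert out[2:12, 2:7].all() and out.sum() == 50

    def test_single_blob_is_identity(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3:7, 3:7] = 1
        assert np.array_equal(extract_largest_component(mask), mask)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no foreground"):
            extract_largest_component(np.zeros((5, 5), dtype=np.uint8))

    def test_diagonal_pixels_are_one_component(self):
        mask = np.eye(5, dtype=np.uint8)  # 8-connected diagonal
        assert extract_largest_component(mask).sum() == 5


# ---------------------------------------------------------------------------
# Moore-neighbor tracing
# ---------------------------------------------------------------------------

class TestTraceBoundary:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[5, 5] = 1
        assert trace_boundary(mask).tolist() == [[5, 5]]

    def test_solid_3x3_square(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        contour = trace_boundary(mask)
        pts = set(map(tuple, contour.tolist()))
        assert pts == boundary_oracle(mask)
        assert len(contour) == 8  # each perimeter pixel exactly once
        # consecutive points are 8-neighbors, path closed
        closed = np.vstack([contour, contour[:1]])
        steps = np.abs(np.diff(closed, axis=0)).max(axis=1)
        assert (steps == 1).all()

    def test_solid_rectangle_matches_oracle(self):
        mask = np.zeros((30, 40), dtype=np.uint8)
        mask[5:25, 5:35] = 1  # 20 x 30 rectangle
        pts = set(map(tuple, trace_boundary(mask).tolist()))
        assert pts == boundary_oracle(mask)
        assert len(pts) == 2 * 20 + 2 * 30 - 4

    def test_object_touching_border(self):
        mask = np.ones((6, 9), dtype=np.uint8)  # fills the whole frame
        pts = set(map(tuple, trace_boundary(mask).tolist()))
        assert pts == boundary_oracle(mask)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_blob_matches_oracle(self, seed):
        mask = random_blob(size=64, seed=seed)
        pts = set(map(tuple, trace_boundary(mask).tolist()))
        assert pts == boundary_oracle(mask)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no foreground"):
            trace_boundary(np.zeros((4, 4), dtype=np.uint8))


# ---------------------------------------------------------------------------
# convex hull
# ---------------------------------------------------------------------------

def _hull_vertex_oracle(points: np.ndarray) -> set:
    """A point is a hull vertex iff it is not a convex combination of the
    others (linear-programming feasibility test)."""
    from scipy.optimize import linprog

    vertices = set()
    n = len(points)
    for j in range(n):
        others = np.delete(points, j, axis=0)
        a_eq = np.vstack([others.T, np.ones(n - 1)])
        b_eq = np.append(points[j], 1.0)
        res = linprog(c=np.zeros(n - 1), A_eq=a_eq, b_eq=b_eq,
                      bounds=(0, None), method="highs")
        if not res.success:
            vertices.add(tuple(points[j]))
    return vertices


class TestConvexHull:
    def test_triangle_returns_all_points(self):
        pts = [(0, 0), (4, 1), (1, 5)]
        assert set(map(tuple, convex_hull(pts))) == set(pts)

    def test_interior_point_dropped(self):
        pts = [(0, 0), (0, 4), (4, 0), (4, 4), (2, 2)]
        assert set(map(tuple, convex_hull(pts))) == {(0, 0), (0, 4), (4, 0), (4, 4)}

    def test_one_and_two_points_returned_as_is(self):
        assert convex_hull([(3, 7)]).tolist() == [[3, 7]]
        assert len(convex_hull([(0, 0), (2, 5)])) == 2

    def test_collinear_returns_endpoints(self):
        pts = [(0, 0), (1, 1), (2, 2), (3, 3)]
        hull = set(map(tuple, convex_hull(pts)))
        assert hull == {(0.0, 0.0), (3.0, 3.0)}

    def test_ccw_orientation(self, rng):
        pts = rng.random((40, 2)) * 100
        hull = convex_hull(pts)
        rolled = np.roll(hull, -1, axis=0)
        rolled2 = np.roll(hull, -2, axis=0)
        cross = ((rolled[:, 0] - hull[:, 0]) * (rolled2[:, 1] - hull[:, 1])
                 - (rolled[:, 1] - hull[:, 1]) * (rolled2[:, 0] - hull[:, 0]))
        assert (cross > 0).all() or (cross < 0).all()  # consistently oriented

    def test_matches_bruteforce_oracle(self, rng):
        pts = np.round(rng.random((200, 2)) * 50, 3)
        hull = set(map(tuple, convex_hull(pts)))
        assert hull == _hull_vertex_oracle(pts)


# ---------------------------------------------------------------------------
# minimum-area rectangle
# ---------------------------------------------------------------------------

class TestMinAreaRect:
    def test_axis_aligned_rectangle_is_self(self):
        rect = min_area_rect([(0, 0), (0, 4), (2, 0), (2, 4)])
        assert rect.area_px == pytest.approx(8.0)
        assert rect.side_long_px == pytest.approx(4.0)
        assert rect.side_short_px == pytest.approx(2.0)

    def test_diamond_gives_rotated_square(self):
        rect = min_area_rect([(0, 0), (1, 1), (2, 0), (1, -1)])
        assert rect.area_px == pytest.approx(2.0, abs=1e-9)
        assert rect.side_long_px == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_collinear_degenerates_to_zero_width(self):
        rect = min_area_rect([(0, 0), (1, 2), (2, 4)])
        assert rect.area_px == pytest.approx(0.0)
        assert rect.side_short_px == pytest.approx(0.0)
        assert rect.side_long_px == pytest.approx(math.hypot(2, 4))

    def test_single_point(self):
        rect = min_area_rect([(3, 4)])
        assert rect.c1 == rect.c4 == (3.0, 4.0)
        assert rect.area_px == 0.0

    def test_corner_labeling_and_parallelism(self, rng):
        pts = rng.random((60, 2)) * 30
        rect = min_area_rect(pts)
        c1, c2, c3, c4 = map(np.asarray, (rect.c1, rect.c2, rect.c3, rect.c4))
        assert np.allclose(c4, c2 + c3 - c1, atol=1e-9)  # parallelogram closure
        assert np.dot(c2 - c1, c3 - c1) == pytest.approx(0.0, abs=1e-9)
        assert rect.side_long_px >= rect.side_short_px

    def test_all_points_contained(self, rng):
        pts = rng.random((80, 2)) * 40 - 20
        rect = min_area_rect(pts)
        u = (np.asarray(rect.c2) - np.asarray(rect.c1))
        v = (np.asarray(rect.c3) - np.asarray(rect.c1))
        rel = pts - np.asarray(rect.c1)
        for axis in (u, v):
            norm2 = axis @ axis
            if norm2 == 0:
                continue
            t = rel @ axis / norm2
            assert (t > -1e-6).all() and (t < 1 + 1e-6).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_angle_sweep_oracle(self, seed):
        g = np.random.default_rng(seed)
        pts = g.random((300, 2)) * 100
        rect = min_area_rect(pts)
        oracle = sweep_min_area(pts)
        assert rect.area_px == pytest.approx(oracle, rel=1e-4)

    def test_matches_shapely_oracle(self, rng):
        from shapely.geometry import MultiPoint

        pts = rng.random((120, 2)) * 60
        rect = min_area_rect(pts)
        expected = MultiPoint([tuple(p) for p in pts]).minimum_rotated_rectangle
        assert rect.area_px == pytest.approx(expected.area, rel=1e-9)


# ---------------------------------------------------------------------------
# diameters and gestational weeks
# ---------------------------------------------------------------------------

class TestMeasureDiameters:
    def test_isotropic_scaling(self):
        rect = min_area_rect([(0, 0), (0, 100), (50, 0), (50, 100)])
        DM, Dm = measure_diameters(rect, PixelSpacing.isotropic(0.05))
        assert (DM, Dm) == (pytest.approx(5.0), pytest.approx(2.5))

    def test_anisotropic_axis_scaling(self):
        # 100 px along both axes; the column axis has the coarser spacing
        rect = min_area_rect([(0, 0), (0, 100), (100, 0), (100, 100)])
        DM, Dm = measure_diameters(rect, PixelSpacing(row_spacing=0.01,
                                                      col_spacing=0.02))
        assert (DM, Dm) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_rotated_rect_matches_direct_formula(self):
        # 45-degree rectangle, anisotropic spacing: evaluate the scaled
        # Euclidean distances on the corner coordinates directly.
        spacing = PixelSpacing(row_spacing=0.013, col_spacing=0.029)
        pts = [(0, 0), (60, 60), (75, 45), (15, -15)]
        rect = min_area_rect(pts)

        def dist(a, b):
            return math.hypot((b[0] - a[0]) * spacing.row_spacing,
                              (b[1] - a[1]) * spacing.col_spacing)

        DM, Dm = measure_diameters(rect, spacing)
        d12 = dist(rect.c1, rect.c2)
        d13 = dist(rect.c1, rect.c3)
        assert DM == pytest.approx(max(d12, d13))
        assert Dm == pytest.approx(min(d12, d13))

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            PixelSpacing(0.0, 0.01)
        with pytest.raises(ValueError):
            PixelSpacing(0.01, -1.0)


class TestEstimateGW:
    def test_msd_25mm_is_week_7_2(self):
        assert estimate_gw(2.5, 2.5) == pytest.approx(7.2043, abs=5e-5)
        assert round(estimate_gw(2.5, 2.5), 1) == 7.2

    def test_zero_diameters_floor(self):
        assert estimate_gw(0.0, 0.0) == pytest.approx(2.543 / 0.7)
        assert estimate_gw(0.0, 0.0) == pytest.approx(GW_FLOOR_WEEKS)

    def test_depends_only_on_sum(self):
        assert estimate_gw(3.0, 2.0) == pytest.approx(estimate_gw(2.5, 2.5))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_gw(-0.1, 1.0)

    @settings(max_examples=60, derandomize=True)
    @given(dm=st.floats(0, 10), dmm=st.floats(0, 10), delta=st.floats(1e-6, 5))
    def test_strictly_increasing(self, dm, dmm, delta):
        base = estimate_gw(dm, dmm)
        assert estimate_gw(dm + delta, dmm) > base
        assert estimate_gw(dm, dmm + delta) > base


# ---------------------------------------------------------------------------
# end-to-end pipeline on digitized ellipses
# ---------------------------------------------------------------------------

class TestRunBiometry:
    SPACING = PixelSpacing.isotropic(0.01)

    def test_axis_aligned_ellipse_recovers_axes(self):
        case = generate_sac(SacParams(a=125, b=75, spacing=self.SPACING), 0)
        res = run_biometry(case.mask, self.SPACING)
        assert res.DM_cm == pytest.approx(2.5, rel=0.02)
        assert res.Dm_cm == pytest.approx(1.5, rel=0.02)
        assert res.GW_weeks == pytest.approx((2.0 + 2.543) / 0.7, abs=0.05)

    def test_circle_at_msd_threshold(self):
        case = generate_sac(SacParams(a=125, b=125, spacing=self.SPACING), 0)
        res = run_biometry(case.mask, self.SPACING)
        assert res.GW_weeks == pytest.approx(7.20, abs=0.05)

    def test_rotation_leaves_diameters_unchanged(self):
        base = run_biometry(
            generate_sac(SacParams(a=125, b=75, spacing=self.SPACING), 0).mask,
            self.SPACING)
        rot = run_biometry(
            generate_sac(SacParams(a=125, b=75, angle=30,
                                   spacing=self.SPACING), 0).mask,
            self.SPACING)
        assert rot.DM_cm == pytest.approx(base.DM_cm, rel=0.02)
        assert rot.Dm_cm == pytest.approx(base.Dm_cm, rel=0.02)

    def test_rotation_series_low_variation(self):
        DMs, Dms = [], []
        for angle in (0, 30, 45, 60, 90):
            mask = generate_sac(SacParams(a=100, b=60, angle=angle,
                                          spacing=self.SPACING), 0).mask
            res = run_biometry(mask, self.SPACING)
            DMs.append(res.DM_cm)
            Dms.append(res.Dm_cm)
        for vals in (DMs, Dms):
            cv = np.std(vals) / np.mean(vals)
            assert cv < 0.02

    def test_scaling_mask_scales_diameters(self):
        small = generate_sac(SacParams(a=60, b=40, spacing=self.SPACING), 0)
        large = generate_sac(SacParams(a=120, b=80, spacing=self.SPACING), 0)
        r_small = run_biometry(small.mask, self.SPACING)
        r_large = run_biometry(large.mask, self.SPACING)
        assert r_large.DM_cm == pytest.approx(2 * r_small.DM_cm, rel=0.02)
        assert r_large.Dm_cm == pytest.approx(2 * r_small.Dm_cm, rel=0.02)

    def test_result_invariants(self):
        case = generate_sac(SacParams(a=80, b=50, angle=70,
                                      spacing=self.SPACING), 0)
        res = run_biometry(case.mask, self.SPACING)
        assert res.DM_cm >= res.Dm_cm >= 0
        expected = (0.5 * (res.DM_cm + res.Dm_cm) + 2.543) / 0.7
        assert res.GW_weeks == pytest.approx(expected, abs=1e-12)
        assert res.GW_weeks >= GW_FLOOR_WEEKS

    def test_degenerate_single_pixel(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 4] = 1
        res = run_biometry(mask, self.SPACING)
        assert res.DM_cm == res.Dm_cm == 0.0
        assert res.GW_weeks == pytest.approx(GW_FLOOR_WEEKS)

    def test_degenerate_two_pixel_line(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 4:6] = 1
        res = run_biometry(mask, self.SPACING)
        assert res.Dm_cm == pytest.approx(0.0)
        assert res.DM_cm == pytest.approx(0.01)

    def test_anisotropic_relabeling_keeps_dm_largest(self):
        # long pixel side along columns, but rows have much coarser spacing
        mask = np.zeros((40, 80), dtype=np.uint8)
        mask[10:20, 10:70] = 1  # 10 rows x 60 cols
        res = run_biometry(mask, PixelSpacing(row_spacing=0.1,
                                              col_spacing=0.005))
        assert res.DM_cm >= res.Dm_cm
        assert res.DM_cm == pytest.approx(9 * 0.1, rel=1e-6)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no foreground"):
            run_biometry(np.zeros((8, 8), dtype=np.uint8), self.SPACING)
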