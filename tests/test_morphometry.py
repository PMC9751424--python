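import numpy as np
import pytest

from meibomorph.calibration import minrect_exhaustive, perimeter_bruteforce, random_blob
from meibomorph.errors import ValidationError
from meibomorph.io_masks import GlandLabelMap, TarsusMask, label_map_from_array
from meibomorph.morphometry import (
    EyelidMetrics,
    boundary_pixel_mask,
    combine_eyelids,
    eyelid_density,
    gland_height,
    gland_perimeter,
    gland_shapes,
    gland_tortuosity,
    gland_width,
    min_external_rect,
    summarize_eyelid,
)
from conftest import full_tarsus, rect_label_map


def single_shape(labelmap):
    shapes = gland_shapes(labelmap)
    assert len(shapes) == 1
    return shapes[0]


class TestHeightWidth:
    def test_single_column_inclusive_extent(self):
        arr = np.zeros((120, 3), np.uint8)
        arr[10:110, 1] = 1
        s = single_shape(label_map_from_array(arr))
        assert gland_height(s) == 100
        assert gland_height(s, inclusive=False) == 99

    def test_single_pixel_gland(self):
        arr = np.zeros((3, 3), np.uint8)
        arr[1, 1] = 1
        s = single_shape(label_map_from_array(arr))
        assert gland_height(s) == 1
        assert gland_width(s) == 1.0
        assert gland_perimeter(s) == 1
        assert s.minrect_height_px == 1.0

    @pytest.mark.parametrize("h,w", [(50, 2), (20, 5), (100, 10)])
    def test_filled_rectangle(self, h, w):
        s = single_shape(rect_label_map(h, w))
        assert gland_height(s) == h
        assert gland_width(s) == pytest.approx(w)

    def test_l_shape_forced_arithmetic(self):
        # area 75 spanning 50 rows -> width 1.5
        arr = np.zeros((60, 40), np.uint8)
        arr[5:55, 5] = 1  # 50 px column
        arr[54, 6:31] = 1  # 25 px along the bottom row
        s = single_shape(label_map_from_array(arr))
        assert s.area_px == 75
        assert gland_height(s) == 50
        assert gland_width(s) == pytest.approx(1.5)

    def test_width_times_height_equals_area(self, rng):
        for _ in range(20):
            mask = random_blob(rng, int(rng.integers(5, 120)))
            s = single_shape(label_map_from_array(mask.astype(np.uint8)))
            assert gland_width(s) * gland_height(s) == pytest.approx(s.area_px)


class TestPerimeter:
    @pytest.mark.parametrize(
        "builder,expected",
        [
            (lambda: rect_label_map(3, 3), 8),  # all but center
            (lambda: rect_label_map(50, 2), 100),  # every pixel on the boundary
        ],
    )
    def test_known_shapes(self, builder, expected):
        assert single_shape(builder()).perimeter_px == expected

    def test_matches_bruteforce_on_random_blobs(self, rng):
        for _ in range(200):
            mask = random_blob(rng, int(rng.integers(1, 200)))
            fast = int(boundary_pixel_mask(mask.astype(np.int32)).sum())
            assert fast == perimeter_bruteforce(mask)

    def test_border_counts_as_outside(self):
        # gland touching the image edge: edge pixels are boundary pixels
        arr = np.ones((4, 4), np.uint8)
        s = single_shape(label_map_from_array(arr))
        assert s.perimeter_px == 12  # all but the 2x2 interior

    def test_adjacent_glands_bound_each_other(self):
        # two labels sharing an edge: shared-edge pixels are boundary for both
        arr = np.zeros((4, 6), np.int32)
        arr[:, 1:3] = 1
        arr[:, 3:5] = 2
        shapes = gland_shapes(GlandLabelMap(arr))
        assert [s.perimeter_px for s in shapes] == [8, 8]


class TestMinExternalRect:
    def test_axis_aligned_rectangle_uses_pixel_centers(self):
        s = single_shape(rect_label_map(50, 2))
        assert s.minrect_height_px == pytest.approx(49.0, abs=1.0)
        assert s.minrect_angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_rotated_rectangle_height_stable(self):
        # a 50x2-ish bar rotated by 30 deg: long side within 2 px of unrotated
        theta = np.deg2rad(30)
        pts = set()
        for t in np.linspace(0, 49, 600):
            for s_ in np.linspace(-0.5, 0.5, 15):
                r = t * np.cos(theta) - s_ * np.sin(theta)
                c = t * np.sin(theta) + s_ * np.cos(theta)
                pts.add((round(r), round(c) + 30))
        rows = np.array([p[0] for p in pts])
        cols = np.array([p[1] for p in pts])
        h, ang = min_external_rect(rows, cols)
        assert h == pytest.approx(49.0, abs=2.0)
        assert ang == pytest.approx(30.0, abs=2.0)

    def test_minimality_and_exhaustive_oracle(self, rng):
        for _ in range(40):
            mask = random_blob(rng, int(rng.integers(3, 400)))
            rows, cols = np.nonzero(mask)
            _, oracle_area = minrect_exhaustive(rows, cols)
            if oracle_area == 0:
                continue
            area = _rect_area(rows, cols)
            # a true minimum: never beaten by the 0.5 deg grid search, nor by
            # the axis-aligned bounding box (one explicit candidate)
            assert area <= oracle_area * (1 + 1e-9)
            assert area <= np.ptp(rows) * np.ptp(cols) + 1e-9
            assert abs(area - oracle_area) <= 0.01 * oracle_area

    def test_matches_shapely_min_rotated_rectangle(self, rng):
        pytest.importorskip("shapely")
        from shapely import MultiPoint

        for _ in range(20):
            mask = random_blob(rng, int(rng.integers(5, 300)))
            rows, cols = np.nonzero(mask)
            mrr = MultiPoint(list(zip(cols.astype(float), rows.astype(float)))).minimum_rotated_rectangle
            if mrr.geom_type == "Polygon" and mrr.area > 0:
                assert _rect_area(rows, cols) == pytest.approx(mrr.area, rel=1e-6)


def _rect_area(rows, cols):
    """Enclosing-rectangle area at the angle the implementation picked."""
    h, ang = min_external_rect(rows, cols)
    theta = np.deg2rad(ang)
    u = np.array([np.cos(theta), np.sin(theta)])
    v = np.array([-u[1], u[0]])
    pts = np.column_stack([rows, cols]).astype(float)
    du = np.ptp(pts @ u)
    dv = np.ptp(pts @ v)
    return du * dv


class TestTortuosity:
    def test_rectangle_forced_arithmetic(self):
        s = single_shape(rect_label_map(50, 2))
        assert gland_tortuosity(s) == pytest.approx(100 / 98 - 1, abs=1e-9)

    @pytest.mark.parametrize("h", [20, 50, 100])
    @pytest.mark.parametrize("w", [2, 5, 10])
    def test_rectangle_closed_form(self, h, w):
        s = single_shape(rect_label_map(h, w))
        expected = (2 * h + 2 * w - 4) / (2 * (h - 1)) - 1
        assert gland_tortuosity(s) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_sinusoidal_amplitude(self):
        from meibomorph.synthetic import GlandSpec, render_gland

        # fractional center keeps the per-row pixel width identical across
        # amplitudes; several periods give the sinusoid enough lateral slope
        # that meandering exposes extra boundary pixels
        torts = []
        for amp in (0.0, 2.0, 4.0, 6.0, 8.0):
            spec = GlandSpec(length_px=80, half_width_px=2.0, amp_px=amp, n_periods=4.0, center_col=30.3, top_row=5)
            rows, cols = render_gland(spec, (100, 60))
            arr = np.zeros((100, 60), np.uint8)
            arr[rows, cols] = 1
            torts.append(gland_tortuosity(single_shape(label_map_from_array(arr))))
        # small amplitudes shift rows by at most one pixel, which exposes no
        # new boundary on a digitized stripe: non-decreasing there, strictly
        # increasing once the slope exceeds a pixel per row
        assert torts[0] <= torts[1]
        assert all(a < b for a, b in zip(torts[1:], torts[2:]))


class TestDensityAndAggregation:
    def test_density_ratio(self):
        tarsus = np.zeros((100, 100), bool)
        tarsus[5:55, 0:100] = True  # 5000 px
        lab = np.zeros((100, 100), np.int32)
        lab[10:35, 10:30] = 1  # 25 x 20 = 500 px, inside the tarsus
        assert eyelid_density(GlandLabelMap(lab), TarsusMask(tarsus)) == pytest.approx(0.10)

    def test_empty_labelmap_density_zero(self):
        lab = GlandLabelMap(np.zeros((10, 10), np.int32))
        assert eyelid_density(lab, full_tarsus((10, 10))) == 0.0

    def test_glands_tiling_tarsus_density_one(self):
        lab = np.ones((6, 6), np.int32)
        assert eyelid_density(GlandLabelMap(lab), full_tarsus((6, 6))) == 1.0

    def test_density_invariant_under_relabeling_and_translation(self, rng):
        lab = np.zeros((40, 40), np.int32)
        lab[2:12, 2:6] = 1
        lab[20:32, 20:25] = 2
        t = full_tarsus((40, 40))
        d0 = eyelid_density(GlandLabelMap(lab), t)
        swapped = np.where(lab == 1, 2, np.where(lab == 2, 1, 0))
        assert eyelid_density(GlandLabelMap(swapped), t) == d0
        rolled = np.roll(np.roll(lab, 3, axis=0), 5, axis=1)
        assert eyelid_density(GlandLabelMap(rolled), t) == d0

    def test_summarize_two_rectangles(self):
        arr = np.zeros((80, 30), np.uint8)
        arr[5:55, 5:7] = 1  # 50x2
        arr[10:40, 20:22] = 1  # 30x2
        m = summarize_eyelid(label_map_from_array(arr), full_tarsus(arr.shape), "upper")
        assert m.n_glands == 2
        assert m.mean_height_px == pytest.approx(40.0)
        assert m.mean_width_px == pytest.approx(2.0)

    def test_summarize_empty_eyelid(self):
        lab = GlandLabelMap(np.zeros((10, 10), np.int32))
        m = summarize_eyelid(lab, full_tarsus((10, 10)), "lower")
        assert m.n_glands == 0
        assert m.density == 0.0
        assert m.mean_height_px is None

    def test_all_indices_invariant_under_horizontal_mirror(self, rng):
        arr = np.zeros((60, 80), np.uint8)
        for _ in range(3):
            r0 = int(rng.integers(2, 20))
            c0 = int(rng.integers(2, 60))
            arr[r0 : r0 + 30, c0 : c0 + 3] = 1
        lm = label_map_from_array(arr)
        lm_m = label_map_from_array(arr[:, ::-1].copy())
        a = summarize_eyelid(lm, full_tarsus(arr.shape), "upper")
        b = summarize_eyelid(lm_m, full_tarsus(arr.shape), "upper")
        assert a.mean_height_px == pytest.approx(b.mean_height_px)
        assert a.mean_width_px == pytest.approx(b.mean_width_px)
        assert a.mean_tortuosity == pytest.approx(b.mean_tortuosity, abs=1e-9)
        assert a.density == pytest.approx(b.density)


class TestCombineEyelids:
    def _metrics(self, density, height=100.0, n=5):
        return EyelidMetrics("upper", n, height, 2.0, 0.1, density, int(density * 1000), 1000)

    def test_mean_of_two_densities(self):
        both = combine_eyelids(self._metrics(0.19), self._metrics(0.16))
        assert both.density == pytest.approx(0.175)

    def test_idempotent_on_identical_eyelids(self):
        m = self._metrics(0.2)
        both = combine_eyelids(m, m)
        assert both.density == m.density
        assert both.mean_height_px == m.mean_height_px
        assert both.n_glands == 2 * m.n_glands

    def test_missing_eyelid_propagates(self):
        assert combine_eyelids(None, self._metrics(0.2)) is None

    def test_pooled_variant_weights_by_gland_count(self):
        u = EyelidMetrics("upper", 10, 100.0, 2.0, 0.1, 0.2, 200, 1000)
        l = EyelidMetrics("lower", 5, 70.0, 2.0, 0.4, 0.1, 100, 1000)
        both = combine_eyelids(u, l, pooled=True)
        assert both.mean_height_px == pytest.approx((100 * 10 + 70 * 5) / 15)
        assert both.density == pytest.approx(300 / 2000)
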