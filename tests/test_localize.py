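import numpy as np
import pytest

from octlens.config import PipelineConfig
from octlens.curves import EXTRAPOLATED, INTERPOLATED, LayerCurve
from octlens.localize import (detect_edges, find_initial_rows, find_inner_limit,
                              identify_cornea_row, preliminary_localization,
                              row_edge_profile, trace_limit)
from octlens.phantom import PhantomSpec, generate_dataset, generate_phantom
from octlens.preprocess import preprocess


class TestDetectEdges:
    def test_constant_image_has_no_edges(self):
        em = detect_edges(np.full((50, 50), 80.0))
        assert em.edges.sum() == 0

    def test_noiseless_phantom_edges_near_truth(self, central_noiseless):
        img, gt = central_noiseless
        em = detect_edges(img.pixels, 90, 120, 3)
        for name in ("scl_outer", "cornea"):
            truth = gt.curves[name]
            misses = 0
            for col in truth.cols[5:-5]:
                r = int(truth.row_at(col))
                misses += em.edges[r - 2:r + 3, col].sum() == 0
            assert misses <= 0.02 * len(truth)

    def test_raising_thresholds_never_adds_edges(self, central_default):
        img, _ = central_default
        prev = None
        for lo, hi in [(40, 60), (80, 110), (120, 160), (160, 220)]:
            count = detect_edges(img.pixels, lo, hi, 3).edges.sum()
            if prev is not None:
                assert count <= prev
            prev = count

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            detect_edges(np.zeros((10, 10)), 120, 90)


class TestRowProfileAndInitialRows:
    def test_single_horizontal_edge_profile(self):
        edges = np.zeros((80, 120), dtype=bool)
        edges[40, 10:110] = True
        prof = row_edge_profile(edges)
        assert prof[40] == 100
        assert prof.sum() == edges.sum()
        assert np.all(prof[:40] == 0)

    def test_empty_map_gives_zero_vector(self):
        assert np.all(row_edge_profile(np.zeros((30, 30), dtype=bool)) == 0)

    def test_three_sharp_rises_found(self):
        prof = np.zeros(200)
        for r, v in ((50, 120.0), (100, 90.0), (160, 150.0)):
            prof[r:r + 4] = v
        rows = find_initial_rows(prof, threshold=30.0)
        assert len(rows) == 3
        for got, want in zip(rows, (50, 100, 160)):
            assert abs(got - want) <= 2

    def test_two_rises_give_two_rows(self):
        prof = np.zeros(150)
        prof[60:64] = 100.0
        prof[90:96] = 130.0
        assert len(find_initial_rows(prof, threshold=40.0)) == 2

    def test_only_first_three_areas_kept(self):
        prof = np.zeros(300)
        for r in (30, 80, 130, 180, 230):
            prof[r:r + 3] = 100.0
        rows = find_initial_rows(prof, threshold=40.0)
        assert len(rows) == 3
        assert max(rows) <= 135

    def test_no_rise_gives_empty(self):
        assert find_initial_rows(np.zeros(50), threshold=10.0) == []


class TestIdentifyCorneaRow:
    def test_brightest_thickest_band_wins(self, central_noiseless):
        img, gt = central_noiseless
        lens_row = int(gt.curves["scl_outer"].rows[200])
        cornea_row = int(gt.curves["cornea"].rows[200])
        labels = identify_cornea_row(img.pixels, [lens_row, cornea_row])
        assert labels["cornea"] == cornea_row
        assert labels["scl_outer"] == lens_row

    def test_two_candidate_extreme_lower_is_cornea(self, extreme_noiseless):
        img, gt = extreme_noiseless
        top = int(gt.curves["scl_outer"].rows[200])
        lower = int(gt.curves["cornea"].rows[200])
        labels = identify_cornea_row(img.pixels, [top, lower])
        assert labels["cornea"] == lower
        assert labels["scl_outer"] == top

    def test_doubling_cornea_brightness_keeps_label(self, central_noiseless):
        img, gt = central_noiseless
        bright = img.pixels.copy()
        c_row = int(gt.curves["cornea"].rows[200])
        bright[c_row:c_row + 12] = np.minimum(bright[c_row:c_row + 12] * 2, 255)
        labels = identify_cornea_row(bright, [int(gt.curves["scl_outer"].rows[200]), c_row])
        assert labels["cornea"] == c_row


def _edge_image_with_gap(gap_cols=(60, 65)):
    """Straight horizontal bright band whose Canny edge has a forced gap."""
    img = np.zeros((60, 120))
    img[30:36] = 200.0
    em = detect_edges(img, 40, 80, 3)
    edges = em.edges.copy()
    edges[:, gap_cols[0]:gap_cols[1]] = False
    return edges, img


class TestTraceLimit:
    def test_gap_interpolated_linearly(self):
        edges, img = _edge_image_with_gap()
        row = int(np.flatnonzero(edges[:, 30])[0])
        curve = trace_limit(edges, img, (row, 30))
        gap = slice(60 - curve.col_start, 65 - curve.col_start)
        assert np.all(curve.provenance[gap] == INTERPOLATED)
        assert np.allclose(curve.rows[gap], row, atol=0.5)

    def test_isolated_noise_pixel_rejected(self):
        edges, img = _edge_image_with_gap(gap_cols=(0, 0))
        row = int(np.flatnonzero(edges[:, 30])[0])
        edges[row - 6, 70] = True  # lone off-curve pixel
        img[row - 6, 70] = 255.0
        curve = trace_limit(edges, img, (row, 30))
        assert abs(curve.row_at(70) - row) <= 1.0

    def test_noiseless_outer_limit_mae_below_one(self, central_noiseless, config):
        img, gt = central_noiseless
        pre = preprocess(img, config)
        em = detect_edges(pre.image.pixels, config.canny_low, config.canny_high,
                          config.canny_kernel)
        truth = gt.curves["scl_outer"]
        start_row = int(truth.rows[200])
        rr = np.flatnonzero(em.edges[start_row - 2:start_row + 3, 200])
        curve = trace_limit(em, pre.image.pixels, (start_row - 2 + rr[0], 200))
        cols = curve.cols[(curve.cols >= 5) & (curve.cols <= 394)]
        mae = np.abs(curve.row_at(cols) - truth.row_at(cols)).mean()
        assert mae <= 1.0

    def test_start_off_edge_rejected(self):
        edges, img = _edge_image_with_gap()
        with pytest.raises(ValueError):
            trace_limit(edges, img, (5, 5))


class TestFindInnerLimit:
    def test_constant_band_width_recovered(self, central_noiseless, config):
        img, gt = central_noiseless
        pre = preprocess(img, config)
        outer = gt.curves["scl_outer"]
        inner = find_inner_limit(pre.image.pixels, outer,
                                 config.inner_search_depth)
        assert inner is not None
        width = inner.rows - outer.rows
        target = 8.0  # default lens thickness
        assert np.mean(np.abs(width - target) <= 1.5) >= 0.95

    def test_zeroed_column_falls_back_to_running_width(self, central_noiseless, config):
        img, gt = central_noiseless
        px = preprocess(img, config).image.pixels.copy()
        outer = gt.curves["scl_outer"]
        r = int(outer.rows[200])
        px[r - 2:r + 30, 198:203] = px[r - 32, 200]  # locally erase contrast
        inner = find_inner_limit(px, outer, config.inner_search_depth)
        assert inner is not None
        assert inner.provenance[200] == EXTRAPOLATED
        assert abs((inner.rows[200] - outer.rows[200]) - 8.0) <= 2.0

    def test_inner_never_above_outer(self, central_default, config):
        img, gt = central_default
        pre = preprocess(img, config)
        inner = find_inner_limit(pre.image.pixels, gt.curves["scl_outer"])
        assert inner is not None
        assert np.all(inner.rows >= gt.curves["scl_outer"].rows)


class TestPreliminaryLocalization:
    def test_central_gives_three_layers(self, central_default, config):
        img, _ = central_default
        layers = preliminary_localization(preprocess(img, config), config)
        assert layers.region_class == "three_layers"
        assert layers.scl_inner is not None

    def test_extreme_gives_two_layers(self, extreme_noiseless, config):
        img, _ = extreme_noiseless
        layers = preliminary_localization(preprocess(img, config), config)
        assert layers.region_class == "two_layers"
        assert layers.scl_inner is None

    def test_blank_image_raises(self, config):
        blank = np.full((120, 160), 6.0)
        with pytest.raises(ValueError, match="no layers"):
            preliminary_localization(blank, config)

    def test_non_crossing_on_random_phantoms(self, config):
        ds = generate_dataset(12, base_seed=21)
        for img, _ in ds:
            layers = preliminary_localization(preprocess(img, config), config)
            if layers.scl_inner is None:
                continue
            lo = max(layers.scl_outer.col_start, layers.scl_inner.col_start,
                     layers.cornea.col_start)
            hi = min(layers.scl_outer.col_end, layers.scl_inner.col_end,
                     layers.cornea.col_end)
            cols = np.arange(lo, hi + 1)
            assert np.all(layers.scl_outer.row_at(cols)
                          <= layers.scl_inner.row_at(cols) + 1e-9)
            assert np.all(layers.scl_inner.row_at(cols)
                          <= layers.cornea.row_at(cols) + 1e-9)

    def test_deterministic(self, lateral_default, config):
        img, _ = lateral_default
        a = preliminary_localization(preprocess(img, config), config)
        b = preliminary_localization(preprocess(img, config), config)
        assert np.array_equal(a.scl_outer.rows, b.scl_outer.rows)
        assert np.array_equal(a.cornea.rows, b.cornea.rows)
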