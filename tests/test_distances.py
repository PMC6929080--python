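import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octlens.curves import LayerCurve, LayerSet
from octlens.distances import (euclidean, nearest_distance, normal_distance,
                               profile, vertical_distance)
from octlens.geometry import point_segment_distance
from octlens.phantom import PhantomSpec, generate_phantom


def flat_pair(gap=20.0, n=100):
    return (LayerCurve(0, np.full(n, 10.0)),
            LayerCurve(0, np.full(n, 10.0 + gap)))


def slanted_pair(offset=20.0, n=200):
    c = np.arange(n, dtype=float)
    return LayerCurve(0, c.copy()), LayerCurve(0, c + offset)


def brute_nearest(inner: LayerCurve, col: int, cornea: LayerCurve) -> float:
    """Exhaustive point-to-polyline minimum, scanning left to right."""
    p = np.array([float(col), float(inner.row_at(col))])
    pts = cornea.points()
    if len(pts) == 1:
        return float(np.hypot(*(pts[0] - p)))
    return float(point_segment_distance(p, pts[:-1], pts[1:]).min())


class TestEuclidean:
    def test_three_four_five(self):
        assert euclidean((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_identical_points_zero(self):
        assert euclidean((2.5, -1), (2.5, -1)) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            euclidean((0, 0), (1, 2, 3))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    def test_triangle_inequality(self, xs):
        p, q, r = np.array(xs[:2]), np.array(xs[2:4]), np.array(xs[4:])
        assert euclidean(p, r) <= euclidean(p, q) + euclidean(q, r) + 1e-9


class TestVerticalDistance:
    def test_flat_parallel_gap(self):
        inner, cornea = flat_pair(20.0)
        assert vertical_distance(inner, cornea, 50) == pytest.approx(20.0)

    def test_identical_curves_zero(self):
        inner, _ = flat_pair()
        assert vertical_distance(inner, inner, 10) == 0.0

    def test_slanted_lines_show_the_paradigm_bias(self):
        inner, cornea = slanted_pair(20.0)
        # vertical reports the full offset although the true gap is 20/sqrt(2)
        assert vertical_distance(inner, cornea, 100) == pytest.approx(20.0)

    def test_outside_span_is_nan(self):
        inner, cornea = flat_pair()
        assert np.isnan(vertical_distance(inner, cornea, 500))


class TestNormalDistance:
    def test_flat_parallel_gap(self):
        inner, cornea = flat_pair(20.0)
        assert normal_distance(inner, 50, cornea) == pytest.approx(20.0, abs=1e-9)

    def test_slanted_lines_true_gap(self):
        inner, cornea = slanted_pair(20.0)
        assert normal_distance(inner, 100, cornea) == pytest.approx(
            20.0 * np.cos(np.pi / 4), abs=0.1)

    def test_concentric_arcs(self):
        cols = np.arange(120, 281)
        inner_arc = LayerCurve(120, 250 - np.sqrt(120.0 ** 2 - (cols - 200.0) ** 2))
        outer_arc = LayerCurve(120, 250 - np.sqrt(100.0 ** 2 - (cols - 200.0) ** 2))
        # radial separation between concentric circles is exactly 20
        assert normal_distance(inner_arc, 200, outer_arc) == pytest.approx(20.0, abs=0.5)
        assert normal_distance(inner_arc, 230, outer_arc) == pytest.approx(20.0, abs=0.5)

    def test_ray_missing_curve_is_nan(self):
        inner = LayerCurve(0, np.full(30, 10.0))
        cornea = LayerCurve(200, np.full(10, 30.0))
        assert np.isnan(normal_distance(inner, 15, cornea))


class TestNearestDistance:
    def test_flat_parallel_gap(self):
        inner, cornea = flat_pair(20.0)
        assert nearest_distance(inner, 50, cornea) == pytest.approx(20.0)

    def test_slanted_lines_true_gap(self):
        inner, cornea = slanted_pair(20.0)
        assert nearest_distance(inner, 100, cornea) == pytest.approx(
            20.0 / np.sqrt(2), abs=0.01)

    def test_equals_brute_force_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(30, 120))
            base = rng.uniform(50, 150)
            x = np.arange(n)
            rows = (base + rng.uniform(-0.003, 0.003) * (x - n / 2) ** 2
                    + 5 * rng.uniform(-0.5, 0.5) * np.sin(x / rng.uniform(5, 30)))
            cornea = LayerCurve(int(rng.integers(0, 10)), rows)
            inner = LayerCurve(0, np.full(80, rng.uniform(10, 45)))
            col = int(rng.integers(0, 80))
            got = nearest_distance(inner, col, cornea, coarse_step=10,
                                   window_cols=None)
            assert got == pytest.approx(brute_nearest(inner, col, cornea), abs=1e-9)

    def test_tie_breaks_toward_smaller_column(self):
        # symmetric V-shaped cornea: two equally near points, left one wins
        rows = np.abs(np.arange(-10.0, 11.0)) + 30.0
        cornea = LayerCurve(0, rows)
        inner = LayerCurve(0, np.full(21, 10.0))
        d = nearest_distance(inner, 10, cornea, coarse_step=3, window_cols=None)
        assert d == pytest.approx(brute_nearest(inner, 10, cornea), abs=1e-12)


class TestProfile:
    def test_central_phantom_vault_at_apex(self, config):
        img, gt = generate_phantom(PhantomSpec(speckle_sigma=0.0, contrast_decay=0.0,
                                               vault=40.0))
        layers = LayerSet(scl_outer=gt.curves["scl_outer"],
                          cornea=gt.curves["cornea"],
                          scl_inner=gt.curves["scl_inner"])
        prof = profile(layers)
        apex = 200
        v, n, nn = prof.at(apex)
        for val in (v, n, nn):
            assert val == pytest.approx(40.0, abs=0.5)

    def test_lateral_distances_vanish_where_gap_closes(self):
        img, gt = generate_phantom(PhantomSpec(scenario="lateral", speckle_sigma=0.0))
        layers = LayerSet(scl_outer=gt.curves["scl_outer"],
                          cornea=gt.curves["cornea"],
                          scl_inner=gt.curves["scl_inner"])
        prof = profile(layers)
        assert prof.nearest[2] < 1.0       # closed side
        assert prof.nearest[-3] > 30.0     # open side

    def test_two_layer_set_uses_outer_curve(self, extreme_noiseless):
        _, gt = extreme_noiseless
        layers = LayerSet(scl_outer=gt.curves["scl_outer"],
                          cornea=gt.curves["cornea"], scl_inner=None,
                          layer_count=2, region_class="two_layers")
        prof = profile(layers)
        # lens rests on the tissue: clearance equals the lens wall thickness
        assert np.nanmedian(prof.nearest) == pytest.approx(8.0, abs=1.0)

    def test_ordering_invariant_on_random_phantom_profiles(self):
        from octlens.phantom import generate_dataset
        for img, gt in generate_dataset(20, base_seed=33, speckle_sigma=0.0):
            inner = gt.curves.get("scl_inner") or gt.curves["scl_outer"]
            layers = LayerSet(scl_outer=gt.curves["scl_outer"],
                              cornea=gt.curves["cornea"],
                              scl_inner=gt.curves.get("scl_inner"),
                              layer_count=gt.layer_count,
                              region_class="three_layers" if gt.layer_count == 3
                              else "two_layers")
            prof = profile(layers)
            ok = np.isfinite(prof.vertical) & np.isfinite(prof.nearest)
            assert np.all(prof.nearest[ok] <= prof.vertical[ok] + 1e-6)
            ok = np.isfinite(prof.normal) & np.isfinite(prof.nearest)
            assert np.all(prof.nearest[ok] <= prof.normal[ok] + 1e-6)

    def test_paradigms_agree_on_flat_layers(self):
        for gap in (5.0, 20.0, 50.0):
            inner, cornea = flat_pair(gap)
            layers = LayerSet(scl_outer=inner, cornea=cornea, scl_inner=None,
                              layer_count=2, region_class="two_layers")
            prof = profile(layers)
            ok = np.isfinite(prof.normal)
            assert np.allclose(prof.vertical[ok], gap, atol=0.5)
            assert np.allclose(prof.normal[ok], gap, atol=0.5)
            assert np.allclose(prof.nearest[ok], gap, atol=0.5)

    def test_missing_cornea_rejected(self):
        inner, cornea = flat_pair()
        layers = LayerSet(scl_outer=inner, cornea=cornea, scl_inner=None,
                          layer_count=2, region_class="two_layers")
        layers.cornea = None
        with pytest.raises(ValueError):
            profile(layers)
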