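import numpy as np
import pytest

from octlens.config import TUNABLE_NAMES, PipelineConfig
from octlens.curves import LayerCurve, LayerSet
from octlens.optimize import (FAIL_PENALTY, DEState, config_fitness, de_crossover,
                              de_init, de_mutate, de_select, fitness_segmentation,
                              pipeline_bounds, run_de, snap)
from octlens.phantom import generate_dataset


class TestDeInit:
    def test_degenerate_bounds_give_constant_population(self):
        state = de_init([(0.0, 0.0, 1.0)] * 3, 6, seed=0)
        assert np.all(state.population == 0)

    def test_same_seed_reproducible(self):
        a = de_init([(0, 10, 1)] * 4, 8, seed=5)
        b = de_init([(0, 10, 1)] * 4, 8, seed=5)
        assert np.array_equal(a.population, b.population)

    def test_grid_sampling_is_uniform(self):
        state = de_init([(0, 10, 1)], 10000, seed=7)
        vals, counts = np.unique(state.population[:, 0], return_counts=True)
        assert len(vals) == 11
        expected = 10000 / 11
        sd = np.sqrt(10000 * (1 / 11) * (10 / 11))
        assert np.all(np.abs(counts - expected) < 3 * sd)

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            de_init([(0, 1)], 4, seed=0)


class TestDeMutate:
    def test_donor_formula_hand_arithmetic(self):
        state = de_init([(0, 10, 1)] * 2, 5, seed=0)
        state.population[:] = [[1, 1], [3, 2], [1, 0], [9, 9], [9, 9]]

        class FixedRng:
            def choice(self, others, size, replace):
                return np.array([0, 1, 2])

        state.rng = FixedRng()
        assert np.allclose(de_mutate(state, 4, F=0.5), [2.0, 2.0])

    def test_f_zero_returns_first_pick(self):
        state = de_init([(0, 20, 1)] * 3, 8, seed=3)
        donor = de_mutate(state, 0, F=0.0)
        found = np.any(np.all(np.isclose(state.population, donor), axis=1))
        assert found

    def test_donor_always_inside_bounds(self):
        state = de_init([(0, 10, 1)] * 4, 10, seed=1, F=1.8)
        for i in range(1000):
            donor = de_mutate(state, i % 10)
            assert np.all(donor >= 0) and np.all(donor <= 10)
            assert np.allclose(donor, np.round(donor))  # snapped to the grid


class TestDeCrossover:
    def test_cr_one_copies_donor(self):
        t, d = np.zeros(6), np.arange(6.0)
        assert np.array_equal(de_crossover(t, d, 1.0, 0), d)

    def test_cr_zero_takes_exactly_one_donor_dim(self):
        t, d = np.zeros(8), np.ones(8)
        out = de_crossover(t, d, 0.0, 4)
        assert out.sum() == 1.0

    def test_expected_donor_dimensions_at_half_cr(self):
        rng = np.random.default_rng(0)
        t, d = np.zeros(10), np.ones(10)
        total = sum(de_crossover(t, d, 0.5, rng).sum() for _ in range(10000))
        assert total / 10000 == pytest.approx(1 + 0.5 * 9, abs=0.1)


class TestDeSelect:
    def test_lower_trial_wins(self):
        w, f = de_select(np.array([2.0]), np.array([1.0]), lambda x: float(x[0]))
        assert w[0] == 1.0 and f == 1.0

    def test_tie_goes_to_trial(self):
        w, _ = de_select(np.array([5.0]), np.array([7.0]), lambda x: 3.0)
        assert w[0] == 7.0

    def test_failing_fitness_keeps_target(self):
        def fragile(x):
            if x[0] == 9.0:
                raise RuntimeError("boom")
            return float(x[0])

        w, f = de_select(np.array([2.0]), np.array([9.0]), fragile)
        assert w[0] == 2.0 and f == 2.0


class TestRunDe:
    def test_sphere_minimised(self):
        best, hist = run_de(lambda x: float((x ** 2).sum()), [(-5.0, 5.0)] * 5,
                            n=20, F=0.8, CR=0.9, max_gen=200, seed=3,
                            stall_gens=10 ** 6)
        assert (best ** 2).sum() < 1e-6

    def test_history_non_increasing_and_reproducible(self):
        fn = lambda x: float((x ** 2).sum() + np.sin(x).sum())
        b1, h1 = run_de(fn, [(-4.0, 4.0)] * 3, n=12, max_gen=60, seed=11)
        b2, h2 = run_de(fn, [(-4.0, 4.0)] * 3, n=12, max_gen=60, seed=11)
        assert np.all(np.diff(h1) <= 0)
        assert np.array_equal(b1, b2)
        assert h1 == h2

    def test_quadratic_parameter_recovery_on_grid(self):
        target = np.array([3.0, 7.0, 1.0])
        best, _ = run_de(lambda x: float(((x - target) ** 2).sum()),
                         [(0, 10, 1)] * 3, n=20, max_gen=100, seed=5)
        assert np.all(np.abs(best - target) <= 1.0)


@pytest.fixture(scope="module")
def tiny_ds():
    return generate_dataset(4, base_seed=3)


class TestSegmentationFitness:
    @staticmethod
    def _perfect_fn(ds):
        def fn(img, cfg):
            for im, gt in ds:
                if im is img:
                    return LayerSet(
                        scl_outer=gt.curves["scl_outer"],
                        cornea=gt.curves["cornea"],
                        scl_inner=gt.curves.get("scl_inner"),
                        layer_count=gt.layer_count,
                        region_class="three_layers" if gt.layer_count == 3
                        else "two_layers")
            raise KeyError("unknown image")
        return fn

    def test_perfect_segmenter_scores_zero(self, tiny_ds):
        cfg = PipelineConfig()
        assert fitness_segmentation(cfg, tiny_ds, self._perfect_fn(tiny_ds)) == 0.0

    def test_edge_free_config_hits_penalty(self, tiny_ds):
        cfg = PipelineConfig(canny_low=1e5, canny_high=1e5)
        assert fitness_segmentation(cfg, tiny_ds) >= FAIL_PENALTY

    def test_smaller_offsets_score_better(self, tiny_ds):
        perfect = self._perfect_fn(tiny_ds)

        def offset_fn(px):
            def fn(img, cfg):
                ls = perfect(img, cfg)

                def shift(c):
                    return None if c is None else LayerCurve(
                        c.col_start, c.rows + px, c.provenance.copy())

                return LayerSet(scl_outer=shift(ls.scl_outer),
                                cornea=shift(ls.cornea),
                                scl_inner=shift(ls.scl_inner),
                                layer_count=ls.layer_count,
                                region_class=ls.region_class)
            return fn

        cfg = PipelineConfig()
        f2 = fitness_segmentation(cfg, tiny_ds, offset_fn(2.0))
        f10 = fitness_segmentation(cfg, tiny_ds, offset_fn(10.0))
        assert f2 == pytest.approx(2.0)
        assert f10 == pytest.approx(10.0)
        assert f2 < f10

    def test_vector_adapter_round_trip(self):
        cfg = PipelineConfig()
        vec = cfg.to_vector()
        back = PipelineConfig.from_vector(vec)
        for name in TUNABLE_NAMES:
            assert getattr(back, name) == getattr(cfg, name)

    def test_snap_respects_grid(self):
        grid = np.arange(3.0, 32.0, 2.0)
        assert snap(20.2, grid) == 21.0
        assert snap(-5.0, grid) == 3.0

    def test_bounds_cover_default_config(self):
        cfg = PipelineConfig()
        for name, grid in zip(TUNABLE_NAMES, pipeline_bounds()):
            assert float(getattr(cfg, name)) in grid
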