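"""Differential-evolution tuning of the pipeline parameters.

Classic rand/1/bin DE: each generation builds a donor vector
``v = x_r1 + F (x_r2 - x_r3)`` from three distinct population members,
recombines it with the target using crossover probability CR (one dimension
always comes from the donor), and keeps whichever of trial/target has the
lower fitness. The search space is discretised per parameter; donors are
clipped to the bounds and snapped to the grid.

The segmentation fitness runs the full pipeline on a ground-truthed image
set and scores the mean per-curve MAE, with a fixed penalty for images that
fail or get the wrong layer count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig, default_grids
from .curves import LayerSet
from .evaluate import curve_error

FAIL_PENALTY = 100.0  # px-equivalent cost of a failed or misclassified image


def _as_grid(bound) -> np.ndarray | tuple[float, float]:
    """A bound is an explicit grid array, (lo, hi, step) or continuous (lo, hi)."""
    if isinstance(bound, np.ndarray):
        return np.sort(np.asarray(bound, dtype=float))
    if len(bound) == 3:
        lo, hi, step = bound
        return np.round(np.arange(lo, hi + step / 2, step), 12)
    lo, hi = bound
    return (float(lo), float(hi))


def snap(value: float, grid) -> float:
    """Clip to the bound and, for discrete grids, snap to the closest value."""
    if isinstance(grid, tuple):
        return float(np.clip(value, grid[0], grid[1]))
    return float(grid[int(np.argmin(np.abs(grid - value)))])


def _bounds_lo_hi(grid) -> tuple[float, float]:
    if isinstance(grid, tuple):
        return grid
    return float(grid[0]), float(grid[-1])


@dataclass
class DEState:
    """Population, fitnesses and the generation counter of a DE run."""

    population: np.ndarray          # (N, D)
    grids: list                     # per-dimension bound/grid
    rng: np.random.Generator
    F: float = 0.8
    CR: float = 0.9
    generation: int = 0
    fitness: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return self.population.shape[0]

    @property
    def dim(self) -> int:
        return self.population.shape[1]


def de_init(bounds, n: int, seed: int | np.random.Generator = 0,
            F: float = 0.8, CR: float = 0.9) -> DEState:
    """Uniform initial population on the (possibly discretised) bounds."""
    if n <= 4:
        raise ValueError("population size must be greater than four")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grids = [_as_grid(b) for b in bounds]
    pop = np.empty((n, len(grids)))
    for j, g in enumerate(grids):
        if isinstance(g, tuple):
            pop[:, j] = rng.uniform(g[0], g[1], size=n)
        else:
            pop[:, j] = rng.choice(g, size=n)
    return DEState(population=pop, grids=grids, rng=rng, F=F, CR=CR)


def de_mutate(state: DEState, i: int, F: float | None = None) -> np.ndarray:
    """Donor vector x_r1 + F (x_r2 - x_r3), r1 != r2 != r3 != i, clipped to
    the bounds and snapped to the grid."""
    if state.n < 4:
        raise ValueError("need at least 4 population members")
    F = state.F if F is None else F
    if not 0 <= F <= 2:
        raise ValueError("F must lie in [0, 2]")
    others = np.delete(np.arange(state.n), i)
    r1, r2, r3 = state.rng.choice(others, size=3, replace=False)
    donor = state.population[r1] + F * (state.population[r2] - state.population[r3])
    return np.array([snap(v, g) for v, g in zip(donor, state.grids)])


def de_crossover(target: np.ndarray, donor: np.ndarray, CR: float,
                 rng: np.random.Generator | int = 0) -> np.ndarray:
    """Binomial recombination; dimension Irand always comes from the donor."""
    if not 0 <= CR <= 1:
        raise ValueError("CR must lie in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    target = np.asarray(target, dtype=float)
    donor = np.asarray(donor, dtype=float)
    d = target.size
    take = rng.uniform(size=d) <= CR
    take[rng.integers(d)] = True
    return np.where(take, donor, target)


def de_select(target: np.ndarray, trial: np.ndarray, fitness_fn,
              f_target: float | None = None) -> tuple[np.ndarray, float]:
    """Greedy survivor selection: the trial wins on a tie.

    A fitness evaluation failure counts as +inf (the target survives).
    """
    if f_target is None:
        f_target = _safe_fitness(fitness_fn, target)
    f_trial = _safe_fitness(fitness_fn, trial)
    if f_trial <= f_target:
        return trial, f_trial
    return target, f_target


def _safe_fitness(fn, x) -> float:
    try:
        v = float(fn(x))
        return v if np.isfinite(v) or v == np.inf else np.inf
    except Exception:
        return np.inf


def run_de(fitness_fn, bounds, n: int = 150, F: float = 0.8, CR: float = 0.9,
           max_gen: int = 200, seed: int = 0, stall_gens: int = 30,
           stall_tol: float = 1e-3) -> tuple[np.ndarray, list[float]]:
    """Full DE loop; returns the best vector and the best-fitness history.

    Stops after ``max_gen`` generations or when the best fitness has not
    improved by more than ``stall_tol`` for ``stall_gens`` generations.
    """
    state = de_init(bounds, n, seed, F=F, CR=CR)
    state.fitness = np.array([_safe_fitness(fitness_fn, x) for x in state.population])
    history = [float(state.fitness.min())]
    since_improve = 0
    for _ in range(max_gen):
        for i in range(state.n):
            donor = de_mutate(state, i)
            trial = de_crossover(state.population[i], donor, state.CR, state.rng)
            trial = np.array([snap(v, g) for v, g in zip(trial, state.grids)])
            winner, f = de_select(state.population[i], trial, fitness_fn,
                                  f_target=float(state.fitness[i]))
            state.population[i] = winner
            state.fitness[i] = f
        state.generation += 1
        best = float(state.fitness.min())
        if history[-1] - best > stall_tol:
            since_improve = 0
        else:
            since_improve += 1
        history.append(min(best, history[-1]))
        if since_improve >= stall_gens:
            break
    best_i = int(np.argmin(state.fitness))
    return state.population[best_i].copy(), history


def pipeline_bounds() -> list[np.ndarray]:
    """The discretised search space of the ten tunable pipeline parameters."""
    return default_grids()


def fitness_segmentation(config: PipelineConfig, dataset,
                         segment_fn=None) -> float:
    """Mean per-curve MAE (px) over a ground-truthed set, plus a
    ``FAIL_PENALTY`` for every failed or misclassified image.

    ``segment_fn(image, config) -> LayerSet`` (original frame) defaults to
    the full pipeline; injectable for testing.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must not be empty")
    if segment_fn is None:
        from .pipeline import segment_image

        def segment_fn(image, cfg):
            return segment_image(image, cfg).layers

    total = 0.0
    for img, gt in dataset:
        try:
            layers: LayerSet = segment_fn(img, config)
        except Exception:
            total += FAIL_PENALTY
            continue
        pred_count = 3 if layers.region_class == "three_layers" else 2
        cost = 0.0
        if pred_count != gt.layer_count:
            cost += FAIL_PENALTY
        maes = []
        for name, truth in gt.curves.items():
            pred = getattr(layers, name, None)
            if pred is None:
                continue
            try:
                _, m, _ = curve_error(pred, truth)
                maes.append(m)
            except ValueError:
                maes.append(FAIL_PENALTY)
        cost += float(np.mean(maes)) if maes else FAIL_PENALTY
        total += cost
    return total / len(dataset)


def config_fitness(dataset, segment_fn=None, **fixed):
    """Adapter: 10-vector -> PipelineConfig -> segmentation fitness."""
    def fn(vec: np.ndarray) -> float:
        cfg = PipelineConfig.from_vector(vec, repair=True, **fixed)
        return fitness_segmentation(cfg, dataset, segment_fn=segment_fn)
    return fn
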