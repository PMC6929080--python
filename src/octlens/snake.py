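"""Open active-contour ("free snake") refinement of preliminary curves.

The contour v(s) = (x(s), y(s)) has one node per image column; only the row
coordinate evolves, which keeps the layer single-valued per column. The
energy is the classic internal + external split: elasticity (alpha, squared
first differences) plus rigidity (beta, squared second differences) plus a
weighted image potential that is minimal on edges. Evolution is greedy
neighbourhood descent: each node moves to the position of lowest energy
within a small vertical window, end nodes included (free ends), so the total
energy never increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .curves import LayerCurve, as_pixels


@dataclass
class SnakeConfig:
    """Weights and schedule of the contour evolution.

    ``alpha`` penalises stretching, ``beta`` bending; ``edge_weight`` scales
    the image potential. ``move_radius`` is the per-iteration vertical search
    window in px, and convergence is declared when fewer than ``conv_tol`` of
    the nodes move in an iteration.
    """

    alpha: float = 50.0
    beta: float = 20.0
    edge_weight: float = 1.0
    max_iter: int = 400
    move_radius: int = 2
    conv_tol: float = 0.01
    potential_sigma: float = 2.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.edge_weight) < 0:
            raise ValueError("energy weights must be >= 0")
        if self.max_iter < 1 or self.move_radius < 1:
            raise ValueError("max_iter and move_radius must be >= 1")


@dataclass
class SnakeState:
    """Final node positions and the per-iteration total-energy trace."""

    nodes: np.ndarray  # (N, 2) of (col, row)
    energy_trace: list[float] = field(default_factory=list)


def internal_energy(nodes: np.ndarray, alpha: float, beta: float) -> float:
    """Discrete elasticity + rigidity energy of a node sequence.

    Nodes are equally spaced in the column direction, so the constant
    horizontal component of the first difference is omitted; the elasticity
    term reduces to alpha * sum((row first differences)^2) and the rigidity
    term to beta * sum(||second differences||^2) over interior nodes.
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 2 or nodes.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    rows = nodes[:, 1]
    d1 = np.diff(rows)
    d2 = np.diff(nodes, n=2, axis=0)
    return float(alpha * (d1 ** 2).sum() + beta * (d2 ** 2).sum())


def image_potential(img, sigma: float = 2.0) -> np.ndarray:
    """Edge-attraction potential: smoothed gradient magnitude, negated and
    min-max normalised to [-1, 0] (minima on the strongest edges)."""
    px = as_pixels(img)
    gy = ndimage.sobel(px, axis=0)
    gx = ndimage.sobel(px, axis=1)
    mag = ndimage.gaussian_filter(np.hypot(gx, gy), sigma)
    top = mag.max()
    if top == 0:
        return np.zeros_like(mag)
    return -mag / top


def external_energy(point, potential: np.ndarray, weight: float = 1.0) -> float:
    """weight x bilinear sample of the potential at (col, row); points
    outside the field are clamped to the border."""
    h, w = potential.shape
    c = float(np.clip(point[0], 0, w - 1))
    r = float(np.clip(point[1], 0, h - 1))
    r0, c0 = int(r), int(c)
    r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
    fr, fc = r - r0, c - c0
    val = (potential[r0, c0] * (1 - fr) * (1 - fc)
           + potential[r1, c0] * fr * (1 - fc)
           + potential[r0, c1] * (1 - fr) * fc
           + potential[r1, c1] * fr * fc)
    return float(weight * val)


def _sample_rows(potential: np.ndarray, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Vectorised bilinear sample of the potential at (cols, rows)."""
    h, w = potential.shape
    c = np.clip(cols, 0, w - 1)
    r = np.clip(rows, 0, h - 1)
    return ndimage.map_coordinates(potential, [r, c], order=1, mode="nearest")


def total_energy(rows: np.ndarray, cols: np.ndarray, potential: np.ndarray,
                 cfg: SnakeConfig) -> float:
    nodes = np.column_stack([cols, rows])
    e_int = internal_energy(nodes, cfg.alpha, cfg.beta)
    e_ext = cfg.edge_weight * _sample_rows(potential, cols, rows).sum()
    return float(e_int + e_ext)


def evolve(initial: LayerCurve, img, cfg: SnakeConfig | None = None,
           potential: np.ndarray | None = None) -> tuple[LayerCurve, SnakeState]:
    """Greedy snake descent starting from a preliminary curve.

    Nodes are updated in three interleaved sweeps (stride 3) so that
    simultaneously moved nodes never share an energy term; every accepted
    move strictly lowers the total energy, making the energy trace
    non-increasing. Returns the refined curve (same column span) and the
    evolution state.
    """
    cfg = cfg or SnakeConfig()
    if len(initial) < 5:
        raise ValueError("initial curve must have at least 5 points")
    if potential is None:
        potential = image_potential(img, cfg.potential_sigma)
    cols = initial.cols.astype(float)
    icols = initial.cols
    rows = initial.rows.astype(np.float64).copy()
    n = rows.size
    alpha, beta, w = cfg.alpha, cfg.beta, cfg.edge_weight
    h = potential.shape[0]
    R = float(cfg.move_radius)
    n_cells = 2 * cfg.move_radius + 2

    trace = [total_energy(rows, cols, potential, cfg)]
    for _ in range(cfg.max_iter):
        moved = 0
        for phase in range(3):
            idx = np.arange(phase, n, 3)
            if idx.size == 0:
                continue
            r_cur = rows[idx]
            prev_r = np.where(idx > 0, rows[np.maximum(idx - 1, 0)], np.nan)
            next_r = np.where(idx < n - 1, rows[np.minimum(idx + 1, n - 1)], np.nan)
            pp = np.where(idx > 1, rows[np.maximum(idx - 2, 0)], np.nan)
            nn = np.where(idx < n - 2, rows[np.minimum(idx + 2, n - 1)], np.nan)
            # quadratic internal energy in r: a r^2 + b r (+ const, dropped);
            # each term is present only where its neighbours exist
            a = np.zeros(idx.size)
            b = np.zeros(idx.size)
            for coef_a, coef_b, present in (
                (alpha, -2 * alpha * prev_r, ~np.isnan(prev_r)),
                (alpha, -2 * alpha * next_r, ~np.isnan(next_r)),
                (4 * beta, -4 * beta * (prev_r + next_r),
                 ~np.isnan(prev_r) & ~np.isnan(next_r)),
                (beta, 2 * beta * (pp - 2 * prev_r), ~np.isnan(pp)),
                (beta, 2 * beta * (nn - 2 * next_r), ~np.isnan(nn)),
            ):
                a += np.where(present, coef_a, 0.0)
                b += np.where(present, np.where(present, coef_b, 0.0), 0.0)
            # candidate integer cells [k, k+1] covering the move window
            k0 = np.floor(r_cur - R).astype(int)
            ks = k0[:, None] + np.arange(n_cells)[None, :]
            ks_cl = np.clip(ks, 0, h - 2)
            pot_lo = potential[ks_cl, icols[idx, None]]
            pot_hi = potential[ks_cl + 1, icols[idx, None]]
            slope = w * (pot_hi - pot_lo)
            # within each cell the energy is a r^2 + (b + slope) r + const
            lo = np.maximum(ks_cl.astype(float), (r_cur - R)[:, None])
            hi = np.minimum(ks_cl + 1.0, (r_cur + R)[:, None])
            lo = np.clip(lo, 0, h - 1)
            hi = np.clip(hi, 0, h - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                r_star = -(b[:, None] + slope) / (2 * a[:, None])
            r_star = np.where(np.isfinite(r_star), r_star, lo)
            r_star = np.clip(r_star, lo, hi)
            e_cand = (a[:, None] * r_star ** 2 + (b[:, None] + slope) * r_star
                      + w * (pot_lo - ks_cl * (pot_hi - pot_lo)))
            e_cand = np.where(hi >= lo, e_cand, np.inf)
            best = np.argmin(e_cand, axis=1)
            r_new = r_star[np.arange(idx.size), best]
            e_new = e_cand[np.arange(idx.size), best]
            # energy of staying put, same decomposition
            cell_cur = np.clip(np.floor(r_cur).astype(int), 0, h - 2)
            s_cur = w * (potential[cell_cur + 1, icols[idx]]
                         - potential[cell_cur, icols[idx]])
            e_stay = (a * r_cur ** 2 + (b + s_cur) * r_cur
                      + w * potential[cell_cur, icols[idx]] - cell_cur * s_cur)
            accept = e_new < e_stay - 1e-12
            rows[idx] = np.where(accept, r_new, r_cur)
            moved += int(np.count_nonzero(accept & (np.abs(r_new - r_cur) > 1e-9)))
        trace.append(total_energy(rows, cols, potential, cfg))
        if moved == 0 or moved < cfg.conv_tol * n:
            break
    refined = LayerCurve(initial.col_start, rows, initial.provenance.copy())
    state = SnakeState(nodes=np.column_stack([cols, rows]), energy_trace=trace)
    return refined, state
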