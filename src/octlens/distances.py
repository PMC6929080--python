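"""Cornea-lens clearance under three point-correspondence paradigms.

For every column of the lens boundary facing the cornea the clearance is
measured as (1) the vertical distance to the cornea in the same column,
(2) the distance along the normal to the local tangent until the cornea is
crossed, and (3) the distance to the nearest point of the cornea polyline.
All three use the Euclidean metric; the nearest-point value can never
exceed the other two. Distances are in pixels, optionally scaled to
micrometres by the image's pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import LayerCurve, LayerSet, shared_cols
from .geometry import fit_tangent, point_segment_distance


def euclidean(p, q) -> float:
    """Euclidean distance between two points of equal dimensionality."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("points must have the same dimensionality")
    return float(np.sqrt(((q - p) ** 2).sum()))


@dataclass
class DistanceProfile:
    """Per-column clearance under each paradigm (NaN where undefined)."""

    cols: np.ndarray
    vertical: np.ndarray
    normal: np.ndarray
    nearest: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        n = len(self.cols)
        for name in ("vertical", "normal", "nearest"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must match cols")
            setattr(self, name, arr)
        self.cols = np.asarray(self.cols, dtype=int)

    def at(self, col: int) -> tuple[float, float, float]:
        """(vertical, normal, nearest) at one column; the point-query hook."""
        i = np.flatnonzero(self.cols == col)
        if i.size == 0:
            raise ValueError(f"column {col} outside profile span")
        i = int(i[0])
        return float(self.vertical[i]), float(self.normal[i]), float(self.nearest[i])

    def in_um(self) -> "DistanceProfile":
        if self.pixel_size_um is None:
            raise ValueError("no pixel size attached")
        s = self.pixel_size_um
        return DistanceProfile(self.cols.copy(), self.vertical * s,
                               self.normal * s, self.nearest * s, None)


def vertical_distance(inner: LayerCurve, cornea: LayerCurve, col: int) -> float:
    """|row difference| in the same column; NaN outside either span."""
    if not (inner.col_start <= col <= inner.col_end
            and cornea.col_start <= col <= cornea.col_end):
        return float("nan")
    return abs(float(cornea.row_at(col)) - float(inner.row_at(col)))


def normal_distance(inner: LayerCurve, col: int, cornea: LayerCurve,
                    tangent_window: int = 10) -> float:
    """Distance along the normal of the lens boundary until the cornea.

    The tangent comes from a least-squares line over ``tangent_window``
    columns centred on ``col``; the ray is cast toward the cornea and
    intersected exactly with the cornea's polyline segments. NaN when the
    ray leaves the cornea's span without crossing it.
    """
    if not (inner.col_start <= col <= inner.col_end):
        return float("nan")
    half = max(tangent_window // 2, 1)
    lo = max(inner.col_start, col - half)
    hi = min(inner.col_end, col + half)
    if hi - lo < half:
        return float("nan")
    cs = np.arange(lo, hi + 1)
    slope = fit_tangent(cs, inner.row_at(cs))
    p = np.array([float(col), float(inner.row_at(col))])
    # unit normal to tangent (1, slope); orient toward the cornea
    nvec = np.array([-slope, 1.0]) / np.hypot(slope, 1.0)
    probe = cornea.row_at(np.clip(col, cornea.col_start, cornea.col_end))
    if probe < p[1]:
        nvec = -nvec
    a = cornea.points()[:-1]
    b = cornea.points()[1:]
    if len(a) == 0:
        return float("nan")
    # solve p + t n = a + u (b - a), 0 <= u <= 1, t > 0
    d = b - a
    denom = d[:, 0] * (-nvec[1]) + d[:, 1] * nvec[0]  # cross(d, -n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ap = p - a
        u = (ap[:, 0] * (-nvec[1]) + ap[:, 1] * nvec[0]) / denom
        t = (d[:, 0] * ap[:, 1] - d[:, 1] * ap[:, 0]) / denom
    valid = np.isfinite(t) & np.isfinite(u) & (u >= -1e-9) & (u <= 1 + 1e-9) & (t > 1e-9)
    if not np.any(valid):
        return float("nan")
    return float(t[valid].min())


def nearest_distance(inner: LayerCurve, col: int, cornea: LayerCurve,
                     coarse_step: int = 10, window_cols: int | None = 50) -> float:
    """Two-stage closest-point search against the cornea polyline.

    A coarse scan every ``coarse_step`` vertices inside a window around the
    vertical projection picks a basin; the refinement then measures exact
    point-to-segment distances around the winner (the same-column segments
    are always included, so the result never exceeds the vertical distance).
    ``window_cols=None`` searches the whole curve. Ties break toward the
    smaller column.
    """
    if not (inner.col_start <= col <= inner.col_end) or len(cornea) == 0:
        return float("nan")
    p = np.array([float(col), float(inner.row_at(col))])
    pts = cornea.points()
    if len(pts) == 1:
        return euclidean(p, pts[0])
    proj = int(np.clip(col, cornea.col_start, cornea.col_end)) - cornea.col_start
    if window_cols is None:
        lo, hi = 0, len(pts) - 1
    else:
        lo = max(0, proj - window_cols)
        hi = min(len(pts) - 1, proj + window_cols)
    # coarse pass over vertices (vertical projection always included)
    step = max(coarse_step, 1)
    coarse_idx = np.unique(np.clip(np.r_[np.arange(lo, hi + 1, step), hi, proj],
                                   lo, hi))
    dv = np.hypot(pts[coarse_idx, 0] - p[0], pts[coarse_idx, 1] - p[1])
    order = np.argsort(dv, kind="stable")
    # refinement: exact distance to every segment near the two best coarse
    # basins and near the vertical projection
    centres = [int(coarse_idx[order[0]]), proj]
    if order.size > 1:
        centres.append(int(coarse_idx[order[1]]))
    seg_idx = set()
    for c0 in centres:
        for k in range(c0 - step - 1, c0 + step + 1):
            if lo <= k <= hi and k < len(pts) - 1:
                seg_idx.add(k)
    seg_idx = np.array(sorted(seg_idx))
    if seg_idx.size == 0:
        return float(dv.min())
    dists = point_segment_distance(p, pts[seg_idx], pts[seg_idx + 1])
    return float(dists.min())


def profile(layers: LayerSet, tangent_window: int = 10, coarse_step: int = 10,
            window_cols: int | None = 50,
            pixel_size_um: float | None = None) -> DistanceProfile:
    """All three paradigms on every column shared by the lens boundary
    facing the cornea and the cornea itself."""
    if layers.cornea is None:
        raise ValueError("layer set has no cornea curve")
    lens = layers.innermost_lens_curve
    cols = shared_cols(lens, layers.cornea)
    if cols.size == 0:
        raise ValueError("no shared columns between lens and cornea curves")
    vert = np.array([vertical_distance(lens, layers.cornea, c) for c in cols])
    norm = np.array([normal_distance(lens, c, layers.cornea, tangent_window)
                     for c in cols])
    near = np.array([nearest_distance(lens, c, layers.cornea, coarse_step,
                                      window_cols) for c in cols])
    # the closest point can never be farther than the other correspondences
    near = np.minimum(near, np.where(np.isnan(vert), np.inf, vert))
    near = np.minimum(near, np.where(np.isnan(norm), np.inf, norm))
    return DistanceProfile(cols, vert, norm, near, pixel_size_um)
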