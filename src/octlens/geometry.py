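"""Rotation with canvas expansion and small planar-geometry primitives.

All point transforms use (x, y) = (col, row) order to match
``skimage.transform``; the rest of the package indexes rasters as (row, col).
"""

from __future__ import annotations

import numpy as np
from skimage.transform import AffineTransform, warp


def rotation_transform(shape: tuple[int, int], angle_deg: float) -> tuple[AffineTransform, tuple[int, int]]:
    """Affine transform rotating about the image centre, shifted so the full
    rotated footprint fits in a new canvas anchored at (0, 0).

    Returns the forward transform (input (x,y) -> output (x,y)) and the
    output (height, width).
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    core = (
        AffineTransform(translation=(-cx, -cy))
        + AffineTransform(rotation=theta)
        + AffineTransform(translation=(cx, cy))
    )
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    moved = core(corners)
    shift = moved.min(axis=0)
    tform = core + AffineTransform(translation=-shift)
    span = moved.max(axis=0) - shift
    out_w = int(np.ceil(span[0])) + 1
    out_h = int(np.ceil(span[1])) + 1
    return tform, (out_h, out_w)


def rotate_expand(pixels: np.ndarray, angle_deg: float, order: int = 1) -> tuple[np.ndarray, AffineTransform]:
    """Rotate with bilinear resampling onto an expanded canvas (fill 0).

    Returns the rotated raster and the forward point transform.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if angle_deg == 0:
        return pixels.copy(), AffineTransform()
    tform, out_shape = rotation_transform(pixels.shape, angle_deg)
    rotated = warp(pixels, inverse_map=tform.inverse, output_shape=out_shape,
                   order=order, cval=0.0, preserve_range=True)
    return rotated, tform


def transform_curve_points(cols: np.ndarray, rows: np.ndarray, tform: AffineTransform) -> tuple[np.ndarray, np.ndarray]:
    """Map curve vertices (col, row) through an affine transform."""
    pts = tform(np.column_stack([np.asarray(cols, float), np.asarray(rows, float)]))
    return pts[:, 0], pts[:, 1]


def resample_to_columns(x: np.ndarray, y: np.ndarray) -> tuple[int, np.ndarray]:
    """Re-express transformed vertices as one row per integer column.

    Input points must describe a single-valued curve after sorting by x.
    Returns (col_start, rows) over the integer columns inside [min x, max x].
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    c0 = int(np.ceil(xs[0]))
    c1 = int(np.floor(xs[-1]))
    if c1 < c0:
        raise ValueError("curve footprint narrower than one column")
    cols = np.arange(c0, c1 + 1)
    return c0, np.interp(cols, xs, ys)


def point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from point ``p`` (2,) to segments a->b.

    ``a`` and ``b`` are (N, 2); returns (N,) distances.
    """
    p = np.asarray(p, float)
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.zeros(len(a))
    nz = denom > 0
    t[nz] = np.einsum("ij,ij->i", (p - a)[nz], ab[nz]) / denom[nz]
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(p - proj).T)


def fit_tangent(cols: np.ndarray, rows: np.ndarray) -> float:
    """Least-squares slope d(row)/d(col) through the given samples."""
    cols = np.asarray(cols, float)
    rows = np.asarray(rows, float)
    if cols.size < 2:
        return 0.0
    c = cols - cols.mean()
    denom = (c ** 2).sum()
    if denom == 0:
        return 0.0
    return float((c * (rows - rows.mean())).sum() / denom)
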