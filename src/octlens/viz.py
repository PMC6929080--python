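"""Clearance heatmap rendering and point queries.

The clearance profile is painted along the lens boundary facing the cornea
as a 3-px polyline over the grayscale image: red where the lens is closest
to the cornea, green where it is farthest, linear RGB interpolation in
between. Columns with undefined distance stay uncoloured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import LayerSet, as_pixels
from .distances import DistanceProfile

PARADIGMS = ("vertical", "normal", "nearest")

RED = np.array([255, 0, 0], dtype=float)
GREEN = np.array([0, 255, 0], dtype=float)


@dataclass
class HeatmapRender:
    """RGB overlay plus the colour-scale range actually used."""

    rgb: np.ndarray
    vmin: float
    vmax: float
    paradigm: str


def distance_to_rgb(d: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Linear red (minimum) to green (maximum) map; degenerate ranges are
    all-red since every distance is then the minimum."""
    d = np.asarray(d, dtype=float)
    if vmax <= vmin:
        t = np.zeros_like(d)
    else:
        t = np.clip((d - vmin) / (vmax - vmin), 0.0, 1.0)
    t = np.nan_to_num(t)  # NaN columns get a colour that is never drawn
    return np.rint(RED[None, :] * (1 - t[:, None]) + GREEN[None, :] * t[:, None]).astype(np.uint8)


def render_heatmap(img, layers: LayerSet, prof: DistanceProfile,
                   paradigm: str = "nearest", thickness: int = 3) -> HeatmapRender:
    """Overlay the chosen paradigm's distances along the lens boundary."""
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    d = getattr(prof, paradigm)
    finite = np.isfinite(d)
    if not np.any(finite):
        raise ValueError("profile has no finite distances for this paradigm")
    vmin, vmax = float(d[finite].min()), float(d[finite].max())
    colors = distance_to_rgb(d, vmin, vmax)

    px = as_pixels(img)
    rgb = np.repeat(np.clip(np.rint(px), 0, 255).astype(np.uint8)[:, :, None], 3, axis=2)
    lens = layers.innermost_lens_curve
    h = rgb.shape[0]
    half = thickness // 2
    for i, c in enumerate(prof.cols):
        if not finite[i]:
            continue
        if not (lens.col_start <= c <= lens.col_end) or not (0 <= c < rgb.shape[1]):
            continue
        r = int(round(float(lens.row_at(c))))
        rgb[max(0, r - half):min(h, r + half + 1), c] = colors[i]
    return HeatmapRender(rgb=rgb, vmin=vmin, vmax=vmax, paradigm=paradigm)


def query_point(prof: DistanceProfile, col: int) -> tuple[float, float, float]:
    """The stored (vertical, normal, nearest) distances at one column."""
    return prof.at(col)
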