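"""Core data containers shared across the pipeline.

Conventions: images are 2-D rasters indexed ``(row, col)`` with row 0 at the
top and rows growing downward; layer boundaries are single-valued per column
and stored as one sub-pixel row value per integer column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# provenance codes for curve samples
TRACED = 0
INTERPOLATED = 1
EXTRAPOLATED = 2
PROVENANCE_NAMES = {TRACED: "traced", INTERPOLATED: "interpolated", EXTRAPOLATED: "extrapolated"}


@dataclass
class GrayImage:
    """Single-channel raster with optional physical pixel size.

    ``pixels`` is kept as float64 in [0, 255]; 8-bit input is promoted on
    construction so downstream arithmetic never wraps.
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixels")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_pixels(img) -> np.ndarray:
    """Accept a GrayImage or a bare 2-D array; return the float pixel grid."""
    if isinstance(img, GrayImage):
        return img.pixels
    px = np.asarray(img, dtype=np.float64)
    if px.ndim != 2 or px.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    return px


@dataclass
class LayerCurve:
    """Ordered sub-pixel boundary polyline: one row value per image column.

    ``col_start`` anchors the contiguous column span; ``rows[i]`` is the
    boundary row at column ``col_start + i``. ``provenance`` records, per
    column, whether the sample was traced from image evidence, interpolated
    across a gap, or extrapolated from neighbours.
    """

    col_start: int
    rows: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.rows.ndim != 1 or self.rows.size == 0:
            raise ValueError("curve needs at least one column")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("curve rows must be finite")
        if self.provenance is None:
            self.provenance = np.full(self.rows.size, TRACED, dtype=np.int8)
        else:
            self.provenance = np.asarray(self.provenance, dtype=np.int8)
            if self.provenance.shape != self.rows.shape:
                raise ValueError("provenance must match rows")

    @property
    def col_end(self) -> int:
        """Inclusive last column of the span."""
        return self.col_start + self.rows.size - 1

    @property
    def cols(self) -> np.ndarray:
        return np.arange(self.col_start, self.col_start + self.rows.size)

    def __len__(self) -> int:
        return self.rows.size

    def row_at(self, col) -> np.ndarray:
        """Linearly interpolated row at (possibly fractional) columns."""
        return np.interp(col, self.cols, self.rows)

    def points(self) -> np.ndarray:
        """(N, 2) array of (col, row) vertices."""
        return np.column_stack([self.cols.astype(float), self.rows])

    def restricted(self, col_lo: int, col_hi: int) -> "LayerCurve":
        """Sub-curve on the intersection of the span with [col_lo, col_hi]."""
        lo = max(self.col_start, int(col_lo))
        hi = min(self.col_end, int(col_hi))
        if hi < lo:
            raise ValueError("empty restriction")
        i0 = lo - self.col_start
        i1 = hi - self.col_start + 1
        return LayerCurve(lo, self.rows[i0:i1].copy(), self.provenance[i0:i1].copy())


def shared_cols(a: LayerCurve, b: LayerCurve) -> np.ndarray:
    """Integer columns covered by both curves (may be empty)."""
    lo = max(a.col_start, b.col_start)
    hi = min(a.col_end, b.col_end)
    if hi < lo:
        return np.empty(0, dtype=int)
    return np.arange(lo, hi + 1)


@dataclass
class LayerSet:
    """Up to three detected boundaries plus the image's layer-count class.

    ``confidence`` is the inner-limit distinctness fraction (share of shared
    columns where the lens inner limit separates from the cornea by more than
    the merge tolerance); it is the continuous score behind the binary
    two/three-layer call and feeds ROC analysis.
    """

    scl_outer: LayerCurve
    cornea: LayerCurve
    scl_inner: LayerCurve | None = None
    layer_count: int = 3
    region_class: str = "three_layers"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.region_class not in ("three_layers", "two_layers"):
            raise ValueError(f"unknown region class {self.region_class!r}")
        if (self.scl_inner is not None) != (self.layer_count == 3):
            raise ValueError("layer_count inconsistent with presence of scl_inner")

    @property
    def innermost_lens_curve(self) -> LayerCurve:
        """The lens boundary facing the cornea (inner limit if distinct)."""
        return self.scl_inner if self.scl_inner is not None else self.scl_outer
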