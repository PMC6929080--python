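"""Preliminary localization of the lens and cornea boundaries.

Pipeline: Canny edge extraction, a per-row edge-count profile whose first
derivative marks the initial searching rows, identification of which row
belongs to the cornea, pixel-by-pixel tracing of each boundary with three
robustness criteria (artifact rejection, smoothness tie-break toward the
orientation-extrapolated point, gap interpolation), and a derivative-based
search for the lens inner limit below the traced outer limit. The result is
an up-to-three-curve LayerSet plus the two/three-layer class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.filters import threshold_otsu

from .config import PipelineConfig
from .curves import (EXTRAPOLATED, INTERPOLATED, TRACED, LayerCurve, LayerSet,
                     as_pixels, shared_cols)
from .geometry import fit_tangent
from .preprocess import PreprocessedImage


@dataclass
class EdgeMap:
    """Binary edge raster plus the detector settings that produced it."""

    edges: np.ndarray
    params_echo: dict

    @property
    def shape(self) -> tuple[int, int]:
        return self.edges.shape


def detect_edges(img, low: float = 90.0, high: float = 120.0,
                 kernel: int = 3) -> EdgeMap:
    """Canny with hysteresis thresholds on the 8-bit Sobel-magnitude scale.

    ``kernel`` sets the Gaussian derivative scale (sigma = kernel / 3), the
    role the aperture size plays in kernel-based Canny implementations.
    """
    if not (0 <= low <= high):
        raise ValueError("need 0 <= low <= high")
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    px = as_pixels(img)
    edges = canny(px, sigma=kernel / 3.0, low_threshold=low, high_threshold=high)
    return EdgeMap(edges=edges,
                   params_echo={"low": low, "high": high, "kernel": kernel})


def row_edge_profile(edges: EdgeMap | np.ndarray) -> np.ndarray:
    """Edge-pixel count per image row."""
    e = edges.edges if isinstance(edges, EdgeMap) else np.asarray(edges)
    if e.size == 0:
        raise ValueError("empty edge map")
    return e.sum(axis=1).astype(float)


def find_initial_rows(profile: np.ndarray, threshold: float | None = None,
                      max_rows: int = 3, min_support: float = 0.0,
                      merge_gap: int = 4) -> list[int]:
    """Rows where the profile's forward difference rises sharply.

    ``threshold`` defaults to mean + 2 SD of the positive forward
    differences. Nearby trigger rows are merged into one area (the area's
    first row is returned, i.e. the top of the accumulation); only areas
    whose peak row count reaches ``min_support`` (in edge pixels) qualify.
    The first ``max_rows`` areas from the top are returned.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ValueError("profile too short")
    d = np.diff(profile)
    if threshold is None:
        if not np.any(d > 0):
            return []
        threshold = d.mean() + 2.0 * d.std()
    trigger = np.flatnonzero(d > threshold)  # rise between rows r and r+1
    if trigger.size == 0:
        return []
    rows: list[int] = []
    group_start = trigger[0]
    prev = trigger[0]
    groups = []
    for t in trigger[1:]:
        if t - prev <= merge_gap:
            prev = t
        else:
            groups.append((group_start, prev))
            group_start = prev = t
    groups.append((group_start, prev))
    for start, end in groups:
        # edge pixels accumulated over the area's rows must be enough to
        # support a boundary spanning a meaningful share of the width; a
        # curved boundary spreads over rows, so look a few rows past the rise
        support = profile[start + 1:end + 10].sum()
        if support >= min_support:
            rows.append(int(start + 1))
        if len(rows) >= max_rows:
            break
    return rows


def identify_cornea_row(img, candidate_rows: list[int],
                        band_height: int = 20) -> dict:
    """Label the candidate searching rows.

    The cornea row is the candidate with the most significant intensity
    variation in the band just below it (the tissue is brighter and thicker
    than the lens walls); the topmost remaining row is the SCL outer limit
    and any other the SCL inner limit.
    """
    if not 1 <= len(candidate_rows) <= 3:
        raise ValueError("need 1-3 candidate rows")
    px = as_pixels(img)
    h = px.shape[0]
    scores = []
    for r in candidate_rows:
        band = px[r:min(r + band_height, h)]
        scores.append(float(band.sum()))
    cornea = candidate_rows[int(np.argmax(scores))]
    rest = [r for r in candidate_rows if r != cornea]
    labels = {"cornea": cornea}
    if rest:
        labels["scl_outer"] = min(rest)
    if len(rest) > 1:
        labels["scl_inner"] = sorted(rest)[1]
    return labels


def _find_start_point(edges: np.ndarray, row: int, window: int = 12) -> tuple[int, int] | None:
    """Edge pixel nearest the image-centre column within rows [row-2, row+window]."""
    h, w = edges.shape
    lo = max(0, row - 2)
    hi = min(h, row + window + 1)
    rr, cc = np.nonzero(edges[lo:hi])
    if rr.size == 0:
        return None
    centre = w / 2.0
    i = int(np.argmin(np.abs(cc - centre)))
    return (int(rr[i] + lo), int(cc[i]))


def _predict_row(cols: list[int], rows: list[float], next_col: int,
                 window: int = 10) -> float:
    """Theoretical next row from the orientation of the last traced points."""
    n = min(len(cols), window)
    c = np.asarray(cols[-n:], dtype=float)
    r = np.asarray(rows[-n:], dtype=float)
    if n == 1:
        return float(r[-1])
    slope = fit_tangent(c, r)
    return float(r[-1] + slope * (next_col - c[-1]))


def _neighbour_count(edges: np.ndarray, r: int, c: int) -> int:
    h, w = edges.shape
    return int(edges[max(0, r - 2):min(h, r + 3), max(0, c - 2):min(w, c + 3)].sum())


def trace_limit(edges: EdgeMap | np.ndarray, img, start: tuple[int, int],
                window_up: int = 7, window_down: int = 7,
                max_extrapolation_cols: int = 30,
                min_neighbours: int = 3, reacquire_tol: float = 3.0,
                max_step: float = 3.0) -> LayerCurve:
    """Grow a boundary column by column from a seed edge point.

    Per column, candidate edge pixels within [prediction - window_up,
    prediction + window_down] are screened by the artifact criterion
    (at least ``min_neighbours`` edge pixels in the 5x5 neighbourhood and a
    local intensity above the Otsu level of the image); among survivors the
    one closest to the orientation-extrapolated theoretical row wins. With
    no survivor the trace continues along the previous orientation; a gap
    that later closes is re-filled by linear interpolation, while a run of
    more than ``max_extrapolation_cols`` unsupported columns ends the trace
    (the unsupported tail is dropped).
    """
    e = edges.edges if isinstance(edges, EdgeMap) else np.asarray(edges)
    px = as_pixels(img)
    r0, c0 = int(start[0]), int(start[1])
    if not e[r0, c0]:
        raise ValueError("start point must lie on an edge pixel")
    # foreground/background split of the whole frame; separates band pixels
    # from the dark background without cutting between the two bands
    otsu = threshold_otsu(px) if px.size > 256 and np.ptp(px) > 0 else -np.inf
    h, w = e.shape

    def grow(direction: int) -> tuple[list[int], list[float], list[int]]:
        cols = [c0]
        rows = [float(r0)]
        prov = [TRACED]
        unsupported = 0
        gap_start = None  # index into lists where the current gap began
        c = c0
        while True:
            c += direction
            if c < 0 or c >= w:
                break
            pred = _predict_row(cols, rows, c)
            lo = int(np.floor(pred - window_up))
            hi = int(np.ceil(pred + window_down))
            lo, hi = max(0, lo), min(h - 1, hi)
            chosen = None
            if lo <= hi:
                cand = np.flatnonzero(e[lo:hi + 1, c]) + lo
                best = None
                for r in cand:
                    # smoothness: a layer boundary cannot jump rows faster
                    # than its local orientation allows
                    if abs(r - rows[-1]) > max_step:
                        continue
                    if _neighbour_count(e, r, c) < min_neighbours:
                        continue
                    # a boundary pixel sits on the dark side of its band, so
                    # judge intensity over a window reaching into the band
                    local = px[max(0, r - 2):r + 4, max(0, c - 1):c + 2].max()
                    if local < 0.9 * otsu:
                        continue
                    d = abs(r - pred)
                    if best is None or d < best[0]:
                        best = (d, int(r))
                if best is not None:
                    chosen = best[1]
                    # while bridging a gap, only reacquire near the predicted
                    # continuation: a parallel neighbouring boundary inside
                    # the window must not capture the trace
                    if unsupported > 0 and best[0] > reacquire_tol:
                        chosen = None
            if chosen is not None:
                if gap_start is not None:
                    # close the gap: straight re-interpolation across it
                    i0 = gap_start - 1
                    span = len(cols) - i0
                    filled = np.linspace(rows[i0], float(chosen), span + 1)[1:-1]
                    for j, v in enumerate(filled):
                        rows[i0 + 1 + j] = float(v)
                        prov[i0 + 1 + j] = INTERPOLATED
                    gap_start = None
                cols.append(c)
                rows.append(float(chosen))
                prov.append(TRACED)
                unsupported = 0
            else:
                if gap_start is None:
                    gap_start = len(cols)
                cols.append(c)
                rows.append(pred)
                prov.append(EXTRAPOLATED)
                unsupported += 1
                if unsupported > max_extrapolation_cols:
                    break
        # drop the trailing unsupported run
        while prov and prov[-1] == EXTRAPOLATED:
            cols.pop(), rows.pop(), prov.pop()
        return cols, rows, prov

    rc, rr, rp = grow(+1)
    lc, lr, lp = grow(-1)
    cols = lc[::-1][:-1] + rc
    rows = lr[::-1][:-1] + rr
    prov = lp[::-1][:-1] + rp
    return LayerCurve(cols[0], np.asarray(rows), np.asarray(prov))


def find_inner_limit(img, outer: LayerCurve, search_depth: int = 25,
                     min_signal_frac: float = 0.1,
                     depth_limit: np.ndarray | None = None) -> LayerCurve | None:
    """Lens inner limit: first strong negative vertical intensity change
    below each outer-limit point.

    Columns without signal reuse the running median band width
    (provenance extrapolated). If fewer than ``min_signal_frac`` of the
    columns carry direct signal there is no distinct inner limit (the lens
    rests on the tissue) and None is returned.
    """
    px = as_pixels(img)
    h = px.shape[0]
    deriv = np.diff(px, axis=0)  # deriv[r] = I[r+1] - I[r]
    rows = np.empty(len(outer))
    direct = np.zeros(len(outer), dtype=bool)
    widths: list[float] = []
    for i, (c, r_out) in enumerate(zip(outer.cols, outer.rows)):
        depth = search_depth
        if depth_limit is not None:
            depth = min(depth, int(depth_limit[i]))
        lo = int(np.ceil(r_out)) + 1
        hi = min(h - 1, lo + depth)
        if hi <= lo:
            rows[i] = np.nan
            continue
        window = deriv[lo:hi, int(c)]
        j = int(np.argmin(window))
        # significance scaled by the local band brightness so the faint
        # lens wall is judged against its own level, not the cornea's
        local_peak = px[lo:min(lo + 4, h), int(c)].max()
        thr = -0.1 * max(local_peak, 1.0)
        if window[j] < thr:
            # sub-pixel edge: gradient minimum between rows lo+j and lo+j+1
            rows[i] = lo + j + 0.5
            direct[i] = True
            widths.append(rows[i] - r_out)
        else:
            rows[i] = np.nan
    if direct.mean() < min_signal_frac or len(widths) < 3:
        return None
    prov = np.where(direct, TRACED, EXTRAPOLATED).astype(np.int8)
    # fill no-signal columns with the running median band width
    med = float(np.median(widths))
    run: list[float] = []
    for i in range(len(rows)):
        if direct[i]:
            run.append(rows[i] - outer.rows[i])
            if len(run) > 15:
                run.pop(0)
        else:
            width = float(np.median(run)) if run else med
            rows[i] = outer.rows[i] + width
    # never above the outer limit
    rows = np.maximum(rows, outer.rows)
    return LayerCurve(outer.col_start, rows, prov)


def _distinctness(inner: LayerCurve, cornea: LayerCurve, tol: float) -> float:
    cols = shared_cols(inner, cornea)
    if cols.size == 0:
        return 0.0
    sep = np.abs(cornea.row_at(cols) - inner.row_at(cols))
    return float((sep > tol).mean())


def _band_below_score(px: np.ndarray, curve: LayerCurve, band_height: int = 12) -> float:
    """Mean intensity mass in the band directly below a curve."""
    h = px.shape[0]
    total = 0.0
    for c, r in zip(curve.cols, curve.rows):
        lo = int(np.ceil(r)) + 1
        total += px[lo:min(lo + band_height, h), int(c)].sum()
    return total / max(len(curve), 1)


def _same_boundary(a: LayerCurve, b: LayerCurve, tol: float = 3.0) -> bool:
    cols = shared_cols(a, b)
    if cols.size < max(10, 0.3 * min(len(a), len(b))):
        return False
    return float(np.median(np.abs(a.row_at(cols) - b.row_at(cols)))) < tol


def _boundary_below(emap: EdgeMap, px: np.ndarray, above: LayerCurve,
                    config: PipelineConfig, max_depth: int = 40) -> LayerCurve | None:
    """Trace the next boundary strictly below ``above`` (used when the
    searching-row areas of two close boundaries merge into one)."""
    h, w = px.shape
    centre = int(np.clip((above.col_start + above.col_end) // 2, 0, w - 1))
    # scan outward from the centre column for a seed edge below the curve
    for offset in range(0, (above.col_end - above.col_start) // 2 + 1):
        for c in {centre - offset, centre + offset}:
            if not (above.col_start <= c <= above.col_end):
                continue
            r_above = above.row_at(c)
            lo = int(np.ceil(r_above)) + 3
            hi = min(h, lo + max_depth)
            if hi <= lo:
                continue
            rr = np.flatnonzero(emap.edges[lo:hi, c])
            if rr.size and _neighbour_count(emap.edges, rr[0] + lo, c) >= 3:
                curve = trace_limit(emap, px, (int(rr[0] + lo), int(c)),
                                    config.loc_window_up, config.loc_window_down,
                                    config.max_extrapolation_cols)
                if len(curve) >= 0.3 * len(above) and not _same_boundary(curve, above):
                    return curve
    return None


def preliminary_localization(pre: PreprocessedImage | np.ndarray,
                             config: PipelineConfig | None = None) -> LayerSet:
    """Full preliminary stage on a preprocessed image.

    Traces one curve per accepted searching-row area (close boundaries whose
    areas merge are recovered by a restricted search below the first trace),
    labels the cornea by the intensity mass under each curve, then looks for
    the lens inner limit below the outer one. The image is classified
    three-layer when a distinct inner limit is found that does not merge
    with the cornea, two-layer otherwise.
    """
    config = config or PipelineConfig()
    px = pre.image.pixels if isinstance(pre, PreprocessedImage) else as_pixels(pre)
    emap = detect_edges(px, config.canny_low, config.canny_high, config.canny_kernel)
    profile = row_edge_profile(emap)
    min_support = config.min_row_support_frac * px.shape[1]
    rows = find_initial_rows(profile, config.initial_row_threshold,
                             config.max_initial_rows, min_support=min_support)
    if not rows:
        raise ValueError("no layers detected")

    curves: list[LayerCurve] = []
    for row in rows:
        start = _find_start_point(emap.edges, row)
        if start is None:
            continue
        curve = trace_limit(emap, px, start, config.loc_window_up,
                            config.loc_window_down, config.max_extrapolation_cols)
        if len(curve) < 0.2 * px.shape[1]:
            continue
        if any(_same_boundary(curve, c) for c in curves):
            continue
        curves.append(curve)
    if not curves:
        raise ValueError("no layers detected")
    curves.sort(key=lambda c: float(np.median(c.rows)))
    if len(curves) == 1:
        below = _boundary_below(emap, px, curves[0], config)
        if below is not None:
            curves.append(below)

    if len(curves) == 1:
        outer = cornea = curves[0]
    else:
        # cornea = curve with the most intensity mass just below it (the
        # tissue band is brighter and thicker than the lens walls)
        scores = [_band_below_score(px, c) for c in curves]
        cornea = curves[int(np.argmax(scores))]
        above = [c for c in curves if c is not cornea
                 and np.median(c.rows) < np.median(cornea.rows)]
        outer = above[0] if above else cornea

    inner = None
    if outer is not cornea:
        # bound the search by the cornea so the tissue's far edge can never
        # masquerade as the lens inner limit
        gap = cornea.row_at(outer.cols) - outer.rows - 3.0
        depth_limit = np.clip(gap, 0, None)
        inner = find_inner_limit(px, outer, config.inner_search_depth,
                                 config.inner_min_signal_frac,
                                 depth_limit=depth_limit)
    confidence = 0.0
    if inner is not None:
        confidence = _distinctness(inner, cornea, config.merge_tol_px)
        if 1.0 - confidence > config.merge_frac:
            inner = None  # merged with the cornea: effectively two layers
    if inner is not None:
        cols = shared_cols(inner, cornea)
        if cols.size:
            i0 = cols[0] - inner.col_start
            n = cols.size
            inner.rows[i0:i0 + n] = np.minimum(inner.rows[i0:i0 + n],
                                               cornea.row_at(cols))
        return LayerSet(scl_outer=outer, cornea=cornea, scl_inner=inner,
                        layer_count=3, region_class="three_layers",
                        confidence=confidence)
    return LayerSet(scl_outer=outer, cornea=cornea, scl_inner=None,
                    layer_count=2, region_class="two_layers",
                    confidence=confidence)
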