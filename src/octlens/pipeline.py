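"""End-to-end orchestration: preprocess, localize, refine, measure.

All results are reported in the original (unrotated) image frame: curves
found in the internally rotated frame are mapped back through the inverse
transform before export, so overlays and distances line up with the input
image.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .curves import GrayImage, LayerCurve, LayerSet
from .distances import DistanceProfile, profile
from .geometry import resample_to_columns, transform_curve_points
from .localize import preliminary_localization
from .preprocess import PreprocessedImage, preprocess
from .snake import SnakeConfig, evolve, image_potential
from .viz import render_heatmap


@dataclass
class SegmentationResult:
    """Curves in both frames plus the preprocessing record."""

    layers: LayerSet            # original-frame curves
    layers_processed: LayerSet  # curves in the preprocessed (rotated) frame
    pre: PreprocessedImage


def snake_config(config: PipelineConfig) -> SnakeConfig:
    return SnakeConfig(alpha=config.snake_alpha, beta=config.snake_beta,
                       edge_weight=config.snake_edge_weight,
                       max_iter=config.snake_max_iter,
                       move_radius=config.snake_move_radius,
                       conv_tol=config.snake_conv_tol,
                       potential_sigma=config.snake_potential_sigma)


def _map_back(curve: LayerCurve, pre: PreprocessedImage,
              orig_shape: tuple[int, int]) -> LayerCurve:
    """Inverse-rotate a curve into the original frame, one row per column."""
    if pre.applied_rotation_deg == 0:
        return LayerCurve(curve.col_start, curve.rows.copy(), curve.provenance.copy())
    x, y = transform_curve_points(curve.cols, curve.rows, pre.transform.inverse)
    keep = (x >= 0) & (x <= orig_shape[1] - 1)
    if keep.sum() < 2:
        raise ValueError("curve fell outside the original frame")
    c0, rows = resample_to_columns(x[keep], y[keep])
    return LayerCurve(c0, rows)


def segment_image(img, config: PipelineConfig | None = None,
                  refine: bool = True) -> SegmentationResult:
    """Full segmentation of one image (preprocess + localization + snake)."""
    config = config or PipelineConfig()
    gray = img if isinstance(img, GrayImage) else GrayImage(np.asarray(img))
    pre = preprocess(gray, config)
    layers = preliminary_localization(pre, config)
    if refine:
        cfg = snake_config(config)
        potential = image_potential(pre.image.pixels, cfg.potential_sigma)
        refined = {}
        for name in ("scl_outer", "scl_inner", "cornea"):
            curve = getattr(layers, name)
            if curve is None or len(curve) < 5:
                refined[name] = curve
                continue
            refined[name], _ = evolve(curve, pre.image.pixels, cfg,
                                      potential=potential)
        layers = LayerSet(scl_outer=refined["scl_outer"], cornea=refined["cornea"],
                          scl_inner=refined["scl_inner"],
                          layer_count=layers.layer_count,
                          region_class=layers.region_class,
                          confidence=layers.confidence)
    mapped = {name: (None if getattr(layers, name) is None
                     else _map_back(getattr(layers, name), pre, gray.shape))
              for name in ("scl_outer", "scl_inner", "cornea")}
    original = LayerSet(scl_outer=mapped["scl_outer"], cornea=mapped["cornea"],
                        scl_inner=mapped["scl_inner"],
                        layer_count=layers.layer_count,
                        region_class=layers.region_class,
                        confidence=layers.confidence)
    return SegmentationResult(layers=original, layers_processed=layers, pre=pre)


def measure(layers: LayerSet, config: PipelineConfig | None = None) -> DistanceProfile:
    """Clearance profile of a segmented image."""
    config = config or PipelineConfig()
    return profile(layers, tangent_window=config.tangent_window,
                   coarse_step=config.nearest_coarse_step,
                   window_cols=config.nearest_window_cols,
                   pixel_size_um=config.pixel_size_um)


@dataclass
class RunManifest:
    """Provenance record of one pipeline invocation."""

    input_path: str
    config_sha256: str
    outputs: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    region_class: str = ""
    version: str = __version__

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def run_pipeline(image_path, config_path=None, out_dir=".",
                 paradigm: str = "nearest") -> RunManifest:
    """File-level entry point: segment, measure, render, export.

    Writes curve CSV + JSON, distance-profile CSV, heatmap PNG and a
    manifest JSON into ``out_dir``.
    """
    from . import io as oio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig.load(config_path) if config_path else PipelineConfig()
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(input_path=str(image_path), config_sha256=cfg_hash)

    try:
        img = oio.load_image(image_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed for {image_path}: {exc}") from exc
    t0 = time.perf_counter()
    try:
        result = segment_image(img, config)
    except Exception as exc:
        raise RuntimeError(f"stage 'segment' failed: {exc}") from exc
    manifest.stage_seconds["segment"] = round(time.perf_counter() - t0, 4)
    manifest.region_class = result.layers.region_class

    t0 = time.perf_counter()
    try:
        prof = measure(result.layers, config)
    except Exception as exc:
        raise RuntimeError(f"stage 'measure' failed: {exc}") from exc
    manifest.stage_seconds["measure"] = round(time.perf_counter() - t0, 4)

    stem = Path(image_path).stem
    curves_csv = out / f"{stem}_curves.csv"
    curves_json = out / f"{stem}_curves.json"
    prof_csv = out / f"{stem}_distances.csv"
    heat_png = out / f"{stem}_heatmap.png"
    oio.save_curves_csv(curves_csv, result.layers)
    oio.save_curves_json(curves_json, result.layers)
    oio.save_profile_csv(prof_csv, prof)
    render = render_heatmap(img, result.layers, prof, paradigm)
    oio.save_image(heat_png, render.rgb)
    manifest.outputs = {"curves_csv": str(curves_csv), "curves_json": str(curves_json),
                        "distances_csv": str(prof_csv), "heatmap_png": str(heat_png)}
    manifest_path = out / f"{stem}_manifest.json"
    manifest.save(manifest_path)
    manifest.outputs["manifest_json"] = str(manifest_path)
    return manifest
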