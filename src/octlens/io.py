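"""File formats: 8-bit grayscale PNG/TIFF images, curve CSV/JSON exports,
distance-profile CSV, phantom ground-truth JSON."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .curves import PROVENANCE_NAMES, GrayImage, LayerCurve, LayerSet
from .phantom import GroundTruth

_PROV_CODES = {v: k for k, v in PROVENANCE_NAMES.items()}


def load_image(path, pixel_size_um: float | None = None) -> GrayImage:
    """Read a PNG/TIFF as 8-bit grayscale (colour inputs are averaged)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return GrayImage(np.asarray(arr, dtype=float), pixel_size_um)


def save_image(path, img) -> None:
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def _curve_records(name: str, curve: LayerCurve) -> list[dict]:
    return [{"layer": name, "col": int(c), "row": float(r),
             "provenance": PROVENANCE_NAMES[int(p)]}
            for c, r, p in zip(curve.cols, curve.rows, curve.provenance)]


def save_curves_csv(path, layers: LayerSet) -> None:
    rows: list[dict] = []
    for name in ("scl_outer", "scl_inner", "cornea"):
        curve = getattr(layers, name)
        if curve is not None:
            rows.extend(_curve_records(name, curve))
    pd.DataFrame(rows).to_csv(path, index=False)


def load_curves_csv(path) -> dict[str, LayerCurve]:
    df = pd.read_csv(path)
    out = {}
    for name, grp in df.groupby("layer"):
        grp = grp.sort_values("col")
        prov = np.array([_PROV_CODES[p] for p in grp["provenance"]], dtype=np.int8)
        out[str(name)] = LayerCurve(int(grp["col"].iloc[0]),
                                    grp["row"].to_numpy(), prov)
    return out


def save_curves_json(path, layers: LayerSet) -> None:
    doc = {"region_class": layers.region_class,
           "layer_count": layers.layer_count,
           "confidence": layers.confidence,
           "curves": {}}
    for name in ("scl_outer", "scl_inner", "cornea"):
        curve = getattr(layers, name)
        if curve is not None:
            doc["curves"][name] = {
                "col_start": int(curve.col_start),
                "rows": [float(r) for r in curve.rows],
                "provenance": [PROVENANCE_NAMES[int(p)] for p in curve.provenance],
            }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_curves_json(path) -> LayerSet:
    with open(path) as fh:
        doc = json.load(fh)
    curves = {}
    for name, c in doc["curves"].items():
        prov = np.array([_PROV_CODES[p] for p in c["provenance"]], dtype=np.int8)
        curves[name] = LayerCurve(c["col_start"], np.asarray(c["rows"]), prov)
    return LayerSet(scl_outer=curves["scl_outer"], cornea=curves["cornea"],
                    scl_inner=curves.get("scl_inner"),
                    layer_count=doc["layer_count"],
                    region_class=doc["region_class"],
                    confidence=doc.get("confidence", 0.0))


def save_profile_csv(path, prof) -> None:
    pd.DataFrame({"col": prof.cols, "vertical": prof.vertical,
                  "normal": prof.normal, "nearest": prof.nearest}).to_csv(
        path, index=False)


def load_profile_csv(path):
    from .distances import DistanceProfile
    df = pd.read_csv(path)
    return DistanceProfile(df["col"].to_numpy(), df["vertical"].to_numpy(),
                           df["normal"].to_numpy(), df["nearest"].to_numpy())


def save_ground_truth_json(path, gt: GroundTruth) -> None:
    doc = {"scenario": gt.scenario, "rotation_deg": gt.rotation_deg,
           "layer_count": gt.layer_count,
           "curves": {name: {"col_start": int(c.col_start),
                             "rows": [float(r) for r in c.rows]}
                      for name, c in gt.curves.items()}}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_ground_truth_json(path) -> GroundTruth:
    with open(path) as fh:
        doc = json.load(fh)
    curves = {name: LayerCurve(c["col_start"], np.asarray(c["rows"]))
              for name, c in doc["curves"].items()}
    return GroundTruth(curves=curves, layer_count=doc["layer_count"],
                       rotation_deg=doc["rotation_deg"], scenario=doc["scenario"])


def save_phantom(out_dir, index: int, img: GrayImage, gt: GroundTruth) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"phantom_{index:03d}_{gt.scenario}.png"
    gt_path = out / f"phantom_{index:03d}_{gt.scenario}_truth.json"
    save_image(img_path, img)
    save_ground_truth_json(gt_path, gt)
    return img_path, gt_path
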