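"""Synthetic AS-OCT phantom images with exact ground-truth layer curves.

A phantom emulates the geometry a B-scan of a scleral-lens wearer shows:
a thin bright band for the lens body (its top edge is the SCL outer limit,
its bottom edge the SCL inner limit) above a thicker, brighter band for the
corneal/scleral tissue, on a dark background. Three scenarios mirror the
regions of the anterior segment:

* ``central``  — the lens vaults the cornea everywhere (three boundaries),
* ``lateral``  — the gap closes linearly toward one side,
* ``extreme``  — the lens rests directly on the tissue (two boundaries).

Speckle is multiplicative mean-one log-normal noise, contrast decays
laterally, and the whole frame can be rotated (ground truth is transformed
analytically, never rasterised).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .curves import GrayImage, LayerCurve
from .geometry import resample_to_columns, rotation_transform, transform_curve_points

SCENARIOS = ("central", "lateral", "extreme")

#: edge softness of the rendered bands (px); gives Canny-realistic gradient
#: width while keeping the maximum vertical gradient on the stated boundary
EDGE_SIGMA = 1.2


@dataclass
class PhantomSpec:
    """Parameters of one synthetic image.

    Band geometry is parabolic in the unrotated frame:
    ``row(c) = apex_row + curvature * (c - width/2)**2``; the cornea is
    derived from the lens inner limit plus the scenario's gap profile.
    Units are pixels and 8-bit gray levels throughout.
    """

    width: int = 400
    height: int = 300
    scenario: str = "central"
    lens_apex_row: float = 90.0
    lens_curvature: float = 3.0e-4
    cornea_curvature: float = 6.0e-4
    lens_thickness: float = 8.0
    cornea_thickness: float = 11.0
    vault: float = 40.0
    rotation_deg: float = 0.0
    speckle_sigma: float = 0.2
    contrast_decay: float = 0.08  # fractional loss per 100 columns off-centre
    band_intensities: dict = field(default_factory=lambda: {
        "lens": 140.0, "cornea": 235.0, "background": 8.0})
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.width < 32 or self.height < 32:
            raise ValueError("phantom must be at least 32x32")
        if self.vault < 0:
            raise ValueError("vault must be >= 0")
        if self.scenario in ("central", "lateral") and self.vault == 0:
            raise ValueError(f"{self.scenario} scenario requires vault > 0")
        if not (0.0 <= self.rotation_deg <= 45.0):
            raise ValueError("rotation_deg must be within [0, 45]")
        if self.speckle_sigma < 0 or self.contrast_decay < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.lens_thickness <= 2 or self.cornea_thickness <= 2:
            raise ValueError("bands must be thicker than 2 px")


@dataclass
class GroundTruth:
    """Analytic boundary curves of a phantom, in the emitted image's frame."""

    curves: dict[str, LayerCurve]
    layer_count: int
    rotation_deg: float
    scenario: str

    def __post_init__(self) -> None:
        expected = 3 if self.layer_count == 3 else 2
        if len(self.curves) != expected:
            raise ValueError("curve count inconsistent with layer_count")


def _analytic_curves(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boundary rows per band in the unrotated frame, one per column."""
    c = np.arange(spec.width, dtype=float)
    d2 = (c - (spec.width - 1) / 2.0) ** 2
    outer = spec.lens_apex_row + spec.lens_curvature * d2
    inner = outer + spec.lens_thickness
    if spec.scenario == "central":
        gap_extra = (spec.cornea_curvature - spec.lens_curvature) * d2
        cornea = inner + spec.vault + np.maximum(gap_extra, 0.0)
    elif spec.scenario == "lateral":
        # gap ramps from 0 at the left edge up to the vault at the right edge
        gap = spec.vault * c / (spec.width - 1)
        cornea = inner + gap
    else:  # extreme: lens rests on the tissue, inner limit == tissue surface
        cornea = inner
    return {"scl_outer": outer, "scl_inner": inner, "cornea": cornea}


def _render_noiseless(spec: PhantomSpec) -> np.ndarray:
    """Render bands with error-function edges; half-maximum sits exactly on
    the analytic boundary and the vertical gradient peaks there."""
    curves = _analytic_curves(spec)
    rows = np.arange(spec.height, dtype=float)[:, None]
    bg = spec.band_intensities["background"]

    def band(top: np.ndarray, bottom: np.ndarray, level: float) -> np.ndarray:
        return (level - bg) * (ndtr((rows - top[None, :]) / EDGE_SIGMA)
                               - ndtr((rows - bottom[None, :]) / EDGE_SIGMA))

    img = np.full((spec.height, spec.width), bg, dtype=np.float64)
    img += band(curves["scl_outer"], curves["scl_inner"],
                spec.band_intensities["lens"])
    img += band(curves["cornea"], curves["cornea"] + spec.cornea_thickness,
                spec.band_intensities["cornea"])
    if spec.contrast_decay > 0:
        c = np.arange(spec.width, dtype=float)
        scale = 1.0 - spec.contrast_decay * np.abs(c - (spec.width - 1) / 2.0) / 100.0
        img *= np.clip(scale, 0.2, 1.0)[None, :]
    return img


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, GroundTruth]:
    """Render one phantom and its exact ground truth.

    The image is 8-bit quantised; identical specs (same seed) produce
    bit-identical pixels. Ground-truth curves are expressed in the rotated
    output frame, restricted to columns where each boundary is defined.
    """
    spec.validate()
    img = _render_noiseless(spec)
    curves = _analytic_curves(spec)
    cols = np.arange(spec.width, dtype=float)

    if spec.rotation_deg != 0:
        tform, out_shape = rotation_transform(img.shape, spec.rotation_deg)
        from skimage.transform import warp
        img = warp(img, inverse_map=tform.inverse, output_shape=out_shape,
                   order=1, cval=0.0, preserve_range=True)
        gt_curves = {}
        for name, r in curves.items():
            x, y = transform_curve_points(cols, r, tform)
            c0, rows = resample_to_columns(x, y)
            gt_curves[name] = LayerCurve(c0, rows)
    else:
        gt_curves = {name: LayerCurve(0, r.copy()) for name, r in curves.items()}

    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        # mean-one log-normal: multiplicative speckle that preserves the
        # expected intensity of the noiseless render
        noise = np.exp(rng.normal(-0.5 * spec.speckle_sigma ** 2,
                                  spec.speckle_sigma, img.shape))
        img = img * noise

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    if spec.scenario == "extreme":
        gt_curves = {"scl_outer": gt_curves["scl_outer"], "cornea": gt_curves["cornea"]}
        layer_count = 2
    else:
        layer_count = 3
    gt = GroundTruth(curves=gt_curves, layer_count=layer_count,
                     rotation_deg=spec.rotation_deg, scenario=spec.scenario)
    return GrayImage(img), gt


def _scenario_counts(n: int, mix) -> list[int]:
    """Largest-remainder apportionment of n items over the scenario mix."""
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("scenario mix must be three proportions summing to 1")
    raw = n * mix
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts)):
        if counts.sum() >= n:
            break
        counts[i] += 1
    return counts.tolist()


def random_spec(scenario: str, seed: int, rng: np.random.Generator,
                speckle_sigma: float = 0.2, contrast_decay: float = 0.08) -> PhantomSpec:
    """Draw realistic per-image geometry for the given scenario."""
    rotation = {"central": (0.0, 4.0), "lateral": (8.0, 25.0),
                "extreme": (15.0, 40.0)}[scenario]
    return PhantomSpec(
        scenario=scenario,
        lens_apex_row=float(rng.uniform(70, 110)),
        lens_curvature=float(rng.uniform(2.0e-4, 4.0e-4)),
        cornea_curvature=float(rng.uniform(5.0e-4, 8.0e-4)),
        lens_thickness=float(rng.uniform(6.5, 9)),
        cornea_thickness=float(rng.uniform(9.5, 11.5)),
        vault=float(rng.uniform(25, 55)),
        rotation_deg=float(np.round(rng.uniform(*rotation), 2)),
        speckle_sigma=speckle_sigma,
        contrast_decay=contrast_decay,
        seed=seed,
    )


def generate_dataset(n: int, scenario_mix=(1 / 3, 1 / 3, 1 / 3),
                     base_seed: int = 0, speckle_sigma: float = 0.2,
                     contrast_decay: float = 0.08) -> list[tuple[GrayImage, GroundTruth]]:
    """Reproducible batch of phantoms with the requested scenario mix."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = _scenario_counts(n, scenario_mix)
    item_seeds = (np.random.SeedSequence(base_seed).generate_state(n)
                  % np.uint32(2 ** 31)).astype(int)
    out = []
    i = 0
    for scenario, k in zip(SCENARIOS, counts):
        for _ in range(k):
            seed = int(item_seeds[i])
            rng = np.random.default_rng(seed)
            spec = random_spec(scenario, seed, rng,
                               speckle_sigma=speckle_sigma,
                               contrast_decay=contrast_decay)
            out.append(generate_phantom(spec))
            i += 1
    return out
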