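"""Denoising, re-orientation and contrast enhancement.

The stage order is median smoothing, speckle-aware anisotropic diffusion, a
global gradient-orientation estimate used to rotate the layers to the
horizontal, and white top-hat enhancement. The diffusion step is
Perona-Malik with the exponential edge-stopping function: it flattens
speckle in near-uniform regions while leaving the layer edges (large
gradients) essentially untouched, which is what the later edge analysis
needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import footprint_rectangle, white_tophat
from skimage.transform import AffineTransform

from .config import PipelineConfig
from .curves import GrayImage, as_pixels
from .geometry import rotate_expand


@dataclass
class PreprocessedImage:
    """Result of the preprocessing stage.

    ``applied_rotation_deg`` is the rotation applied to horizontalise the
    layers; ``transform`` maps (col, row) points of the input frame into the
    output frame (its inverse takes results back to the original image).
    """

    image: GrayImage
    applied_rotation_deg: float
    transform: AffineTransform
    config_echo: PipelineConfig


def median_smooth(img, k: int = 7) -> np.ndarray:
    """k x k median filter (impulse-noise rejection before diffusion)."""
    if k % 2 == 0:
        raise ValueError("median kernel must be odd")
    px = as_pixels(img)
    if k == 1:
        return px.copy()
    return ndimage.median_filter(px, size=k, mode="nearest")


def anisotropic_diffuse(img, n_iter: int = 15, kappa: float = 30.0,
                        dt: float = 0.2) -> np.ndarray:
    """Perona-Malik diffusion, explicit non-negative 4-neighbour scheme.

    Conduction g(|dI|) = exp(-(|dI|/kappa)^2) per face; Neumann (replicated)
    boundaries make the update conservative, so the global mean is preserved
    to floating-point accuracy. Stability requires dt <= 1/4 in 2-D.
    """
    px = as_pixels(img)
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite pixels")
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if not (0 < dt <= 0.25):
        raise ValueError("dt must be in (0, 0.25] for the explicit scheme")
    u = px.copy()
    for _ in range(n_iter):
        dn = np.diff(u, axis=0, prepend=u[:1])        # I[r] - I[r-1]
        ds = np.diff(u, axis=0, append=u[-1:])        # I[r+1] - I[r]
        dw = np.diff(u, axis=1, prepend=u[:, :1])
        de = np.diff(u, axis=1, append=u[:, -1:])
        flux = (np.exp(-(ds / kappa) ** 2) * ds - np.exp(-(dn / kappa) ** 2) * dn
                + np.exp(-(de / kappa) ** 2) * de - np.exp(-(dw / kappa) ** 2) * dw)
        u += dt * flux
    return u


def estimate_dominant_orientation(img, n_bins: int = 36) -> float:
    """Dominant edge direction from a magnitude-weighted orientation
    histogram (global HOG), in degrees within (-90, 90].

    Rotating the image by the negated estimate brings the majority of edges
    to the horizontal. The circular mode over the 180-degree-periodic
    histogram is refined to sub-bin precision with a parabolic fit.
    """
    px = as_pixels(img)
    gy = ndimage.sobel(px, axis=0)
    gx = ndimage.sobel(px, axis=1)
    mag = np.hypot(gx, gy)
    if not np.any(mag > 0):
        raise ValueError("no orientation signal: zero-gradient image")
    # edge direction is perpendicular to the gradient; for a horizontal edge
    # (vertical gradient) this angle is 0
    theta = np.degrees(np.arctan2(gy, gx)) - 90.0
    theta = (theta + 90.0) % 180.0 - 90.0  # wrap to [-90, 90)
    bin_w = 180.0 / n_bins
    # bins centred on multiples of the bin width so 0 degrees is a centre
    idx = np.floor((theta + 90.0 + bin_w / 2) / bin_w).astype(int) % n_bins
    hist = np.bincount(idx.ravel(), weights=mag.ravel(), minlength=n_bins)
    k = int(np.argmax(hist))
    # parabolic sub-bin refinement on the circular neighbourhood
    y0, y1, y2 = hist[(k - 1) % n_bins], hist[k], hist[(k + 1) % n_bins]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    angle = -90.0 + (k + delta) * bin_w
    angle = (angle + 90.0) % 180.0 - 90.0
    if angle <= -90.0:
        angle += 180.0
    return float(angle)


def rotate_to_horizontal(img, angle: float) -> tuple[np.ndarray, AffineTransform]:
    """Rotate by ``angle`` degrees about the centre with bilinear resampling,
    expanding the canvas to hold the whole frame (fill 0).

    Returns the rotated raster and the forward (input -> output) point
    transform. Pass the negated orientation estimate to horizontalise.
    """
    if abs(angle) > 90:
        raise ValueError("|angle| must be <= 90 degrees")
    return rotate_expand(as_pixels(img), angle)


def tophat_enhance(img, kernel_px: int = 21) -> np.ndarray:
    """White top-hat with a square structuring element: keeps bands narrower
    than the kernel, suppresses wide plateaus and slowly varying background."""
    if kernel_px % 2 == 0 or kernel_px < 3:
        raise ValueError("top-hat kernel must be odd and >= 3")
    px = as_pixels(img)
    if kernel_px > min(px.shape):
        raise ValueError("top-hat kernel larger than image")
    return white_tophat(px, footprint_rectangle((kernel_px, kernel_px)))


def preprocess(img, config: PipelineConfig | None = None) -> PreprocessedImage:
    """Full preprocessing chain; rotation is only applied when the estimated
    tilt exceeds the dead-band (central images pass through unrotated)."""
    config = config or PipelineConfig()
    gray = img if isinstance(img, GrayImage) else GrayImage(np.asarray(img))
    u = median_smooth(gray.pixels, config.median_k)
    u = anisotropic_diffuse(u, config.diffusion_n_iter, config.diffusion_kappa,
                            config.diffusion_dt)
    try:
        angle = estimate_dominant_orientation(u, config.hog_bins)
    except ValueError:
        angle = 0.0
    if abs(angle) > config.rotation_deadband_deg:
        u, tform = rotate_to_horizontal(u, -angle)
        applied = -angle
    else:
        tform = AffineTransform()
        applied = 0.0
    u = tophat_enhance(u, config.tophat_kernel)
    return PreprocessedImage(image=GrayImage(u, gray.pixel_size_um),
                             applied_rotation_deg=float(applied),
                             transform=tform, config_echo=config)
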