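"""Pipeline configuration: the ten evolution-tunable parameters plus the
fixed numerical settings of each stage.

The tunables (median kernel, tracing windows, snake weights, Canny limits and
kernels, top-hat kernel) are the parameters the differential-evolution stage
searches over; shipped defaults are the optimised operating point used
throughout the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

#: names of the DE-tunable parameters, in vector order
TUNABLE_NAMES = (
    "median_k",
    "loc_window_up",
    "loc_window_down",
    "snake_alpha",
    "snake_beta",
    "snake_edge_weight",
    "canny_high",
    "canny_low",
    "canny_kernel",
    "tophat_kernel",
)


def _odd_grid(lo: int, hi: int) -> np.ndarray:
    return np.arange(lo, hi + 1, 2, dtype=float)


#: discretised search grid per tunable (kernel sizes odd, windows integer,
#: snake weights and Canny limits on coarse grids bracketing the defaults)
TUNABLE_GRIDS: dict[str, np.ndarray] = {
    "median_k": _odd_grid(3, 31),
    "loc_window_up": np.arange(3, 16, dtype=float),
    "loc_window_down": np.arange(3, 16, dtype=float),
    "snake_alpha": np.arange(1, 101, dtype=float),
    "snake_beta": np.arange(1, 101, dtype=float),
    "snake_edge_weight": np.round(np.arange(0.1, 5.05, 0.1), 10),
    "canny_high": np.arange(10, 251, 10, dtype=float),
    "canny_low": np.arange(10, 251, 10, dtype=float),
    "canny_kernel": _odd_grid(3, 31),
    "tophat_kernel": _odd_grid(3, 31),
}

_INT_TUNABLES = {
    "median_k", "loc_window_up", "loc_window_down",
    "canny_high", "canny_low", "canny_kernel", "tophat_kernel",
    "snake_alpha", "snake_beta",
}


@dataclass
class PipelineConfig:
    # --- evolution-tunable parameters ---
    median_k: int = 7
    loc_window_up: int = 7
    loc_window_down: int = 7
    snake_alpha: float = 50.0
    snake_beta: float = 20.0
    snake_edge_weight: float = 1.0
    canny_high: float = 120.0
    canny_low: float = 90.0
    canny_kernel: int = 3
    tophat_kernel: int = 21

    # --- fixed numerical settings ---
    diffusion_n_iter: int = 15
    diffusion_kappa: float = 12.0
    diffusion_dt: float = 0.2
    rotation_deadband_deg: float = 5.0
    hog_bins: int = 36
    initial_row_threshold: float | None = None  # None -> adaptive (mean + 2 SD)
    min_row_support_frac: float = 0.2
    max_initial_rows: int = 3
    max_extrapolation_cols: int = 30
    inner_search_depth: int = 25
    inner_min_signal_frac: float = 0.1
    merge_tol_px: float = 2.0
    merge_frac: float = 0.8
    snake_max_iter: int = 400
    snake_move_radius: int = 2
    snake_conv_tol: float = 0.01
    snake_potential_sigma: float = 2.0
    tangent_window: int = 10
    nearest_coarse_step: int = 10
    nearest_window_cols: int = 50
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        for k in ("median_k", "canny_kernel", "tophat_kernel"):
            if getattr(self, k) % 2 == 0 or getattr(self, k) < 3:
                raise ValueError(f"{k} must be odd and >= 3")
        if self.canny_low > self.canny_high:
            raise ValueError("canny_low must not exceed canny_high")
        if self.loc_window_up < 1 or self.loc_window_down < 1:
            raise ValueError("tracing windows must be >= 1")

    # --- DE vector interface ---
    def to_vector(self) -> np.ndarray:
        return np.array([float(getattr(self, n)) for n in TUNABLE_NAMES])

    @classmethod
    def from_vector(cls, vec, repair: bool = True, **fixed) -> "PipelineConfig":
        """Build a config from a 10-vector on the tunable grids.

        With ``repair`` the Canny ordering constraint is enforced by swapping
        (useful inside the optimiser, where raw donors may violate it).
        """
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(TUNABLE_NAMES),):
            raise ValueError(f"expected a {len(TUNABLE_NAMES)}-vector")
        kv: dict = {}
        for name, value in zip(TUNABLE_NAMES, vec):
            grid = TUNABLE_GRIDS[name]
            snapped = grid[np.argmin(np.abs(grid - value))]
            kv[name] = int(snapped) if name in _INT_TUNABLES else float(snapped)
        if repair and kv["canny_low"] > kv["canny_high"]:
            kv["canny_low"], kv["canny_high"] = kv["canny_high"], kv["canny_low"]
        kv.update(fixed)
        return cls(**kv)

    # --- (de)serialisation ---
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_grids() -> list[np.ndarray]:
    """Search grids in tunable-vector order, for the optimiser."""
    return [TUNABLE_GRIDS[n] for n in TUNABLE_NAMES]
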