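"""Analysis configuration shared by all pipeline stages.

Every threshold that enters the classification is held here and is printed
into the run manifest, because several of the original cut-offs (the α and
φ thresholds for the directed state, the mode boundaries) are method
parameters rather than universal constants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class AnalysisConfig:
    """Parameters of the local-MSD / persistence classification pipeline.

    Defaults correspond to 10 Hz imaging with 267 nm pixels: a 20-frame
    sliding window, MSD fitted over the first 10 lags, the diffusion
    constant over the first 5 lags, and directed segments required to last
    at least 5 frames while displacing more than one pixel per 0.5 s.
    """

    dt: float = 0.1                    # s / frame
    pixel_size: float = 0.267          # µm
    window_frames: int = 20            # local MSD / persistence window
    n_max: int = 10                    # MSD lags used in the power-law fit
    d_fit_points: int = 5              # MSD lags used in the linear D fit
    alpha_dir: float = 1.4             # directed state: alpha threshold
    phi_min: float = 0.7               # directed state: persistence threshold
    alpha_constrained: float = 0.4     # mode boundary: constrained / sub
    alpha_super: float = 1.0           # mode boundary: sub / super
    min_directed_frames: int = 5       # minimum run length (points)
    min_displacement_um: float = 0.267 # required displacement per displacement_window_s
    displacement_window_s: float = 0.5
    velocity_halfwidth: int = 2        # frames each side for smoothed velocity
    persistence_halfwidth: int = 2     # frames each side for smoothed turning angles (0 = raw steps)
    bin_5min: float = 300.0            # s, velocity statistics bin
    bin_15min: float = 900.0           # s, mode-proportion bin
    smooth_points: int = 20            # moving-average window for time series
    min_traj_frames: int = 50          # selection filter (strictly greater)
    endocytic_ratio_mode: str = "mean_of_ratios"  # or "ratio_of_means"
    loc_noise_var: float = 0.0         # known static localization variance σ² (µm²)

    def __post_init__(self) -> None:
        if not (0 < self.alpha_constrained < self.alpha_super):
            raise ValueError("need 0 < alpha_constrained < alpha_super")
        if self.n_max >= self.window_frames:
            raise ValueError("n_max must be smaller than window_frames")
        if self.d_fit_points > self.n_max:
            raise ValueError("d_fit_points cannot exceed n_max")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.endocytic_ratio_mode not in ("mean_of_ratios", "ratio_of_means"):
            raise ValueError("unknown endocytic_ratio_mode")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the full parameter set, embedded in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
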