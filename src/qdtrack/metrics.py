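"""Single-cell trafficking metrics: endocytic ratio and puncta intensity.

The *endocytic ratio* quantifies how far internalized cargo has progressed
from the plasma membrane toward the cell centre.  For each visible punctum
at distance ``a`` from the centre, ``b`` is the distance from the centre to
the cell boundary along the same ray; the per-frame ratio is the mean of
``b / a`` over puncta.  It equals 1 when everything sits on the boundary
and grows as cargo approaches the centre.  (The alternative reading —
mean boundary radius divided by mean cargo distance — is available via
``AnalysisConfig.endocytic_ratio_mode = "ratio_of_means"``.)

The *intensity series* tracks vesicle fusion: per frame, the mean
intensity of all visible puncta, normalized to its value in the first
frame.  Fusion conserves total intensity while reducing the punctum count,
so the normalized mean rises as vesicles merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .config import AnalysisConfig
from .io import CellGeometry, CellRecording
from .synthetic import _geom_coords  # shared shapely coordinate extraction


@dataclass
class EndocyticRatioSeries:
    frames: np.ndarray
    R: np.ndarray          # nan where a frame had no usable points
    n_points: np.ndarray
    R_smooth: np.ndarray   # centred moving average, truncated at the ends

    def to_frame(self, dt: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "t_s": self.frames * dt,
                "R_raw": self.R,
                "R_smooth": self.R_smooth,
                "n_points": self.n_points,
            }
        )


@dataclass
class IntensitySeries:
    frames: np.ndarray
    mean_intensity: np.ndarray  # nan where the frame had no puncta
    normalized: np.ndarray      # mean / first-frame mean

    def to_frame(self, dt: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "t_s": self.frames * dt,
                "mean_intensity": self.mean_intensity,
                "normalized": self.normalized,
            }
        )


def boundary_distance_along_ray(geom: CellGeometry, point: np.ndarray) -> float:
    """Distance centre→boundary along the ray through ``point``.

    The first crossing of the ray with the boundary polygon (the nearest
    intersection at positive ray parameter).
    """
    c = geom.center
    p = np.asarray(point, dtype=float)
    u = p - c
    norm = np.hypot(*u)
    if norm < 1e-12:
        raise ValueError("point coincides with the centre; ray undefined")
    u = u / norm
    xs, ys = geom.boundary[:, 0], geom.boundary[:, 1]
    span = 4.0 * max(np.max(np.abs(xs - c[0])), np.max(np.abs(ys - c[1])), norm)
    ray = LineString([tuple(c), tuple(c + span * u)])
    inter = geom.polygon.exterior.intersection(ray)
    dists = [float(np.hypot(cx - c[0], cy - c[1])) for cx, cy in _geom_coords(inter)]
    dists = [d for d in dists if d > 1e-12]
    if not dists:
        raise RuntimeError("ray from centre failed to intersect the boundary")
    return min(dists)


def endocytic_ratio_frame(
    points: np.ndarray, geom: CellGeometry, mode: str = "mean_of_ratios"
) -> float:
    """Endocytic ratio of one frame from all visible punctum positions.

    ``points`` is an (m, 2) array in µm.  Points exactly at the centre are
    excluded (the ratio is undefined there).  Returns nan when no usable
    point remains.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return np.nan
    a = np.hypot(pts[:, 0] - geom.center[0], pts[:, 1] - geom.center[1])
    usable = a > 1e-12
    if not usable.any():
        return np.nan
    b = np.array([boundary_distance_along_ray(geom, p) for p in pts[usable]])
    if mode == "mean_of_ratios":
        return float(np.mean(b / a[usable]))
    elif mode == "ratio_of_means":
        return float(np.mean(b) / np.mean(a[usable]))
    raise ValueError(f"unknown endocytic ratio mode {mode!r}")


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred nan-aware moving average with truncated edge windows."""
    n = len(values)
    out = np.full(n, np.nan)
    half = window // 2
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(int))])
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half)
        cnt = ccnt[hi] - ccnt[lo]
        if cnt > 0:
            out[i] = (csum[hi] - csum[lo]) / cnt
    return out


def endocytic_ratio_series(
    recording: CellRecording, cfg: AnalysisConfig | None = None
) -> EndocyticRatioSeries:
    """Per-frame endocytic ratio over all trajectory points of a cell.

    Frames with no visible point are carried as nan gaps; the smoothed
    trace is the centred moving average over ``smooth_points`` frames,
    skipping gaps and truncating at the series ends.
    """
    cfg = cfg or AnalysisConfig()
    if recording.geometry is None:
        raise ValueError("recording has no cell geometry")
    n_frames = recording.n_frames
    per_frame: list[list[np.ndarray]] = [[] for _ in range(n_frames)]
    for tr in recording.trajectories:
        for f, x, y in zip(tr.frames, tr.x, tr.y):
            if 0 <= f < n_frames:
                per_frame[int(f)].append(np.array([x, y]))
    R = np.full(n_frames, np.nan)
    n_pts = np.zeros(n_frames, dtype=int)
    for f in range(n_frames):
        if per_frame[f]:
            pts = np.vstack(per_frame[f])
            R[f] = endocytic_ratio_frame(pts, recording.geometry, cfg.endocytic_ratio_mode)
            n_pts[f] = len(pts)
    R_smooth = moving_average(R, cfg.smooth_points)
    R_smooth[~np.isfinite(R)] = np.nan  # gaps stay gaps
    return EndocyticRatioSeries(
        frames=np.arange(n_frames), R=R, n_points=n_pts, R_smooth=R_smooth
    )


def normalized_intensity_series(puncta: list[np.ndarray]) -> IntensitySeries:
    """Mean punctum intensity per frame, normalized to the first frame.

    ``puncta[f]`` holds the intensities of all visible puncta in frame
    ``f``.  Frames without puncta become nan gaps.  The first frame must
    contain at least one punctum with a positive mean.
    """
    n = len(puncta)
    mean = np.full(n, np.nan)
    for f, vals in enumerate(puncta):
        vals = np.asarray(vals, dtype=float)
        if vals.size:
            mean[f] = float(np.mean(vals))
    if not np.isfinite(mean[0]) or mean[0] <= 0:
        raise ValueError("first frame needs at least one punctum with positive mean intensity")
    return IntensitySeries(frames=np.arange(n), mean_intensity=mean, normalized=mean / mean[0])
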