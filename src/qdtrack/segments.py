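"""Directed-segment extraction, motion-mode labels and binned statistics.

A *directed segment* is a maximal run of consecutive directed-state points
that (a) lasts at least ``min_directed_frames`` points and (b) displaces
more than one pixel (267 nm) in every rolling 0.5-s sub-window.  Segment
velocities are smoothed instantaneous speeds: per component, a central
difference over ±``velocity_halfwidth`` frames, which suppresses the
frame-to-frame localization error.

Population statistics follow a two-step average: first the mean over all
samples within one cell (and one time bin), then the unweighted mean ±
standard error across cells — so every cell counts equally regardless of
how many vesicles it contributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import Trajectory
from .motion import MotionProfile, fit_alpha, trajectory_msd

MODES = ("constrained", "subdiffusive", "superdiffusive")


@dataclass
class DirectedSegment:
    """One extracted run of directed motion."""

    traj_id: str
    start_frame: int          # absolute frame of the first point
    end_frame: int            # absolute frame of the last point (inclusive)
    run_length: float         # µm, path length over the segment
    mean_velocity: float      # µm/s
    point_velocities: np.ndarray  # µm/s, one per point with a valid estimate
    point_times: np.ndarray       # s, absolute times of those points

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class ModeLabel:
    """Whole-trajectory motion-mode classification."""

    traj_id: str
    mean_alpha: float         # exponent of the whole-trajectory MSD fit
    mode: str                 # constrained | subdiffusive | superdiffusive | unclassified
    midpoint_t: float         # s, trajectory midpoint (used for time binning)


def instantaneous_velocity(traj: Trajectory, i: int, cfg: AnalysisConfig) -> float:
    """Smoothed speed at point ``i``: central difference over ±halfwidth frames.

    Returns nan when ``i`` is within ``velocity_halfwidth`` of either end.
    """
    h = cfg.velocity_halfwidth
    if i < h or i >= len(traj) - h:
        return np.nan
    d = traj.xy[i + h] - traj.xy[i - h]
    return float(np.linalg.norm(d) / (2 * h * traj.dt))


def _all_speeds(traj: Trajectory, cfg: AnalysisConfig) -> np.ndarray:
    """Vectorised instantaneous speed at every point (nan near the ends)."""
    h = cfg.velocity_halfwidth
    n = len(traj)
    v = np.full(n, np.nan)
    if n > 2 * h:
        d = traj.xy[2 * h :] - traj.xy[: n - 2 * h]
        v[h : n - h] = np.linalg.norm(d, axis=1) / (2 * h * traj.dt)
    return v


def _runs_of_true(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, stop) index pairs."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def displacement_rule_ok(xy: np.ndarray, cfg: AnalysisConfig, dt: float) -> bool:
    """Check the rolling minimum-displacement rule on a candidate run.

    Every sub-window of ``w = min(0.5 s / dt, P-1)`` frame intervals must
    displace more than ``min_displacement_um`` (prorated when the run is too
    short to hold a full 0.5-s window, keeping the same minimum speed).
    """
    P = len(xy)
    w_full = max(1, int(round(cfg.displacement_window_s / dt)))
    w = min(w_full, P - 1)
    threshold = cfg.min_displacement_um * (w * dt) / cfg.displacement_window_s
    disp = np.linalg.norm(xy[w:] - xy[:-w], axis=1)
    return bool(np.all(disp > threshold))


def _split_passing(
    xy: np.ndarray, a: int, b: int, cfg: AnalysisConfig, dt: float
) -> list[tuple[int, int]]:
    """Maximal sub-runs of points ``a..b`` (inclusive) obeying the rolling rule.

    A candidate run can contain an isolated slow sub-window — typically where
    the sliding classification window bleeds past the true end of a directed
    phase.  Rather than discarding the whole run, split it inside the slowest
    failing sub-window and recurse, so every returned sub-run satisfies
    ``displacement_rule_ok`` and only the slow stretch itself is dropped.
    """
    if b - a + 1 < cfg.min_directed_frames:
        return []
    if displacement_rule_ok(xy[a : b + 1], cfg, dt):
        return [(a, b)]
    P = b - a + 1
    w_full = max(1, int(round(cfg.displacement_window_s / dt)))
    w = min(w_full, P - 1)
    disp = np.linalg.norm(xy[a + w : b + 1] - xy[a : b + 1 - w], axis=1)
    mid = a + int(np.argmin(disp)) + w // 2  # split inside the slowest window
    return _split_passing(xy, a, mid, cfg, dt) + _split_passing(xy, mid + 1, b, cfg, dt)


def extract_directed_segments(
    profile: MotionProfile, traj: Trajectory, cfg: AnalysisConfig
) -> list[DirectedSegment]:
    """Extract directed segments from a profiled trajectory.

    Maximal runs of directed-flagged points are trimmed/split to their
    largest sub-runs satisfying the rolling displacement rule; each kept
    sub-run of at least ``min_directed_frames`` points becomes one segment
    with its path length and the mean of the valid smoothed instantaneous
    speeds inside it.
    """
    speeds = _all_speeds(traj, cfg)
    xy = traj.xy
    dt = traj.dt
    candidates: list[tuple[int, int]] = []
    for a0, b0 in _runs_of_true(np.asarray(profile.directed, dtype=bool)):
        candidates.extend(_split_passing(xy, a0, b0, cfg, dt))
    segments: list[DirectedSegment] = []
    for a, b in candidates:
        steps = np.diff(xy[a : b + 1], axis=0)
        run_length = float(np.linalg.norm(steps, axis=1).sum())
        sv = speeds[a : b + 1]
        times = traj.frames[a : b + 1] * dt
        # prefer interior points: their ±halfwidth velocity window lies fully
        # inside the segment, so no non-directed frames dilute the estimate
        h = cfg.velocity_halfwidth
        idx = np.arange(a, b + 1)
        ok = np.isfinite(sv) & (idx >= a + h) & (idx <= b - h)
        if not ok.any():
            ok = np.isfinite(sv)
        if ok.any():
            mean_v = float(np.mean(sv[ok]))
            pv, pt = sv[ok], times[ok]
        else:  # segment hugs a trajectory end: fall back to net path speed
            mean_v = run_length / ((b - a) * dt)
            pv, pt = np.array([mean_v]), np.array([times[0]])
        segments.append(
            DirectedSegment(
                traj_id=traj.id,
                start_frame=int(traj.frames[a]),
                end_frame=int(traj.frames[b]),
                run_length=run_length,
                mean_velocity=mean_v,
                point_velocities=pv,
                point_times=pt,
            )
        )
    return segments


def classify_mode(traj: Trajectory, cfg: AnalysisConfig) -> ModeLabel:
    """Label a trajectory by the exponent of its whole-trajectory MSD.

    The time-averaged MSD over lags ``1..n_max`` is fitted with a power law
    (optionally correcting the known static-noise floor from
    ``cfg.loc_noise_var``); the exponent falls into half-open intervals
    ``[0, alpha_constrained)`` → constrained, ``[alpha_constrained,
    alpha_super)`` → subdiffusive, ``[alpha_super, ∞)`` → superdiffusive.
    """
    curve = trajectory_msd(traj, cfg)
    fit = fit_alpha(curve, offset=4.0 * cfg.loc_noise_var)
    midpoint = float((traj.frames[0] + traj.frames[-1]) / 2.0 * traj.dt)
    if not fit.valid:
        return ModeLabel(traj.id, np.nan, "unclassified", midpoint)
    return ModeLabel(traj.id, float(fit.alpha), mode_from_alpha(fit.alpha, cfg), midpoint)


def mode_from_alpha(alpha: float, cfg: AnalysisConfig) -> str:
    """Map an MSD exponent to a motion mode via half-open intervals.

    Boundary values belong to the upper interval: ``[0, alpha_constrained)``
    → constrained, ``[alpha_constrained, alpha_super)`` → subdiffusive,
    ``[alpha_super, ∞)`` → superdiffusive.
    """
    if not np.isfinite(alpha):
        return "unclassified"
    if alpha < cfg.alpha_constrained:
        return "constrained"
    if alpha < cfg.alpha_super:
        return "subdiffusive"
    return "superdiffusive"


# ---------------------------------------------------------------------------
# Two-step binned statistics
# ---------------------------------------------------------------------------


def two_step_mean(per_cell_values: dict[str, np.ndarray]) -> tuple[float, float, int]:
    """Mean of per-cell means, with the standard error across cells.

    Cells with no samples are omitted.  Returns (mean, se, n_cells); se is
    nan for fewer than 2 cells.
    """
    cell_means = [float(np.mean(v)) for v in per_cell_values.values() if len(v) > 0]
    n = len(cell_means)
    if n == 0:
        return np.nan, np.nan, 0
    mean = float(np.mean(cell_means))
    se = float(np.std(cell_means, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return mean, se, n


def binned_velocity_stats(
    cells: dict[str, list[DirectedSegment]], cfg: AnalysisConfig
) -> pd.DataFrame:
    """Two-step directed-velocity statistics per 5-min time bin.

    Every point of directed motion is one sample.  Step 1 averages the
    point speeds within each cell and bin; step 2 averages those per-cell
    means (unweighted) across cells.  Cells with an empty bin are omitted
    from that bin.
    """
    rows = []
    # gather per-cell, per-bin samples
    binned: dict[int, dict[str, list[float]]] = {}
    for cell_id, segs in cells.items():
        for seg in segs:
            bins = np.floor(seg.point_times / cfg.bin_5min).astype(int)
            for b, v in zip(bins, seg.point_velocities):
                binned.setdefault(int(b), {}).setdefault(cell_id, []).append(float(v))
    for b in sorted(binned):
        per_cell = {c: np.asarray(v) for c, v in binned[b].items()}
        mean, se, n = two_step_mean(per_cell)
        rows.append(
            {
                "bin_start_s": b * cfg.bin_5min,
                "bin_end_s": (b + 1) * cfg.bin_5min,
                "mean_velocity": mean,
                "se_velocity": se,
                "n_cells": n,
                "n_samples": int(sum(len(v) for v in per_cell.values())),
            }
        )
    columns = ["bin_start_s", "bin_end_s", "mean_velocity", "se_velocity", "n_cells", "n_samples"]
    return pd.DataFrame(rows, columns=columns)


def mode_proportions(
    cells: dict[str, list[ModeLabel]], cfg: AnalysisConfig
) -> pd.DataFrame:
    """Two-step motion-mode proportions per 15-min time bin.

    A trajectory belongs to the bin containing its midpoint.  Per cell and
    bin the fractions over the three modes (of classified trajectories) sum
    to 1; the unclassified fraction is reported separately.
    """
    binned: dict[int, dict[str, list[ModeLabel]]] = {}
    for cell_id, labels in cells.items():
        for lab in labels:
            b = int(np.floor(lab.midpoint_t / cfg.bin_15min))
            binned.setdefault(b, {}).setdefault(cell_id, []).append(lab)
    rows = []
    for b in sorted(binned):
        fractions = {m: {} for m in MODES}
        unclassified = {}
        for cell_id, labels in binned[b].items():
            classified = [l for l in labels if l.mode in MODES]
            if classified:
                for m in MODES:
                    fractions[m][cell_id] = np.array(
                        [1.0 if l.mode == m else 0.0 for l in classified]
                    )
            unclassified[cell_id] = np.array(
                [1.0 if l.mode == "unclassified" else 0.0 for l in labels]
            )
        for m in MODES:
            mean, se, n = two_step_mean(fractions[m])
            rows.append(
                {
                    "bin_start_s": b * cfg.bin_15min,
                    "bin_end_s": (b + 1) * cfg.bin_15min,
                    "mode": m,
                    "fraction": mean,
                    "se": se,
                    "n_cells": n,
                }
            )
        mean_u, se_u, n_u = two_step_mean(unclassified)
        rows.append(
            {
                "bin_start_s": b * cfg.bin_15min,
                "bin_end_s": (b + 1) * cfg.bin_15min,
                "mode": "unclassified",
                "fraction": mean_u,
                "se": se_u,
                "n_cells": n_u,
            }
        )
    columns = ["bin_start_s", "bin_end_s", "mode", "fraction", "se", "n_cells"]
    return pd.DataFrame(rows, columns=columns)


def velocity_vs_runlength(
    segments: list[DirectedSegment], length_bin_edges: np.ndarray
) -> pd.DataFrame:
    """Mean segment velocity per run-length bin (left-closed, right-open).

    Segments falling outside every bin are pooled into an ``overflow`` row.
    """
    edges = np.asarray(length_bin_edges, dtype=float)
    if len(segments) == 0:
        raise ValueError("need at least one segment")
    rows = []
    lengths = np.array([s.run_length for s in segments])
    vels = np.array([s.mean_velocity for s in segments])
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (lengths >= lo) & (lengths < hi)
        n = int(sel.sum())
        rows.append(
            {
                "length_lo_um": lo,
                "length_hi_um": hi,
                "n_segments": n,
                "mean_velocity": float(vels[sel].mean()) if n else np.nan,
                "se_velocity": float(vels[sel].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            }
        )
    out = (lengths < edges[0]) | (lengths >= edges[-1])
    n_out = int(out.sum())
    rows.append(
        {
            "length_lo_um": np.nan,
            "length_hi_um": np.nan,
            "n_segments": n_out,
            "mean_velocity": float(vels[out].mean()) if n_out else np.nan,
            "se_velocity": float(vels[out].std(ddof=1) / np.sqrt(n_out)) if n_out > 1 else np.nan,
        }
    )
    df = pd.DataFrame(rows)
    df["bin"] = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])] + ["overflow"]
    return df
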