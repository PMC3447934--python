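"""Composition of the analysis stages for whole recordings.

Order of operations per cell: trajectory selection filter → per-point
motion profiling → directed-segment extraction → whole-trajectory mode
labels → binned two-step statistics → endocytic-ratio and intensity time
series.  Everything here is a thin orchestration layer over the other
modules; it exists so the command-line interface, the tests and the
reproduction script run the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import CellRecording, filter_trajectories
from .metrics import (
    EndocyticRatioSeries,
    IntensitySeries,
    endocytic_ratio_series,
    normalized_intensity_series,
)
from .motion import MotionProfile, profile_trajectory
from .segments import (
    DirectedSegment,
    ModeLabel,
    binned_velocity_stats,
    classify_mode,
    extract_directed_segments,
    mode_proportions,
)


@dataclass
class CellAnalysis:
    """All per-cell outputs of the trafficking pipeline."""

    cell_id: str
    n_input_trajectories: int
    n_filtered_trajectories: int
    profiles: list[MotionProfile] = field(default_factory=list)
    segments: list[DirectedSegment] = field(default_factory=list)
    modes: list[ModeLabel] = field(default_factory=list)
    ratio_series: EndocyticRatioSeries | None = None
    intensity_series: IntensitySeries | None = None


def analyze_recording(rec: CellRecording, cfg: AnalysisConfig) -> CellAnalysis:
    """Run the full single-cell pipeline on one recording."""
    filtered = filter_trajectories(rec, cfg.min_traj_frames)
    out = CellAnalysis(
        cell_id=rec.cell_id,
        n_input_trajectories=len(rec.trajectories),
        n_filtered_trajectories=len(filtered.trajectories),
    )
    for tr in filtered.trajectories:
        prof = profile_trajectory(tr, cfg)
        out.profiles.append(prof)
        out.segments.extend(extract_directed_segments(prof, tr, cfg))
        out.modes.append(classify_mode(tr, cfg))
    if rec.geometry is not None and filtered.trajectories:
        out.ratio_series = endocytic_ratio_series(filtered, cfg)
    if rec.puncta is not None and len(rec.puncta) and len(rec.puncta[0]):
        out.intensity_series = normalized_intensity_series(rec.puncta)
    return out


@dataclass
class ConditionAnalysis:
    """Pipeline outputs pooled over the cells of one condition."""

    condition: str
    cells: list[CellAnalysis]
    velocity_bins: pd.DataFrame
    mode_bins: pd.DataFrame


def analyze_condition(
    condition: str, recordings: list[CellRecording], cfg: AnalysisConfig
) -> ConditionAnalysis:
    cells = [analyze_recording(rec, cfg) for rec in recordings]
    seg_by_cell = {c.cell_id: c.segments for c in cells}
    mode_by_cell = {c.cell_id: c.modes for c in cells}
    return ConditionAnalysis(
        condition=condition,
        cells=cells,
        velocity_bins=binned_velocity_stats(seg_by_cell, cfg),
        mode_bins=mode_proportions(mode_by_cell, cfg),
    )


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------


def profiles_to_frame(cells: list[CellAnalysis]) -> pd.DataFrame:
    rows = []
    for cell in cells:
        for prof in cell.profiles:
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell.cell_id,
                        "traj_id": prof.traj_id,
                        "frame": prof.frames,
                        "alpha": prof.alpha,
                        "D": prof.D,
                        "phi": prof.phi,
                        "directed": prof.directed.astype(int),
                        "valid": prof.valid.astype(int),
                    }
                )
            )
    cols = ["cell_id", "traj_id", "frame", "alpha", "D", "phi", "directed", "valid"]
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)


def segments_to_frame(cells: list[CellAnalysis]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": cell.cell_id,
            "traj_id": s.traj_id,
            "start_frame": s.start_frame,
            "end_frame": s.end_frame,
            "n_frames": s.n_frames,
            "run_length_um": s.run_length,
            "mean_velocity_um_s": s.mean_velocity,
        }
        for cell in cells
        for s in cell.segments
    ]
    cols = [
        "cell_id", "traj_id", "start_frame", "end_frame", "n_frames",
        "run_length_um", "mean_velocity_um_s",
    ]
    return pd.DataFrame(rows, columns=cols)


def modes_to_frame(cells: list[CellAnalysis]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": cell.cell_id,
            "traj_id": m.traj_id,
            "mean_alpha": m.mean_alpha,
            "mode": m.mode,
            "midpoint_t_s": m.midpoint_t,
        }
        for cell in cells
        for m in cell.modes
    ]
    cols = ["cell_id", "traj_id", "mean_alpha", "mode", "midpoint_t_s"]
    return pd.DataFrame(rows, columns=cols)
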