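"""Trajectory and cell-geometry input/output.

Trajectories arrive either as ImageJ Particle Tracker report text (the
dialect produced by the MOSAIC plugin: ``Trajectory k`` headers followed by
per-frame rows ``frame x y z m0 ...`` in pixel units) or as a tidy CSV with
columns ``cell_id, traj_id, frame, x_um, y_um, intensity``.  Cell geometry
(a hand-drawn boundary polygon plus a centre point, standing in for manual
selection on DIC images) is stored as JSON with an explicit units field.

Conventions: frame indices are 0-based; positions are in micrometres with
the image convention (origin top-left, y increasing downward).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_UM = 0.267
DEFAULT_DT_S = 0.1


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class GeometryError(ValueError):
    """Raised when a cell geometry violates its invariants."""


@dataclass
class Trajectory:
    """One tracked punctum: ordered frames, planar positions in µm."""

    id: str
    frames: np.ndarray  # int, strictly increasing
    x: np.ndarray  # µm
    y: np.ndarray  # µm
    intensity: np.ndarray | None = None
    dt: float = DEFAULT_DT_S

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.frames) < 2:
            raise ValueError(f"trajectory {self.id!r} has < 2 points")
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError(f"trajectory {self.id!r}: column lengths differ")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"trajectory {self.id!r}: frames not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"trajectory {self.id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def t(self) -> np.ndarray:
        """Absolute time of each point in seconds."""
        return self.frames * self.dt

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) position array in µm."""
        return np.column_stack([self.x, self.y])


@dataclass
class CellGeometry:
    """Cell boundary polygon and centre point, both in µm."""

    boundary: np.ndarray  # (n, 2) closed or open ring; stored open
    center: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundary, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 3:
            raise GeometryError("boundary must be an (n>=3, 2) vertex array")
        # drop an explicit closing vertex; shapely closes rings itself
        if np.allclose(b[0], b[-1]):
            b = b[:-1]
        if b.shape[0] < 3:
            raise GeometryError("boundary has fewer than 3 distinct vertices")
        self.boundary = b
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        poly = Polygon(b)
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("boundary polygon is not simple (self-intersecting)")
        if not poly.contains(Point(self.center)):
            raise GeometryError("center point lies outside the boundary polygon")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.boundary)


@dataclass
class CellRecording:
    """All trajectories of one cell plus optional geometry and puncta lists."""

    cell_id: str
    trajectories: list[Trajectory] = field(default_factory=list)
    geometry: CellGeometry | None = None
    dt: float = DEFAULT_DT_S
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    # puncta[f] = intensities of all visible puncta in frame f
    puncta: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for tr in self.trajectories:
            tr.dt = self.dt

    @property
    def n_frames(self) -> int:
        if self.puncta is not None:
            return len(self.puncta)
        if not self.trajectories:
            return 0
        return int(max(tr.frames[-1] for tr in self.trajectories)) + 1


# ---------------------------------------------------------------------------
# Particle Tracker report text
# ---------------------------------------------------------------------------

_TRAJ_HEADER = re.compile(r"^%*\s*Trajectory\s+(\S+)", re.IGNORECASE)


def read_particle_tracker_text(
    path: str | Path,
    *,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    dt: float = DEFAULT_DT_S,
    cell_id: str | None = None,
) -> CellRecording:
    """Parse an ImageJ Particle Tracker report into a :class:`CellRecording`.

    Each trajectory block starts with a ``Trajectory k`` line (an optional
    ``%`` comment prefix is tolerated) followed by whitespace-separated
    numeric rows ``frame x y [z m0 m1 ...]``.  Tracker coordinates are in
    pixels and are converted to µm with ``pixel_size``; the zeroth intensity
    moment (5th column), when present, is kept as the point intensity.  The
    z and higher-moment columns are parsed but ignored downstream.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("%s: empty tracker file, returning empty recording", path)
        return CellRecording(cell_id=cell_id or path.stem, dt=dt, pixel_size=pixel_size)

    trajectories: list[Trajectory] = []
    cur_id: str | None = None
    rows: list[tuple[int, float, float, float | None]] = []

    def flush(lineno: int) -> None:
        nonlocal rows, cur_id
        if cur_id is None:
            return
        if len(rows) < 2:
            logger.warning("trajectory %s dropped: fewer than 2 points (line %d)", cur_id, lineno)
            rows, cur_id = [], None
            return
        rows.sort(key=lambda r: r[0])
        frames = np.array([r[0] for r in rows])
        x = np.array([r[1] for r in rows]) * pixel_size
        y = np.array([r[2] for r in rows]) * pixel_size
        inten = None
        if all(r[3] is not None for r in rows):
            inten = np.array([r[3] for r in rows])
        trajectories.append(Trajectory(id=cur_id, frames=frames, x=x, y=y, intensity=inten, dt=dt))
        rows, cur_id = [], None

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        m = _TRAJ_HEADER.match(stripped)
        if m:
            flush(lineno)
            cur_id = m.group(1)
            continue
        if stripped.startswith(("%", "#")):
            continue
        if cur_id is None:
            continue  # preamble outside any block
        parts = stripped.split()
        try:
            frame = int(float(parts[0]))
            px, py = float(parts[1]), float(parts[2])
            inten = float(parts[4]) if len(parts) >= 5 else None
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: unparseable tracker row {stripped!r}") from exc
        rows.append((frame, px, py, inten))
    flush(lineno=len(text.splitlines()))

    return CellRecording(
        cell_id=cell_id or path.stem,
        trajectories=trajectories,
        dt=dt,
        pixel_size=pixel_size,
    )


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["cell_id", "traj_id", "frame", "x_um", "y_um", "intensity"]


def write_csv(recordings: Sequence[CellRecording] | CellRecording, path: str | Path) -> None:
    """Write one or more recordings as tidy CSV (one row per point)."""
    if isinstance(recordings, CellRecording):
        recordings = [recordings]
    frames = []
    for rec in recordings:
        for tr in rec.trajectories:
            inten = tr.intensity if tr.intensity is not None else np.full(len(tr), np.nan)
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": rec.cell_id,
                        "traj_id": tr.id,
                        "frame": tr.frames,
                        "x_um": tr.x,
                        "y_um": tr.y,
                        "intensity": inten,
                    }
                )
            )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CSV_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_csv(
    path: str | Path,
    *,
    dt: float = DEFAULT_DT_S,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[CellRecording]:
    """Read recordings written by :func:`write_csv`; positions already in µm."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    recs = []
    for cell_id, cell_df in df.groupby("cell_id", sort=True):
        trajectories = []
        for traj_id, g in cell_df.groupby("traj_id", sort=True):
            g = g.sort_values("frame")
            inten = None
            if "intensity" in g and not g["intensity"].isna().any():
                inten = g["intensity"].to_numpy()
            trajectories.append(
                Trajectory(
                    id=str(traj_id),
                    frames=g["frame"].to_numpy(),
                    x=g["x_um"].to_numpy(),
                    y=g["y_um"].to_numpy(),
                    intensity=inten,
                    dt=dt,
                )
            )
        recs.append(
            CellRecording(
                cell_id=str(cell_id),
                trajectories=trajectories,
                dt=dt,
                pixel_size=pixel_size,
            )
        )
    return recs


# ---------------------------------------------------------------------------
# Geometry JSON
# ---------------------------------------------------------------------------


def write_geometry(geom: CellGeometry, path: str | Path) -> None:
    payload = {
        "units": "um",
        "boundary": np.asarray(geom.boundary).tolist(),
        "center": np.asarray(geom.center).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_geometry(path: str | Path) -> CellGeometry:
    """Load and validate a boundary-polygon + centre annotation file."""
    payload = json.loads(Path(path).read_text())
    if payload.get("units", "um") != "um":
        raise GeometryError(f"{path}: unsupported units {payload.get('units')!r}")
    return CellGeometry(
        boundary=np.asarray(payload["boundary"], dtype=float),
        center=np.asarray(payload["center"], dtype=float),
    )


# ---------------------------------------------------------------------------
# Trajectory selection
# ---------------------------------------------------------------------------


def filter_trajectories(recording: CellRecording, min_frames: int = 50) -> CellRecording:
    """Keep trajectories strictly longer than ``min_frames`` points.

    The selection rule for further analysis is a strict inequality: a
    trajectory of exactly ``min_frames`` points is discarded.
    """
    kept = [tr for tr in recording.trajectories if len(tr) > min_frames]
    removed = len(recording.trajectories) - len(kept)
    if removed:
        logger.info("cell %s: removed %d trajectories <= %d frames", recording.cell_id, removed, min_frames)
    return CellRecording(
        cell_id=recording.cell_id,
        trajectories=kept,
        geometry=recording.geometry,
        dt=recording.dt,
        pixel_size=recording.pixel_size,
        puncta=recording.puncta,
    )
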