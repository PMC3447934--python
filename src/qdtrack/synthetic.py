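"""Synthetic trajectory, scene and image generation with known ground truth.

No raw tracking data accompany the study this pipeline targets, so every
analysis stage is validated against simulations that emulate the
acquisition regime: 10 Hz sampling, 267 nm pixels, 10–30 nm localization
noise, per-cell ensembles of quantum-dot-labelled vesicles mixing
constrained, sub-diffusive and directed motion with Markovian state
switching, slow inward drift toward the cell centre, two-state QD blinking
and pairwise vesicle fusion that conserves total intensity.

Motion states
-------------
constrained
    Mean-reverting (discrete Ornstein–Uhlenbeck) walk around an anchor
    point, hard-reflected inside ``confinement_radius``.
subdiffusive
    Fractional Gaussian noise with Hurst exponent ``alpha_sub / 2``
    (circulant-embedding construction), so the ensemble MSD is exactly
    ``4 D_free dt · k^alpha_sub`` at lag *k* frames.
directed
    Constant speed ``v_directed`` with per-frame angular jitter of the
    heading plus a weak diffusive overlay ``D_directed`` (cargo on a
    microtubule has strongly suppressed transverse diffusion).

All randomness flows from one explicit seed per call; there is no global
random state, and identical (params, seed) give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .io import CellGeometry, CellRecording, Trajectory

STATES = ("constrained", "subdiffusive", "directed")


class ParameterError(ValueError):
    """Raised for physically impossible generator parameters."""


@dataclass
class MotionParams:
    """Single-trajectory motion model parameters.

    ``switch_rates[a][b]`` is the per-frame probability of switching from
    state ``a`` to state ``b``; missing entries are zero, so the default is
    a pure single-state walk starting in ``initial_state``.
    """

    dt: float = 0.1                 # s / frame (10 Hz)
    D_free: float = 0.01            # µm²/s, diffusive scale of non-directed states
    confinement_radius: float = 0.1 # µm, hard cage radius of the constrained state
    alpha_sub: float = 0.75         # target sub-diffusive MSD exponent, in (0, 1)
    v_directed: float = 1.0         # µm/s, speed of the directed state
    dir_jitter: float = 0.2         # rad per frame, sd of heading change while directed
    D_directed: float = 0.002       # µm²/s, diffusive overlay during directed motion
    loc_noise_sigma: float = 0.02   # µm, static localization error per coordinate
    initial_state: str = "subdiffusive"
    switch_rates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.D_free < 0 or self.D_directed < 0:
            raise ParameterError("diffusion constants must be non-negative")
        if self.loc_noise_sigma < 0:
            raise ParameterError("loc_noise_sigma must be non-negative")
        if self.v_directed < 0:
            raise ParameterError("v_directed must be non-negative")
        if not (0 < self.alpha_sub < 2):
            raise ParameterError("alpha_sub must lie in (0, 2)")
        if self.confinement_radius <= 0:
            raise ParameterError("confinement_radius must be positive")
        if self.initial_state not in STATES:
            raise ParameterError(f"unknown initial_state {self.initial_state!r}")
        for a, row in self.switch_rates.items():
            if a not in STATES:
                raise ParameterError(f"unknown state {a!r} in switch_rates")
            for b, p in row.items():
                if b not in STATES:
                    raise ParameterError(f"unknown state {b!r} in switch_rates")
                if not (0.0 <= p <= 1.0):
                    raise ParameterError("switch rates must lie in [0, 1]")
            if sum(row.values()) > 1.0 + 1e-12:
                raise ParameterError(f"outgoing rates from {a!r} exceed 1")

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 3x3 per-frame transition matrix over STATES."""
        P = np.eye(3)
        for a, row in self.switch_rates.items():
            ia = STATES.index(a)
            for b, p in row.items():
                ib = STATES.index(b)
                if ia != ib:
                    P[ia, ib] = p
            P[ia, ia] = 1.0 - sum(p for b, p in row.items() if b != a)
        return P


@dataclass
class SceneParams:
    """Whole-cell scene: an ensemble of trajectories inside one boundary."""

    n_trajectories: int = 30
    n_frames: int = 600
    cell_radius: float = 10.0          # µm
    boundary_irregularity: float = 0.0 # fractional radial perturbation of the polygon
    n_boundary_vertices: int = 64
    inward_drift_speed: float = 0.0    # µm/s toward the cell centre
    start_radius_range: tuple = (0.75, 0.95)  # fraction of boundary radius
    blink_on_rate: float = 0.2         # per-frame OFF -> ON probability
    blink_off_rate: float = 0.05       # per-frame ON -> OFF probability
    fusion_rate: float = 0.0           # per-frame probability of one pairwise fusion
    base_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 0:
            raise ParameterError("n_trajectories must be >= 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.cell_radius <= 0:
            raise ParameterError("cell_radius must be positive")
        for r in (self.blink_on_rate, self.blink_off_rate, self.fusion_rate):
            if not (0.0 <= r <= 1.0):
                raise ParameterError("rates must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generator ground truth for one trajectory or one scene."""

    # per-trajectory, per-frame motion-state label (length = n points)
    states: dict = field(default_factory=dict)          # traj_id -> array of str
    # traj_id -> list of (start_idx, end_idx, speed): true directed runs,
    # inclusive point indices
    segments: dict = field(default_factory=dict)
    # scene-level
    puncta_counts: np.ndarray | None = None             # per-frame visible puncta
    puncta_intensities: list | None = None              # per-frame intensity arrays
    base_intensities: dict | None = None                # traj_id -> final base
    fusion_events: list = field(default_factory=list)   # (frame, absorbed, survivor)
    overlap_fraction: float | None = None               # for rendered image pairs

    def to_jsonable(self) -> dict:
        out: dict = {
            "states": {k: list(map(str, v)) for k, v in self.states.items()},
            "segments": {k: [list(map(float, s)) for s in v] for k, v in self.segments.items()},
            "fusion_events": [list(e) for e in self.fusion_events],
        }
        if self.puncta_counts is not None:
            out["puncta_counts"] = [int(c) for c in self.puncta_counts]
        if self.base_intensities is not None:
            out["base_intensities"] = {k: float(v) for k, v in self.base_intensities.items()}
        if self.overlap_fraction is not None:
            out["overlap_fraction"] = float(self.overlap_fraction)
        return out


# ---------------------------------------------------------------------------
# Fractional Gaussian noise (circulant embedding)
# ---------------------------------------------------------------------------


def fractional_gaussian_noise(n: int, hurst: float, var1: float, rng: np.random.Generator) -> np.ndarray:
    """``n`` increments of fractional Brownian motion with Hurst ``hurst``.

    Scaled so the variance of the *k*-step partial sum is ``var1 * k^{2H}``
    (``var1`` is the one-step variance).  Uses the exact circulant-embedding
    spectral method; falls back to i.i.d. Gaussians at H = 1/2.
    """
    if n <= 0:
        return np.zeros(0)
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n) * np.sqrt(var1)
    k = np.arange(n + 1, dtype=float)
    H2 = 2.0 * hurst
    gamma = 0.5 * var1 * (np.abs(k + 1) ** H2 - 2 * np.abs(k) ** H2 + np.abs(k - 1) ** H2)
    # circulant embedding of the covariance: [g0..gn, g(n-1)..g1]
    row = np.concatenate([gamma, gamma[1:-1][::-1]])
    m = len(row)
    lam = np.fft.fft(row).real
    lam = np.maximum(lam, 0.0)  # clip numerical negatives
    # synthesize a complex Gaussian spectrum; the real part of the FFT has
    # covariance c_{j-l} when each mode is scaled by sqrt(lam/m)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(z * np.sqrt(lam / m))
    return w.real[:n]


# ---------------------------------------------------------------------------
# Single-trajectory simulation
# ---------------------------------------------------------------------------


def _sample_states(params: MotionParams, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    P = params.transition_matrix()
    states = np.empty(n_frames, dtype=object)
    cur = STATES.index(params.initial_state)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n_frames)
    for t in range(n_frames):
        states[t] = STATES[cur]
        if t < n_frames - 1:
            cur = int(np.searchsorted(cum[cur], u[t], side="right"))
            cur = min(cur, 2)
    return states


def _true_directed_runs(states: np.ndarray, speed: float) -> list[tuple[int, int, float]]:
    """Maximal runs of directed frames as inclusive point-index spans."""
    runs = []
    start = None
    for t, s in enumerate(states):
        if s == "directed" and start is None:
            start = t
        elif s != "directed" and start is not None:
            runs.append((start, t - 1, speed))
            start = None
    if start is not None:
        runs.append((start, len(states) - 1, speed))
    return runs


def simulate_trajectory(
    params: MotionParams,
    n_frames: int,
    seed: int,
    *,
    states: Sequence[str] | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    traj_id: str = "sim",
    start_frame: int = 0,
) -> tuple[Trajectory, SyntheticTruth]:
    """Simulate one trajectory with per-frame Markov state switching.

    ``states`` overrides the Markov chain with an explicit per-frame label
    sequence (used to embed runs at known locations).  The step from point
    *t* to *t+1* is governed by the state at *t*.  Independent Gaussian
    localization noise is added to every coordinate at the end.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    if states is None:
        st = _sample_states(params, n_frames, rng)
    else:
        st = np.asarray(list(states), dtype=object)
        if len(st) != n_frames:
            raise ParameterError("states must have one label per frame")
        for s in st:
            if s not in STATES:
                raise ParameterError(f"unknown state label {s!r}")

    dt = params.dt
    # pre-draw correlated sub-diffusive increments; consumed sequentially
    var1 = 2.0 * params.D_free * dt  # per-coordinate one-step variance
    fgn_x = fractional_gaussian_noise(n_frames - 1, params.alpha_sub / 2.0, var1, rng)
    fgn_y = fractional_gaussian_noise(n_frames - 1, params.alpha_sub / 2.0, var1, rng)
    sub_ptr = 0

    pos = np.empty((n_frames, 2))
    pos[0] = origin
    s_brown = np.sqrt(2.0 * params.D_free * dt)
    s_dir = np.sqrt(2.0 * params.D_directed * dt)
    sigma_c = params.confinement_radius / 2.0  # stationary sd of the cage walk
    rho = np.sqrt(max(0.0, 1.0 - (s_brown / sigma_c) ** 2)) if sigma_c > 0 else 0.0

    anchor = pos[0].copy()
    heading = rng.uniform(0, 2 * np.pi)
    prev_state = None
    for t in range(n_frames - 1):
        s = st[t]
        if s != prev_state:
            if s == "constrained":
                anchor = pos[t].copy()
            elif s == "directed":
                heading = rng.uniform(0, 2 * np.pi)
            prev_state = s
        if s == "constrained":
            nxt = anchor + rho * (pos[t] - anchor) + s_brown * rng.standard_normal(2)
            # hard reflection inside the cage
            delta = nxt - anchor
            r = np.hypot(*delta)
            if r > params.confinement_radius:
                nxt = anchor + delta * (params.confinement_radius / r)
            pos[t + 1] = nxt
        elif s == "subdiffusive":
            pos[t + 1] = pos[t] + np.array([fgn_x[sub_ptr], fgn_y[sub_ptr]])
            sub_ptr += 1
        else:  # directed
            if params.dir_jitter > 0:
                heading += params.dir_jitter * rng.standard_normal()
            step = params.v_directed * dt * np.array([np.cos(heading), np.sin(heading)])
            if params.D_directed > 0:
                step = step + s_dir * rng.standard_normal(2)
            pos[t + 1] = pos[t] + step

    if params.loc_noise_sigma > 0:
        pos = pos + params.loc_noise_sigma * rng.standard_normal(pos.shape)

    traj = Trajectory(
        id=traj_id,
        frames=np.arange(start_frame, start_frame + n_frames),
        x=pos[:, 0],
        y=pos[:, 1],
        dt=dt,
    )
    truth = SyntheticTruth(
        states={traj_id: st},
        segments={traj_id: _true_directed_runs(st, params.v_directed)},
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Blinking
# ---------------------------------------------------------------------------


def blinking_intensity_trace(
    on_rate: float,
    off_rate: float,
    base_intensity: float,
    n_frames: int,
    seed: int,
    *,
    start_on: bool = True,
    noise_cv: float = 0.0,
) -> np.ndarray:
    """Two-state telegraph emission trace of a single quantum dot.

    ON frames emit ``base_intensity`` (optionally with multiplicative shot
    noise of coefficient of variation ``noise_cv``), OFF frames emit 0.
    ``on_rate`` is the per-frame OFF→ON probability, ``off_rate`` the
    ON→OFF probability.
    """
    for r in (on_rate, off_rate):
        if not (0.0 <= r <= 1.0):
            raise ParameterError("blinking rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(n_frames)
    on = np.empty(n_frames, dtype=bool)
    state = bool(start_on)
    for t in range(n_frames):
        on[t] = state
        state = (u[t] >= off_rate) if state else (u[t] < on_rate)
    trace = np.where(on, float(base_intensity), 0.0)
    if noise_cv > 0:
        trace = trace * (1.0 + noise_cv * rng.standard_normal(n_frames))
        trace = np.maximum(trace, 0.0)
    return trace


# ---------------------------------------------------------------------------
# Whole-cell scenes
# ---------------------------------------------------------------------------


def _make_boundary(scene: SceneParams, rng: np.random.Generator) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, scene.n_boundary_vertices, endpoint=False)
    r = np.full_like(ang, scene.cell_radius)
    if scene.boundary_irregularity > 0:
        # smooth low-order radial perturbation keeps the polygon star-shaped
        a1, a2 = rng.uniform(-1, 1, 2) * scene.boundary_irregularity
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        r = r * (1.0 + a1 * np.sin(2 * ang + p1) + a2 * np.sin(3 * ang + p2))
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def _ray_boundary_distance(poly: Polygon, u: np.ndarray) -> float:
    """Distance from the origin-centre to the boundary along direction u."""
    from shapely.geometry import LineString

    span = 4.0 * max(abs(b) for b in poly.bounds)
    ray = LineString([(0.0, 0.0), (span * u[0], span * u[1])])
    inter = poly.exterior.intersection(ray)
    dists = [np.hypot(*c) for c in _geom_coords(inter)]
    dists = [d for d in dists if d > 1e-12]
    if not dists:
        raise RuntimeError("ray failed to hit the boundary")
    return min(dists)


def _geom_coords(geom) -> list[tuple[float, float]]:
    if geom.is_empty:
        return []
    if geom.geom_type == "Point":
        return [(geom.x, geom.y)]
    if geom.geom_type in ("MultiPoint", "GeometryCollection"):
        out = []
        for g in geom.geoms:
            out.extend(_geom_coords(g))
        return out
    if geom.geom_type == "LineString":
        return list(geom.coords)
    if geom.geom_type == "MultiLineString":
        out = []
        for g in geom.geoms:
            out.extend(g.coords)
        return out
    return []


def _reflect_inside(poly: Polygon, p: np.ndarray) -> np.ndarray:
    """Radially reflect a point that stepped outside the boundary polygon."""
    if poly.contains(Point(p)):
        return p
    d = np.hypot(*p)
    if d < 1e-12:
        return p
    u = p / d
    b = _ray_boundary_distance(poly, u)
    over = d - b
    new_d = max(b - over, 0.0) if over > 0 else b
    if new_d > b:  # pathological double-overshoot
        new_d = 0.5 * b
    return new_d * u


def simulate_cell_scene(
    scene: SceneParams,
    motion: MotionParams,
    *,
    cell_id: str = "cell0",
) -> tuple[CellRecording, SyntheticTruth]:
    """Simulate one cell: boundary, drifting trajectory ensemble, puncta.

    Trajectories are seeded near the boundary and, on top of their motion
    state, drift toward the cell centre at ``inward_drift_speed``; any step
    leaving the polygon is reflected radially back inside.  Per-frame puncta
    intensities combine two-state blinking with pairwise fusion: a fused
    aggregate carries the sum of its members' base intensities and no
    longer blinks.
    """
    if scene.inward_drift_speed * motion.dt > scene.cell_radius:
        raise ParameterError("inward drift step exceeds the cell radius")
    if scene.n_trajectories == 0:
        raise ParameterError("scene needs at least one trajectory")

    rng = np.random.default_rng(scene.seed)
    boundary = _make_boundary(scene, rng)
    geom = CellGeometry(boundary=boundary, center=np.array([0.0, 0.0]))
    poly = geom.polygon
    nf = scene.n_frames
    drift_step = scene.inward_drift_speed * motion.dt

    # simulate raw per-trajectory motion (relative to its own origin), then
    # superimpose drift and reflect inside the boundary
    trajs: list[Trajectory] = []
    truth = SyntheticTruth(states={}, segments={})
    bl_on = []
    for k in range(scene.n_trajectories):
        tid = f"{cell_id}_t{k}"
        theta = rng.uniform(0, 2 * np.pi)
        frac = rng.uniform(*scene.start_radius_range)
        # start at the given fraction of the boundary radius along theta
        u = np.array([np.cos(theta), np.sin(theta)])
        b_dist = _ray_boundary_distance(poly, u)
        start = frac * b_dist * u
        sub_seed = int(rng.integers(0, 2**31 - 1))
        traj, tr_truth = simulate_trajectory(
            motion, nf, sub_seed, origin=(0.0, 0.0), traj_id=tid
        )
        pos = traj.xy.copy()
        out = np.empty_like(pos)
        out[0] = start
        for t in range(1, nf):
            step = pos[t] - pos[t - 1]
            p = out[t - 1] + step
            # inward drift toward the centre, never overshooting it
            d = np.hypot(*p)
            if drift_step > 0 and d > 1e-9:
                p = p * max(d - drift_step, 0.05 * d) / d
            out[t] = _reflect_inside(poly, p)
        trajs.append(
            Trajectory(id=tid, frames=np.arange(nf), x=out[:, 0], y=out[:, 1], dt=motion.dt)
        )
        truth.states[tid] = tr_truth.states[tid]
        truth.segments[tid] = tr_truth.segments[tid]
        bl_seed = int(rng.integers(0, 2**31 - 1))
        bl_on.append(
            blinking_intensity_trace(scene.blink_on_rate, scene.blink_off_rate, 1.0, nf, bl_seed) > 0
        )

    # fusion bookkeeping: base intensities, aggregate flags, end frames
    base = {tr.id: scene.base_intensity for tr in trajs}
    aggregate = {tr.id: False for tr in trajs}
    end_frame = {tr.id: nf for tr in trajs}  # exclusive
    active = [tr.id for tr in trajs]
    order = {tr.id: i for i, tr in enumerate(trajs)}
    fuse_u = rng.random(nf)
    puncta: list[np.ndarray] = []
    counts = np.zeros(nf, dtype=int)
    for t in range(nf):
        if t > 0 and len(active) >= 2 and fuse_u[t] < scene.fusion_rate:
            i, j = rng.choice(len(active), size=2, replace=False)
            absorbed, survivor = active[max(i, j)], active[min(i, j)]
            base[survivor] += base[absorbed]
            aggregate[survivor] = True
            end_frame[absorbed] = t
            active.remove(absorbed)
            truth.fusion_events.append((t, absorbed, survivor))
        vals = [
            base[tid]
            for tid in active
            if aggregate[tid] or bl_on[order[tid]][t]
        ]
        arr = np.array(vals, dtype=float)
        puncta.append(arr)
        counts[t] = len(arr)

    # truncate absorbed trajectories at their fusion frame
    final_trajs = []
    for tr in trajs:
        ef = end_frame[tr.id]
        if ef >= nf:
            final_trajs.append(tr)
        elif ef >= 2:
            final_trajs.append(
                Trajectory(id=tr.id, frames=tr.frames[:ef], x=tr.x[:ef], y=tr.y[:ef], dt=tr.dt)
            )
            truth.states[tr.id] = truth.states[tr.id][:ef]
            truth.segments[tr.id] = [
                (a, min(b, ef - 1), v) for (a, b, v) in truth.segments[tr.id] if a < ef
            ]
        # trajectories absorbed before frame 2 are dropped entirely

    rec = CellRecording(
        cell_id=cell_id,
        trajectories=final_trajs,
        geometry=geom,
        dt=motion.dt,
        pixel_size=0.267,
        puncta=puncta,
    )
    truth.puncta_counts = counts
    truth.puncta_intensities = puncta
    truth.base_intensities = {tid: base[tid] for tid in base}
    return rec, truth


# ---------------------------------------------------------------------------
# Two-channel image fixtures
# ---------------------------------------------------------------------------


def render_two_channel_image(
    width: int,
    height: int,
    n_red_spots: int,
    overlap_fraction: float,
    seed: int,
    *,
    green_region_mask: np.ndarray | None = None,
    spot_sigma: float = 2.0,
    green_intensity: float = 400.0,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Render a (red, green) image pair with an exact red-on-green overlap.

    The red channel is a sum of truncated 2-D Gaussian spots; the green
    channel is ``green_intensity`` on a mask region (default: left half of
    the image) and 0 elsewhere.  Spot centres are placed at least 4 sigma
    plus one pixel away from the mask edge and the image border, and
    inside/outside amplitudes are scaled so that exactly
    ``overlap_fraction`` of the total red intensity falls on mask pixels.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ParameterError("overlap_fraction must lie in [0, 1]")
    if n_red_spots < 1:
        raise ParameterError("need at least one red spot")
    rng = np.random.default_rng(seed)
    if green_region_mask is None:
        green_region_mask = np.zeros((height, width), dtype=bool)
        green_region_mask[:, : width // 2] = True
    mask = np.asarray(green_region_mask, dtype=bool)
    if mask.shape != (height, width):
        raise ParameterError("green_region_mask shape must be (height, width)")

    from scipy.ndimage import binary_erosion

    margin = int(np.ceil(4.0 * spot_sigma)) + 1
    footprint = np.ones((2 * margin + 1, 2 * margin + 1), dtype=bool)
    border = np.zeros_like(mask)
    border[margin:-margin, margin:-margin] = True
    safe_in = binary_erosion(mask, structure=footprint) & border
    safe_out = binary_erosion(~mask, structure=footprint) & border

    f = overlap_fraction
    n = n_red_spots
    if f == 0.0:
        m_in = 0
    elif f == 1.0:
        m_in = n
    else:
        m_in = max(1, min(int(np.ceil(f * n)), n - 1))
    m_out = n - m_in
    if m_in > 0 and not safe_in.any():
        raise ParameterError("green region too small to host red spots away from its edge")
    if m_out > 0 and not safe_out.any():
        raise ParameterError("non-green region too small to host red spots")
    amp_in = (f * n / m_in) if m_in else 0.0
    amp_out = ((1.0 - f) * n / m_out) if m_out else 0.0

    red = np.zeros((height, width))
    rad = int(np.ceil(4.0 * spot_sigma))
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    kernel = np.exp(-(xx**2 + yy**2) / (2.0 * spot_sigma**2))
    kernel[xx**2 + yy**2 > rad**2] = 0.0  # hard truncation: compact support

    def place(region: np.ndarray, count: int, amp: float) -> None:
        ys, xs = np.nonzero(region)
        pick = rng.choice(len(ys), size=count, replace=True)
        for idx in pick:
            cy, cx = ys[idx], xs[idx]
            red[cy - rad : cy + rad + 1, cx - rad : cx + rad + 1] += amp * kernel

    if m_in:
        place(safe_in, m_in, amp_in)
    if m_out:
        place(safe_out, m_out, amp_out)

    green = np.where(mask, float(green_intensity), 0.0)
    achieved = float(red[mask].sum() / red.sum()) if red.sum() > 0 else float("nan")
    truth = SyntheticTruth(overlap_fraction=achieved)
    return red, green, truth


def save_two_channel_tiff(red: np.ndarray, green: np.ndarray, red_path, green_path) -> None:
    """Write the pair as 16-bit grayscale TIFFs, rescaled to the uint16 range."""
    import tifffile

    for img, path in ((red, red_path), (green, green_path)):
        top = img.max()
        scaled = (img / top * 60000.0) if top > 0 else img
        tifffile.imwrite(str(path), scaled.astype(np.uint16))
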