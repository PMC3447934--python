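"""Local mean-square-displacement and persistence analysis of trajectories.

For every point *i* of a trajectory, a sliding window of ``window_frames``
points centred on *i* yields

* a local MSD curve over lags ``n = 1..n_max`` (frames), averaged over all
  ordered pairs inside the window;
* the anomalous exponent ``alpha_i`` from a least-squares line through
  (log lag, log MSD) — the power-law fit ``MSD = Γ t^α``;
* the local diffusion constant ``D_i`` from the slope of the first
  ``d_fit_points`` MSD points (``MSD = 4 D t`` + free intercept, so a static
  localization-noise offset is absorbed by the intercept);
* the directional persistence ``phi_i``: the mean cosine of the turning
  angle between adjacent steps, 1 for perfectly straight motion, −1 for a
  path that reverses every frame, ~0 for an isotropic random walk.

A point is in the *directed state* when ``alpha_i >= alpha_dir`` and
``phi_i >= phi_min`` simultaneously.

Independent localization noise of variance σ² per coordinate adds a
constant ``4 σ²`` to the planar MSD, which flattens the log–log slope at
short lags.  When the static error is known (it always is for synthetic
data) it can be removed before the power-law fit via ``offset`` /
``cfg.loc_noise_var``; the default is no correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .config import AnalysisConfig
from .io import Trajectory


@dataclass
class MsdCurve:
    """Mean square displacement vs lag time, in µm² and seconds."""

    lags: np.ndarray  # seconds, n*dt for n = 1..n_max
    msd: np.ndarray   # µm²
    valid: bool = True

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)


class AlphaFit(NamedTuple):
    alpha: float      # power-law exponent (nan when fit invalid)
    prefactor: float  # Γ in MSD = Γ t^α
    valid: bool


class DFit(NamedTuple):
    D: float          # µm²/s (nan when invalid)
    clamped: bool     # True when a negative slope was clamped to 0
    valid: bool


@dataclass
class MotionProfile:
    """Per-point local dynamics of one trajectory."""

    traj_id: str
    frames: np.ndarray
    alpha: np.ndarray     # nan where invalid
    D: np.ndarray         # nan where invalid
    phi: np.ndarray       # nan where invalid
    directed: np.ndarray  # bool; directed implies valid
    valid: np.ndarray     # bool


def _window_bounds(n_points: int, i: int, window: int) -> tuple[int, int]:
    """Half-open index range of the centred window, truncated at the ends."""
    half = window // 2
    return max(0, i - half), min(n_points, i + half)


def _check_contiguous(traj: Trajectory) -> None:
    if np.any(np.diff(traj.frames) != 1):
        raise ValueError(
            f"trajectory {traj.id!r} has frame gaps; motion analysis requires "
            "consecutive frames"
        )


def local_msd(traj: Trajectory, i: int, cfg: AnalysisConfig) -> MsdCurve:
    """Local MSD curve in the window centred on point ``i``.

    ``msd(n)`` averages the squared planar displacement over every ordered
    pair ``(j, j+n)`` with both indices inside the window.  The curve is
    flagged invalid when the (truncated) window holds fewer than
    ``n_max + 1`` points.
    """
    _check_contiguous(traj)
    lo, hi = _window_bounds(len(traj), i, cfg.window_frames)
    wlen = hi - lo
    lags = np.arange(1, cfg.n_max + 1) * traj.dt
    if wlen < cfg.n_max + 1:
        return MsdCurve(lags=lags, msd=np.full(cfg.n_max, np.nan), valid=False)
    xy = traj.xy[lo:hi]
    msd = np.empty(cfg.n_max)
    for k, n in enumerate(range(1, cfg.n_max + 1)):
        d = xy[n:] - xy[:-n]
        msd[k] = np.mean(np.einsum("ij,ij->i", d, d))
    return MsdCurve(lags=lags, msd=msd, valid=True)


def trajectory_msd(traj: Trajectory, cfg: AnalysisConfig) -> MsdCurve:
    """Time-averaged MSD over the whole trajectory, lags ``1..n_max``.

    This is the curve used for whole-trajectory motility analysis; it pools
    every ordered pair at each lag, so it is far less noisy than any single
    local window.
    """
    _check_contiguous(traj)
    n_pts = len(traj)
    lags = np.arange(1, cfg.n_max + 1) * traj.dt
    if n_pts < cfg.n_max + 1:
        return MsdCurve(lags=lags, msd=np.full(cfg.n_max, np.nan), valid=False)
    xy = traj.xy
    msd = np.empty(cfg.n_max)
    for k, n in enumerate(range(1, cfg.n_max + 1)):
        d = xy[n:] - xy[:-n]
        msd[k] = np.mean(np.einsum("ij,ij->i", d, d))
    return MsdCurve(lags=lags, msd=msd, valid=True)


def fit_alpha(curve: MsdCurve, offset: float = 0.0) -> AlphaFit:
    """Power-law fit ``MSD = Γ t^α`` by least squares in log–log space.

    ``offset`` (µm²) is subtracted from the MSD before fitting; pass
    ``4 σ²`` to remove a known static localization-error floor.  Lags whose
    (corrected) MSD is not strictly positive are excluded; the fit needs at
    least 3 positive points.
    """
    if not curve.valid:
        return AlphaFit(np.nan, np.nan, False)
    y = curve.msd - offset
    mask = np.isfinite(y) & (y > 0)
    if mask.sum() < 3:
        return AlphaFit(np.nan, np.nan, False)
    lx = np.log(curve.lags[mask])
    ly = np.log(y[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    return AlphaFit(float(slope), float(np.exp(intercept)), True)


def fit_diffusion_constant(curve: MsdCurve, cfg: AnalysisConfig) -> DFit:
    """Diffusion constant from the initial linear part of the MSD curve.

    Least-squares slope *s* of MSD vs lag over the first ``d_fit_points``
    lags with a free intercept; ``D = s / 4``, clamped at zero when the
    slope is negative.
    """
    if not curve.valid or len(curve.lags) < cfg.d_fit_points:
        return DFit(np.nan, False, False)
    x = curve.lags[: cfg.d_fit_points]
    y = curve.msd[: cfg.d_fit_points]
    if not np.all(np.isfinite(y)):
        return DFit(np.nan, False, False)
    slope, _ = np.polyfit(x, y, 1)
    if slope < 0:
        return DFit(0.0, True, True)
    return DFit(float(slope / 4.0), False, True)


def _smoothed_vectors(xy: np.ndarray, h: int) -> np.ndarray:
    """Displacement vector at each point over ±h frames (h=0: raw steps).

    ``out[j] = xy[j+h] - xy[j-h]`` for h >= 1 (indexed so out[j] belongs to
    point ``j``, defined for j in [h, n-1-h]); for h = 0 the forward step
    ``xy[j+1] - xy[j]``.  Returned array starts at the first defined j.
    """
    if h == 0:
        return np.diff(xy, axis=0)
    if len(xy) <= 2 * h:
        return np.empty((0, 2))
    return xy[2 * h :] - xy[: len(xy) - 2 * h]


def local_persistence(traj: Trajectory, i: int, cfg: AnalysisConfig) -> float:
    """Mean cosine of turning angles in the window centred on point ``i``.

    Angles are measured between consecutive smoothed displacement vectors
    ``r(j + h) − r(j − h)`` with ``h = persistence_halfwidth``; smoothing
    suppresses the apparent zig-zag that frame-to-frame localization noise
    imposes on genuinely straight motion (``h = 0`` gives raw adjacent
    steps).  Zero-length vectors contribute no angle.  Returns nan when
    fewer than two usable angles remain.
    """
    _check_contiguous(traj)
    h = cfg.persistence_halfwidth
    lo, hi = _window_bounds(len(traj), i, cfg.window_frames)
    xy = traj.xy[lo:hi]
    vecs = _smoothed_vectors(xy, h)
    norms = np.linalg.norm(vecs, axis=1)
    cosines = []
    for j in range(len(vecs) - 1):
        if norms[j] == 0 or norms[j + 1] == 0:
            continue
        c = np.dot(vecs[j], vecs[j + 1]) / (norms[j] * norms[j + 1])
        cosines.append(np.clip(c, -1.0, 1.0))
    if len(cosines) < 2:
        return np.nan
    return float(np.mean(cosines))


# ---------------------------------------------------------------------------
# Vectorised whole-trajectory profiling
# ---------------------------------------------------------------------------


def _windowed_means(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values[lo_i:hi_i]`` per point via prefix sums; nan-aware.

    Returns (means, counts); mean is nan where the count is zero.
    """
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    lo_c = np.clip(lo, 0, len(values))
    hi_c = np.clip(hi, 0, len(values))
    hi_c = np.maximum(hi_c, lo_c)
    counts = ccnt[hi_c] - ccnt[lo_c]
    sums = csum[hi_c] - csum[lo_c]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def profile_trajectory(traj: Trajectory, cfg: AnalysisConfig) -> MotionProfile:
    """Compute per-point α, D, φ and the directed-state flag for a trajectory.

    Equivalent to calling :func:`local_msd`, :func:`fit_alpha`,
    :func:`fit_diffusion_constant` and :func:`local_persistence` at every
    point, but computed with prefix sums so whole movies profile quickly.
    When ``cfg.loc_noise_var`` is nonzero, the α fit subtracts the implied
    ``4 σ²`` MSD floor (the D fit needs no correction: its free intercept
    absorbs the offset).
    """
    _check_contiguous(traj)
    n = len(traj)
    xy = traj.xy
    dt = traj.dt
    n_max = cfg.n_max
    idx = np.arange(n)
    half = cfg.window_frames // 2
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half)
    wlen = hi - lo

    # local MSD for every point and lag: msd_all[i, k] for lag n = k+1
    msd_all = np.full((n, n_max), np.nan)
    for k in range(n_max):
        lag = k + 1
        if n <= lag:
            continue
        d = xy[lag:] - xy[:-lag]
        d2 = np.einsum("ij,ij->i", d, d)  # length n - lag, index j = pair start
        means, counts = _windowed_means(d2, lo, hi - lag)
        msd_all[:, k] = np.where(counts > 0, means, np.nan)

    window_ok = wlen >= (n_max + 1)

    # persistence: cosine of turning angle between consecutive smoothed
    # displacement vectors (see local_persistence)
    ph = cfg.persistence_halfwidth
    vecs = _smoothed_vectors(xy, ph)
    norms = np.linalg.norm(vecs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosv = np.einsum("ij,ij->i", vecs[:-1], vecs[1:]) / (norms[:-1] * norms[1:])
    cosv = np.clip(cosv, -1.0, 1.0)  # nan preserved for zero-length vectors
    # cosv[v] involves points [v, v + 2*max(ph,1)]; keep pairs fully inside the window
    upper = (hi - 2 * ph - 1) if ph >= 1 else (hi - 2)
    phi, phi_counts = _windowed_means(cosv, lo, upper)
    phi = np.where(phi_counts >= 2, phi, np.nan)

    # power-law exponent per point (offset-corrected log-log regression)
    lags_s = np.arange(1, n_max + 1) * dt
    lx = np.log(lags_s)
    lx_c = lx - lx.mean()
    denom = np.sum(lx_c**2)
    y = msd_all - 4.0 * cfg.loc_noise_var
    alpha = np.full(n, np.nan)
    all_pos = window_ok & np.all(y > 0, axis=1) & np.all(np.isfinite(y), axis=1)
    if np.any(all_pos):
        ly = np.log(y[all_pos])
        alpha[all_pos] = ly @ lx_c / denom
    # rows with some non-positive lags: fall back to the per-point fit
    partial = window_ok & ~all_pos
    for i in np.nonzero(partial)[0]:
        fit = fit_alpha(MsdCurve(lags=lags_s, msd=msd_all[i], valid=True), offset=4.0 * cfg.loc_noise_var)
        alpha[i] = fit.alpha if fit.valid else np.nan

    # diffusion constant per point: linear slope over the first d_fit_points
    p = cfg.d_fit_points
    xd = lags_s[:p]
    xd_c = xd - xd.mean()
    dden = np.sum(xd_c**2)
    D = np.full(n, np.nan)
    d_ok = window_ok & np.all(np.isfinite(msd_all[:, :p]), axis=1)
    if np.any(d_ok):
        slopes = msd_all[d_ok, :p] @ xd_c / dden
        D[d_ok] = np.maximum(slopes, 0.0) / 4.0

    valid = window_ok & np.isfinite(alpha) & np.isfinite(phi)
    with np.errstate(invalid="ignore"):
        directed = valid & (alpha >= cfg.alpha_dir) & (phi >= cfg.phi_min)

    return MotionProfile(
        traj_id=traj.id,
        frames=traj.frames.copy(),
        alpha=alpha,
        D=D,
        phi=phi,
        directed=directed,
        valid=valid,
    )
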