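"""Synthetic generator: motion classes, blinking, fusion, scenes, images."""

import numpy as np
import pytest

from qdtrack import (
    MotionParams,
    SceneParams,
    blinking_intensity_trace,
    render_two_channel_image,
    simulate_cell_scene,
    simulate_trajectory,
)
from qdtrack.synthetic import ParameterError, fractional_gaussian_noise
from shapely.geometry import Point


def test_directed_noise_free_straight_line():
    params = MotionParams(
        initial_state="directed", switch_rates={}, v_directed=1.0,
        dir_jitter=0.0, D_directed=0.0, loc_noise_sigma=0.0,
    )
    traj, _ = simulate_trajectory(params, 10, seed=1)
    steps = np.diff(traj.xy, axis=0)
    np.testing.assert_allclose(np.linalg.norm(steps, axis=1), 0.1, rtol=1e-12)
    # collinear: all steps identical
    np.testing.assert_allclose(steps - steps[0], 0.0, atol=1e-12)


def test_seeded_determinism():
    params = MotionParams()
    t1, _ = simulate_trajectory(params, 100, seed=5)
    t2, _ = simulate_trajectory(params, 100, seed=5)
    np.testing.assert_array_equal(t1.xy, t2.xy)


def test_free_diffusion_ensemble_msd():
    """Brute-force ensemble MSD vs the analytic 4 D t line, lags 1-10."""
    D, dt, n_frames, n_traj = 0.01, 0.1, 200, 500
    params = MotionParams(alpha_sub=1.0, D_free=D, loc_noise_sigma=0.0)
    acc = np.zeros(10)
    for k in range(n_traj):
        traj, _ = simulate_trajectory(params, n_frames, seed=k)
        xy = traj.xy
        for n in range(1, 11):
            d = xy[n:] - xy[:-n]
            acc[n - 1] += np.mean(np.einsum("ij,ij->i", d, d))
    msd = acc / n_traj
    expected = 4 * D * np.arange(1, 11) * dt
    np.testing.assert_allclose(msd, expected, rtol=0.10)


def test_subdiffusive_ensemble_exponent():
    """log-log regression of the ensemble MSD recovers alpha_sub within 0.1."""
    alpha, n_traj = 0.75, 500
    params = MotionParams(alpha_sub=alpha, D_free=0.01, loc_noise_sigma=0.0)
    acc = np.zeros(10)
    for k in range(n_traj):
        traj, _ = simulate_trajectory(params, 100, seed=10_000 + k)
        xy = traj.xy
        for n in range(1, 11):
            d = xy[n:] - xy[:-n]
            acc[n - 1] += np.mean(np.einsum("ij,ij->i", d, d))
    msd = acc / n_traj
    lags = np.arange(1, 11) * 0.1
    slope = np.polyfit(np.log(lags), np.log(msd), 1)[0]
    assert abs(slope - alpha) < 0.1


def test_fgn_one_step_variance():
    rng = np.random.default_rng(0)
    x = fractional_gaussian_noise(200_000, hurst=0.375, var1=0.002, rng=rng)
    assert np.var(x) == pytest.approx(0.002, rel=0.05)


def test_states_override_and_truth_runs():
    states = ["subdiffusive"] * 10 + ["directed"] * 20 + ["subdiffusive"] * 10
    params = MotionParams(v_directed=0.8)
    traj, truth = simulate_trajectory(params, 40, seed=2, states=states, traj_id="t")
    assert truth.segments["t"] == [(10, 29, 0.8)]
    with pytest.raises(ParameterError):
        simulate_trajectory(params, 5, seed=2, states=["bogus"] * 5)


def test_parameter_validation():
    with pytest.raises(ParameterError):
        MotionParams(dt=0.0)
    with pytest.raises(ParameterError):
        MotionParams(initial_state="ballistic")
    with pytest.raises(ParameterError):
        SceneParams(blink_on_rate=1.5)
    with pytest.raises(ParameterError):
        simulate_trajectory(MotionParams(), 1, seed=0)


# ---------------------------------------------------------------------------
# blinking
# ---------------------------------------------------------------------------


def test_blinking_absorbing_on():
    trace = blinking_intensity_trace(0.2, 0.0, 3.0, 50, seed=1, start_on=True)
    np.testing.assert_allclose(trace, 3.0)


def test_blinking_absorbing_off():
    trace = blinking_intensity_trace(0.0, 0.3, 3.0, 50, seed=1, start_on=False)
    np.testing.assert_allclose(trace, 0.0)


def test_blinking_values_binary_without_noise():
    trace = blinking_intensity_trace(0.3, 0.2, 2.5, 500, seed=4)
    assert set(np.unique(trace)) <= {0.0, 2.5}
    assert (trace == 0).any() and (trace == 2.5).any()


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


def _mean_radius(rec):
    acc = []
    n = rec.n_frames
    per_frame = [[] for _ in range(n)]
    for tr in rec.trajectories:
        for f, x, y in zip(tr.frames, tr.x, tr.y):
            per_frame[int(f)].append(np.hypot(x, y))
    return np.array([np.mean(v) for v in per_frame if v])


def test_scene_no_drift_flat_radius():
    scene = SceneParams(n_trajectories=20, n_frames=300, inward_drift_speed=0.0, seed=3)
    rec, _ = simulate_cell_scene(scene, MotionParams(loc_noise_sigma=0.0))
    r = _mean_radius(rec)
    # stationary radial distribution: start vs end differ only by sampling noise
    assert abs(r[-50:].mean() - r[:50].mean()) < 0.05 * r[:50].mean()


def test_scene_drift_monotone_radius():
    scene = SceneParams(n_trajectories=30, n_frames=400, inward_drift_speed=0.05, seed=3)
    rec, _ = simulate_cell_scene(scene, MotionParams())
    r = _mean_radius(rec)
    smooth = np.convolve(r, np.ones(20) / 20, mode="valid")
    assert np.all(np.diff(smooth) < 0)


def test_scene_positions_inside_boundary():
    scene = SceneParams(n_trajectories=15, n_frames=200, inward_drift_speed=0.0, seed=8)
    rec, _ = simulate_cell_scene(scene, MotionParams(v_directed=2.0))
    poly = rec.geometry.polygon.buffer(1e-9)
    for tr in rec.trajectories:
        for x, y in tr.xy:
            assert poly.contains(Point(x, y))


def test_scene_single_punctum_count_conserved():
    scene = SceneParams(
        n_trajectories=1, n_frames=100, blink_on_rate=1.0, blink_off_rate=0.0,
        fusion_rate=0.0, seed=5,
    )
    rec, truth = simulate_cell_scene(scene, MotionParams())
    np.testing.assert_array_equal(truth.puncta_counts, 1)
    assert all(len(p) == 1 for p in rec.puncta)


def test_scene_fusion_conserves_total_intensity():
    scene = SceneParams(
        n_trajectories=10, n_frames=200, blink_on_rate=1.0, blink_off_rate=0.0,
        fusion_rate=0.2, base_intensity=1.0, seed=11,
    )
    rec, truth = simulate_cell_scene(scene, MotionParams())
    assert len(truth.fusion_events) > 0
    totals = np.array([p.sum() for p in rec.puncta])
    np.testing.assert_allclose(totals, 10.0, rtol=1e-12)
    counts = truth.puncta_counts
    assert counts[0] == 10 and counts[-1] == 10 - len(truth.fusion_events)
    # pairwise additivity: each survivor's base is the sum of its members
    assert sum(truth.base_intensities.values()) == pytest.approx(
        10.0 + sum(truth.base_intensities[a] for _, a, _ in truth.fusion_events)
    )


def test_scene_zero_trajectories_rejected():
    scene = SceneParams(n_trajectories=0, n_frames=100, seed=1)
    with pytest.raises(ParameterError):
        simulate_cell_scene(scene, MotionParams())


def test_scene_determinism():
    scene = SceneParams(n_trajectories=5, n_frames=100, seed=21)
    r1, _ = simulate_cell_scene(scene, MotionParams())
    r2, _ = simulate_cell_scene(scene, MotionParams())
    for a, b in zip(r1.trajectories, r2.trajectories):
        np.testing.assert_array_equal(a.xy, b.xy)


# ---------------------------------------------------------------------------
# two-channel image fixtures
# ---------------------------------------------------------------------------


def test_render_full_overlap():
    red, green, truth = render_two_channel_image(64, 64, 5, 1.0, seed=1)
    assert truth.overlap_fraction == pytest.approx(1.0)
    assert red[green == 0].sum() == 0.0


def test_render_disjoint():
    red, green, truth = render_two_channel_image(64, 64, 5, 0.0, seed=1)
    assert truth.overlap_fraction == pytest.approx(0.0)
    assert red[green > 0].sum() == 0.0


def test_render_half_overlap_pixel_sum():
    red, green, truth = render_two_channel_image(64, 64, 6, 0.5, seed=2)
    # brute-force pixel summation oracle
    frac = red[green > 0].sum() / red.sum()
    assert frac == pytest.approx(0.5, abs=1e-9)
    assert truth.overlap_fraction == pytest.approx(frac)


def test_render_invalid_fraction():
    with pytest.raises(ParameterError):
        render_two_channel_image(64, 64, 5, 1.5, seed=1)
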