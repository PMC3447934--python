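"""Directed segments, mode classification, and binned statistics."""

import numpy as np
import pytest

from qdtrack import (
    AnalysisConfig,
    binned_velocity_stats,
    classify_mode,
    extract_directed_segments,
    instantaneous_velocity,
    mode_proportions,
    profile_trajectory,
    two_step_mean,
    velocity_vs_runlength,
)
from qdtrack.motion import MotionProfile
from qdtrack.segments import DirectedSegment, ModeLabel, displacement_rule_ok, mode_from_alpha

from conftest import line_traj, make_traj


def _profile_with_flags(traj, flags):
    n = len(traj)
    return MotionProfile(
        traj_id=traj.id,
        frames=traj.frames,
        alpha=np.full(n, 2.0),
        D=np.full(n, 0.01),
        phi=np.full(n, 1.0),
        directed=np.asarray(flags, dtype=bool),
        valid=np.ones(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------


def test_instantaneous_velocity_linear(cfg):
    traj = line_traj(30, v=0.5)
    assert instantaneous_velocity(traj, 15, cfg) == pytest.approx(0.5, rel=1e-12)


def test_instantaneous_velocity_stationary_and_edges(cfg):
    traj = make_traj(np.zeros((30, 2)))
    assert instantaneous_velocity(traj, 15, cfg) == 0.0
    assert np.isnan(instantaneous_velocity(traj, 0, cfg))
    assert np.isnan(instantaneous_velocity(traj, 29, cfg))


# ---------------------------------------------------------------------------
# displacement rule and extraction
# ---------------------------------------------------------------------------


def test_displacement_rule(cfg):
    fast = line_traj(20, v=1.0).xy     # 0.5 µm per 0.5 s > 0.267
    slow = line_traj(20, v=0.2).xy     # 0.1 µm per 0.5 s < 0.267
    assert displacement_rule_ok(fast, cfg, 0.1)
    assert not displacement_rule_ok(slow, cfg, 0.1)


def test_displacement_rule_prorated_short_run(cfg):
    # 3 intervals at 1 µm/s: 0.3 µm > 0.267 * (3*0.1/0.5) = 0.160
    assert displacement_rule_ok(line_traj(4, v=1.0).xy, cfg, 0.1)
    assert not displacement_rule_ok(line_traj(4, v=0.2).xy, cfg, 0.1)


def test_four_frame_run_rejected(cfg):
    traj = line_traj(40, v=1.0)
    flags = np.zeros(40, dtype=bool)
    flags[10:14] = True  # 4 consecutive points: below the 5-frame minimum
    segs = extract_directed_segments(_profile_with_flags(traj, flags), traj, cfg)
    assert segs == []


def test_twenty_frame_run_one_segment(cfg):
    traj = line_traj(60, v=1.0)
    flags = np.zeros(60, dtype=bool)
    flags[20:40] = True
    segs = extract_directed_segments(_profile_with_flags(traj, flags), traj, cfg)
    assert len(segs) == 1
    s = segs[0]
    assert s.n_frames == 20
    assert s.mean_velocity == pytest.approx(1.0, rel=1e-12)
    assert s.run_length == pytest.approx(19 * 0.1, rel=1e-12)


def test_slow_crawl_rejected(cfg):
    traj = line_traj(60, v=0.2)
    flags = np.zeros(60, dtype=bool)
    flags[20:40] = True
    segs = extract_directed_segments(_profile_with_flags(traj, flags), traj, cfg)
    assert segs == []


def test_run_with_slow_middle_is_split(cfg):
    """A stall inside a flagged run yields two rule-obeying segments."""
    fast1 = line_traj(20, v=1.0).xy
    stall = np.repeat(fast1[-1:], 10, axis=0)
    fast2 = stall[-1] + line_traj(20, v=1.0).xy
    xy = np.vstack([fast1, stall, fast2])
    traj = make_traj(xy)
    flags = np.ones(len(xy), dtype=bool)
    segs = extract_directed_segments(_profile_with_flags(traj, flags), traj, cfg)
    assert len(segs) >= 2
    for s in segs:
        assert s.n_frames >= cfg.min_directed_frames
        a, b = s.start_frame, s.end_frame
        assert displacement_rule_ok(traj.xy[a : b + 1], cfg, traj.dt)


def test_reported_segments_never_violate_rules(cfg):
    from qdtrack import MotionParams, simulate_trajectory

    params = MotionParams(
        v_directed=0.8,
        switch_rates={"subdiffusive": {"directed": 0.05}, "directed": {"subdiffusive": 0.1}},
    )
    for seed in range(20):
        traj, _ = simulate_trajectory(params, 300, seed=seed)
        prof = profile_trajectory(traj, cfg)
        for s in extract_directed_segments(prof, traj, cfg):
            assert s.n_frames >= cfg.min_directed_frames
            a = int(np.searchsorted(traj.frames, s.start_frame))
            b = int(np.searchsorted(traj.frames, s.end_frame))
            assert displacement_rule_ok(traj.xy[a : b + 1], cfg, traj.dt)


# ---------------------------------------------------------------------------
# mode classification
# ---------------------------------------------------------------------------


def test_mode_boundaries_half_open(cfg):
    assert mode_from_alpha(0.0, cfg) == "constrained"
    assert mode_from_alpha(cfg.alpha_constrained, cfg) == "subdiffusive"
    assert mode_from_alpha(cfg.alpha_super, cfg) == "superdiffusive"
    assert mode_from_alpha(np.nan, cfg) == "unclassified"


def test_classify_mode_ballistic(cfg):
    lab = classify_mode(line_traj(100, v=1.0), cfg)
    assert lab.mode == "superdiffusive"
    assert lab.mean_alpha == pytest.approx(2.0, abs=1e-9)


def test_classify_mode_confined(cfg):
    from qdtrack import MotionParams, simulate_trajectory

    params = MotionParams(
        initial_state="constrained", switch_rates={}, confinement_radius=0.1, loc_noise_sigma=0.0
    )
    traj, _ = simulate_trajectory(params, 300, seed=1)
    assert classify_mode(traj, cfg).mode == "constrained"


def test_classify_mode_unclassified_for_stationary(cfg):
    lab = classify_mode(make_traj(np.zeros((100, 2))), cfg)
    assert lab.mode == "unclassified"


# ---------------------------------------------------------------------------
# two-step statistics
# ---------------------------------------------------------------------------


def _segment(cell_t, vels, t0=0.0):
    vels = np.asarray(vels, dtype=float)
    return DirectedSegment(
        traj_id=cell_t,
        start_frame=0,
        end_frame=len(vels) - 1,
        run_length=1.0,
        mean_velocity=float(vels.mean()),
        point_velocities=vels,
        point_times=t0 + np.arange(len(vels)) * 0.1,
    )


def test_two_step_mean_weights_cells_equally():
    mean, se, n = two_step_mean({"A": np.array([1.0, 1.0, 1.0]), "B": np.array([2.0])})
    assert mean == pytest.approx(1.5)  # not 1.25
    assert n == 2


def test_binned_velocity_stats_two_step(cfg):
    cells = {"A": [_segment("a", [1.0, 1.0, 1.0])], "B": [_segment("b", [2.0])]}
    df = binned_velocity_stats(cells, cfg)
    assert len(df) == 1
    row = df.iloc[0]
    assert row["bin_start_s"] == 0.0 and row["bin_end_s"] == 300.0
    assert row["mean_velocity"] == pytest.approx(1.5)
    assert row["n_cells"] == 2 and row["n_samples"] == 4


def test_binned_velocity_stats_omits_empty_cells(cfg):
    cells = {
        "A": [_segment("a", [1.0, 1.0], t0=0.0)],
        "B": [_segment("b", [3.0, 3.0], t0=400.0)],  # only in the second bin
    }
    df = binned_velocity_stats(cells, cfg)
    first = df[df["bin_start_s"] == 0.0].iloc[0]
    second = df[df["bin_start_s"] == 300.0].iloc[0]
    assert first["mean_velocity"] == pytest.approx(1.0) and first["n_cells"] == 1
    assert second["mean_velocity"] == pytest.approx(3.0) and second["n_cells"] == 1


def test_mode_proportions_all_super(cfg):
    labels = [ModeLabel(f"t{i}", 2.0, "superdiffusive", 10.0) for i in range(5)]
    df = mode_proportions({"A": labels}, cfg)
    frac = df.set_index("mode")["fraction"]
    assert frac["superdiffusive"] == pytest.approx(1.0)
    assert frac["constrained"] == pytest.approx(0.0)
    assert frac["subdiffusive"] == pytest.approx(0.0)
    assert frac["unclassified"] == pytest.approx(0.0)


def test_mode_proportions_sum_to_one(cfg):
    rng = np.random.default_rng(0)
    modes = ["constrained", "subdiffusive", "superdiffusive"]
    cells = {
        c: [ModeLabel(f"{c}{i}", 0.5, rng.choice(modes), 10.0) for i in range(20)]
        for c in ("A", "B", "C")
    }
    df = mode_proportions(cells, cfg)
    total = df[df["mode"] != "unclassified"]["fraction"].sum()
    assert total == pytest.approx(1.0)


def test_mode_proportions_midpoint_binning(cfg):
    early = [ModeLabel("e", 2.0, "superdiffusive", 100.0)]
    late = [ModeLabel("l", 0.5, "subdiffusive", 1000.0)]
    df = mode_proportions({"A": early + late}, cfg)
    assert set(df["bin_start_s"]) == {0.0, 900.0}


def test_velocity_vs_runlength_binning():
    segs = [_segment("a", [0.5]), _segment("b", [1.5])]
    segs[0].run_length = 0.3
    segs[1].run_length = 1.2
    df = velocity_vs_runlength(segs, np.array([0.0, 0.5, 1.5]))
    assert list(df["n_segments"]) == [1, 1, 0]  # one per bin, empty overflow
    assert df.iloc[0]["mean_velocity"] == pytest.approx(0.5)
    assert df.iloc[1]["mean_velocity"] == pytest.approx(1.5)


def test_velocity_vs_runlength_overflow():
    seg = _segment("a", [1.0])
    seg.run_length = 9.0
    df = velocity_vs_runlength([seg], np.array([0.0, 1.0]))
    assert df[df["bin"] == "overflow"].iloc[0]["n_segments"] == 1
    with pytest.raises(ValueError):
        velocity_vs_runlength([], np.array([0.0, 1.0]))
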