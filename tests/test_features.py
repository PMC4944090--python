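"""Step decomposition: resampling, turning events, step geometry,
normalization, and the geometric invariances."""

import numpy as np
import pandas as pd
import pytest

from wormrle import (
    DegenerateFeatureWarning,
    EmptyResultWarning,
    InputError,
    SampledPath,
    SimParams,
    Trajectory,
    TurningEvents,
    compute_steps,
    detect_turning_events,
    normalize_features,
    resample_path,
    simulate_path,
)


def path_from_points(xs, ys, dt=1.0):
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    return SampledPath(np.arange(xs.size) * dt, xs, ys, dt)


def events_from_points(xs, ys):
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    n = xs.size
    return TurningEvents(
        np.arange(n), np.arange(n, dtype=float), xs, ys, theta_deg=40.0
    )


# -- resampling ------------------------------------------------------------

def test_resample_linear_interpolation():
    traj = Trajectory("a", "g", [0.0, 2.0], [0.0, 4.0], [0.0, 0.0])
    sp = resample_path(traj, 1.0)
    assert np.allclose(sp.t_s, [0, 1, 2])
    assert np.allclose(sp.x_mm, [0, 2, 4])


def test_resample_identity_on_grid():
    t = np.arange(5.0)
    traj = Trajectory("a", "g", t, t * 2, t * 3)
    sp = resample_path(traj, 1.0)
    assert np.allclose(sp.x_mm, t * 2)
    assert np.allclose(sp.y_mm, t * 3)
    assert sp.n_points == 5


def test_resample_30hz_straight_line():
    traj = simulate_path(
        SimParams(
            duration_s=10,
            roam_heading_sd_deg=0,
            p_roam_to_turn=0,
            speed_sd_mm_s=0,
            seed=0,
        )
    )
    sp = resample_path(traj, 1.0)
    assert sp.n_points == 11
    dx = np.diff(sp.x_mm)
    dy = np.diff(sp.y_mm)
    assert np.allclose(dx[:-1] * dy[1:] - dy[:-1] * dx[1:], 0, atol=1e-12)


def test_resample_too_short_rejected():
    traj = Trajectory("a", "g", [0.0, 1.5], [0.0, 1.0], [0.0, 0.0])
    with pytest.raises(InputError):
        resample_path(traj, 1.0)


# -- turning events --------------------------------------------------------

def test_collinear_path_only_initial_event():
    sp = path_from_points(np.arange(10.0), np.zeros(10))
    ev = detect_turning_events(sp, 40.0)
    assert list(ev.indices) == [0]


def test_right_angle_corner_detected_at_corner_adjacent_point():
    # 5 points going east, then 5 going north
    xs = [0, 1, 2, 3, 4, 4, 4, 4, 4, 4]
    ys = [0, 0, 0, 0, 0, 1, 2, 3, 4, 5]
    ev = detect_turning_events(path_from_points(xs, ys), 40.0)
    assert list(ev.indices) == [0, 5]


def test_zigzag_within_threshold_gives_initial_event_only():
    """Headings fluctuating within +-30 deg of the reference stay below
    theta=40, like a worm moving straight with wobbling head angle."""
    rng = np.random.default_rng(5)
    heads = np.deg2rad(rng.uniform(-30, 30, 30))
    heads[0] = 0.0  # reference heading = east
    xs = np.concatenate(([0], np.cumsum(np.cos(heads))))
    ys = np.concatenate(([0], np.cumsum(np.sin(heads))))
    ev = detect_turning_events(path_from_points(xs, ys), 40.0)
    assert list(ev.indices) == [0]


def test_stationary_path_warns_and_returns_initial_event():
    sp = path_from_points(np.zeros(6), np.zeros(6))
    with pytest.warns(EmptyResultWarning):
        ev = detect_turning_events(sp, 40.0)
    assert list(ev.indices) == [0]


def test_zero_displacement_inherits_heading():
    # pause in the middle of a straight run must not create an event
    xs = [0, 1, 2, 2, 2, 3, 4]
    ys = [0, 0, 0, 0, 0, 0, 0]
    ev = detect_turning_events(path_from_points(xs, ys), 40.0)
    assert list(ev.indices) == [0]


def test_reference_resets_after_event():
    # east, corner to north, then north continues: only one extra event
    xs = [0, 1, 2, 2, 2, 2]
    ys = [0, 0, 0, 1, 2, 3]
    ev = detect_turning_events(path_from_points(xs, ys), 40.0)
    assert list(ev.indices) == [0, 3]


def test_theta_bounds_validated():
    sp = path_from_points([0, 1, 2], [0, 0, 0])
    for bad in (0.0, 180.0, -5.0):
        with pytest.raises(InputError):
            detect_turning_events(sp, bad)


def test_theta_monotonicity_on_random_paths():
    """Raising theta never increases the number of turning events."""
    thetas = [20.0, 40.0, 60.0, 90.0, 120.0]
    for seed in range(25):
        traj = simulate_path(SimParams(duration_s=60, seed=seed))
        sp = resample_path(traj, 1.0)
        counts = [
            detect_turning_events(sp, th).n_events for th in thetas
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# -- steps -----------------------------------------------------------------

@pytest.mark.parametrize(
    "pts,expected_angle",
    [
        ([(0, 0), (1, 0), (2, 0)], 180.0),  # straight continuation
        ([(0, 0), (1, 0), (1, 1)], 90.0),   # perpendicular
        ([(0, 0), (1, 0), (0, 0)], 0.0),    # full reversal
    ],
)
def test_interior_angle_convention(pts, expected_angle):
    xs, ys = zip(*pts)
    table = compute_steps(events_from_points(xs, ys))
    assert table.n_steps == 2
    assert np.isnan(table.steps["angle_deg"].iloc[0])
    assert np.isclose(table.steps["angle_deg"].iloc[1], expected_angle)


def test_speed_is_displacement_over_time():
    ev = TurningEvents(
        np.array([0, 3]),
        np.array([2.0, 5.0]),
        np.array([0.0, 1.5]),
        np.array([0.0, 0.0]),
        theta_deg=40.0,
    )
    table = compute_steps(ev)
    assert np.isclose(table.steps["speed_mm_s"].iloc[0], 0.5)
    assert np.isclose(table.steps["length_mm"].iloc[0], 1.5)


def test_step_times_conserved():
    traj = simulate_path(SimParams(duration_s=120, seed=4))
    sp = resample_path(traj, 1.0)
    ev = detect_turning_events(sp, 40.0)
    table = compute_steps(ev)
    elapsed = (table.steps["t_end"] - table.steps["t_start"]).sum()
    assert np.isclose(elapsed, ev.t_s[-1] - ev.t_s[0])


def test_single_event_gives_empty_table_with_warning():
    ev = TurningEvents(
        np.array([0]), np.array([0.0]), np.array([0.0]), np.array([0.0]),
        theta_deg=40.0,
    )
    with pytest.warns(EmptyResultWarning):
        table = compute_steps(ev)
    assert table.n_steps == 0


def test_reflection_leaves_angles_unchanged():
    traj = simulate_path(SimParams(duration_s=90, seed=8))
    sp = resample_path(traj, 1.0)
    ev = detect_turning_events(sp, 40.0)
    t1 = compute_steps(ev)
    mirrored = SampledPath(sp.t_s, sp.x_mm, -sp.y_mm, sp.delta_t_s)
    t2 = compute_steps(detect_turning_events(mirrored, 40.0))
    a1 = t1.steps["angle_deg"].to_numpy()
    a2 = t2.steps["angle_deg"].to_numpy()
    assert np.allclose(a1, a2, equal_nan=True)


def test_scaling_coordinates_scales_lengths_not_angles():
    traj = simulate_path(SimParams(duration_s=90, seed=9))
    sp = resample_path(traj, 1.0)
    t1 = compute_steps(detect_turning_events(sp, 40.0))
    c = 3.5
    scaled = SampledPath(sp.t_s, c * sp.x_mm, c * sp.y_mm, sp.delta_t_s)
    t2 = compute_steps(detect_turning_events(scaled, 40.0))
    assert np.allclose(
        t2.steps["length_mm"], c * t1.steps["length_mm"]
    )
    assert np.allclose(
        t2.steps["speed_mm_s"], c * t1.steps["speed_mm_s"]
    )
    assert np.allclose(
        t2.steps["angle_deg"], t1.steps["angle_deg"], equal_nan=True
    )


# -- normalization ---------------------------------------------------------

def test_minmax_endpoints_and_midpoint():
    from conftest import make_step_table

    t = make_step_table(
        [np.nan, 30.0, 90.0],
        lengths=[1.0, 3.0, 2.0],
        speeds=[0.2, 0.5, 0.8],
    )
    (out,) = normalize_features([t])
    assert np.allclose(
        out.steps["length_norm"], [0.0, 1.0, 0.5]
    )
    assert np.isclose(out.steps["speed_norm"].iloc[1], 0.5)
    assert np.isnan(out.steps["angle_norm"].iloc[0])
    assert np.allclose(out.steps["angle_norm"].iloc[1:], [0.0, 1.0])


def test_normalization_is_pooled_across_animals():
    from conftest import make_step_table

    t1 = make_step_table([np.nan, 10.0], lengths=[1.0, 1.0], animal_id="a")
    t2 = make_step_table([np.nan, 170.0], lengths=[5.0, 5.0], animal_id="b")
    o1, o2 = normalize_features([t1, t2])
    # animal a holds the global minimum length, animal b the maximum
    assert np.allclose(o1.steps["length_norm"], 0.0)
    assert np.allclose(o2.steps["length_norm"], 1.0)


def test_zero_range_feature_flagged_and_zeroed():
    from conftest import make_step_table

    t = make_step_table(
        [np.nan, 45.0, 45.0], lengths=[1.0, 2.0, 3.0],
        speeds=[1.0, 1.0, 1.0],
    )
    with pytest.warns(DegenerateFeatureWarning):
        (out,) = normalize_features([t])
    assert set(out.degenerate_features) == {"angle", "speed"}
    assert np.allclose(out.steps["speed_norm"], 0.0)


def test_empty_pool_rejected():
    with pytest.raises(InputError):
        normalize_features([])
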