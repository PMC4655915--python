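"""4D trajectories: centres of activity, velocity fields, Euler integration."""

import numpy as np
import pytest

from neuroeit import (ConductivityImage, InverseGrid, TrajectoryConfig,
                      center_of_activity, depth_connection_profile,
                      integrate_trajectories, seed_lattice, velocity_field)
from neuroeit.trajectories import Termination


@pytest.fixture(scope="module")
def grid():
    return InverseGrid((0, 0, 0), 0.1, (24, 24, 20))


def image_from(values, grid, times=None):
    t = np.arange(values.shape[0]) if times is None else times
    return ConductivityImage(values, t, grid)


def gaussian_frame(grid, center, sigma=0.25, amp=1.0):
    c = grid.voxel_centers.reshape(*grid.shape, 3)
    r2 = ((c - np.asarray(center)) ** 2).sum(axis=-1)
    return amp * np.exp(-r2 / (2 * sigma ** 2))


# ----------------------------------------------------------------------
# centre of activity

def test_single_voxel_center(grid):
    v = np.zeros((1,) + grid.shape)
    v[0, 4, 5, 6] = 0.3
    com = center_of_activity(image_from(v, grid), 0)
    truth = grid.voxel_centers.reshape(*grid.shape, 3)[4, 5, 6]
    assert np.allclose(com, truth)


def test_two_equal_blobs_give_midpoint(grid):
    v = np.zeros((1,) + grid.shape)
    v[0, 4, 4, 4] = 1.0
    v[0, 16, 4, 4] = 1.0
    com = center_of_activity(image_from(v, grid), 0)
    cc = grid.voxel_centers.reshape(*grid.shape, 3)
    mid = (cc[4, 4, 4] + cc[16, 4, 4]) / 2
    assert np.allclose(com, mid)


def test_gaussian_blob_centroid_within_voxel(grid):
    target = np.array([1.23, 0.87, 1.02])
    v = gaussian_frame(grid, target)[None]
    com = center_of_activity(image_from(v, grid), 0)
    assert np.linalg.norm(com - target) <= grid.pitch


def test_all_zero_frame_sentinel(grid):
    com = center_of_activity(image_from(np.zeros((1,) + grid.shape), grid), 0)
    assert np.isnan(com).all()


# ----------------------------------------------------------------------
# velocity field

def test_time_constant_image_zero_velocity(grid):
    v = np.repeat(gaussian_frame(grid, (1.2, 1.2, 1.0))[None], 3, axis=0)
    field = velocity_field(image_from(v, grid))
    assert np.allclose(field.values, 0.0)


def test_linear_ramp_velocity_exact(grid):
    """sigma(r, t) = a t z -> v = (0, 0, a), discretization-exact."""
    a = 0.4
    zz = grid.voxel_centers.reshape(*grid.shape, 3)[..., 2]
    v = np.stack([a * t * zz for t in range(4)])
    field = velocity_field(image_from(v, grid))
    interior = field.values[:, 1:-1, 1:-1, 1:-1, :]
    assert np.allclose(interior[..., 2], a, atol=1e-12)
    assert np.allclose(interior[..., :2], 0.0, atol=1e-12)


def test_spatially_uniform_image_zero_velocity(grid):
    v = np.stack([np.full(grid.shape, t * 0.3) for t in range(4)])
    field = velocity_field(image_from(v, grid))
    interior = field.values[:, 1:-1, 1:-1, 1:-1, :]
    assert np.allclose(interior, 0.0, atol=1e-12)


def test_single_frame_rejected(grid):
    with pytest.raises(ValueError):
        velocity_field(image_from(np.zeros((1,) + grid.shape), grid))


# ----------------------------------------------------------------------
# integration

def moving_gaussian_image(grid, u=(0.12, 0.0, 0.0), n_frames=12):
    start = np.array([0.7, 1.2, 1.0])
    frames = [gaussian_frame(grid, start + np.asarray(u) * t)
              for t in range(n_frames)]
    return image_from(np.stack(frames), grid)


def test_zero_field_trajectories_stay_at_seed(grid):
    img = image_from(np.zeros((3,) + grid.shape), grid)
    field = velocity_field(img)
    trajs = integrate_trajectories(field, TrajectoryConfig(n_trajectories=8),
                                   center=np.array([1.2, 1.2, 1.0]))
    for tr in trajs:
        assert np.allclose(tr.points, tr.points[0])
        assert tr.termination == Termination.STAGNATION


def test_translating_gaussian_direction_and_speed(grid):
    u = np.array([0.12, 0.0, 0.0])   # mm per frame (= mm/ms)
    img = moving_gaussian_image(grid, u)
    field = velocity_field(img)
    cfg = TrajectoryConfig(n_trajectories=64, seed_roi_um=300.0,
                           time_window_ms=(2.0, 9.0))
    com = center_of_activity(img, 2.0)
    trajs = integrate_trajectories(field, cfg, center=com)
    disp = np.array([tr.points[-1] - tr.points[0] for tr in trajs
                     if len(tr.points) > 5])
    mean_disp = disp.mean(axis=0)
    angle = np.degrees(np.arccos(
        mean_disp @ u / (np.linalg.norm(mean_disp) * np.linalg.norm(u))))
    assert angle < 10.0
    # settled mean speed within 15% of |u|: trajectories first relax from
    # the seed onto the comoving flank of the blob (where the local drift
    # speed equals the translation speed), so measure the second half
    speeds = []
    for tr in trajs:
        if len(tr.points) > 5:
            k = len(tr.points) // 2
            speeds.append(np.linalg.norm(tr.points[-1] - tr.points[k])
                          / (tr.times_ms[-1] - tr.times_ms[k]))
    assert np.mean(speeds) == pytest.approx(np.linalg.norm(u), rel=0.15)


def test_step_length_bound_never_violated(grid):
    img = moving_gaussian_image(grid)
    field = velocity_field(img)
    cfg = TrajectoryConfig(n_trajectories=27)
    trajs = integrate_trajectories(field, cfg,
                                   center=center_of_activity(img, 0))
    for tr in trajs:
        steps = np.linalg.norm(tr.steps(), axis=1)
        if len(steps):
            assert steps.max() <= cfg.r_z_um / 1000.0 + 1e-12


def test_seed_lattice_deterministic():
    cfg = TrajectoryConfig(n_trajectories=1000)
    s1 = seed_lattice(np.array([1.0, 2.0, 0.5]), cfg)
    s2 = seed_lattice(np.array([1.0, 2.0, 0.5]), cfg)
    assert np.array_equal(s1, s2)
    assert s1.shape == (1000, 3)
    assert np.abs(s1 - [1.0, 2.0, 0.5]).max() <= 0.25


def test_time_reversed_field_reverses_direction(grid):
    img = moving_gaussian_image(grid)
    field = velocity_field(img)
    rev = velocity_field(ConductivityImage(img.values[::-1], img.times_ms,
                                           grid))
    cfg = TrajectoryConfig(n_trajectories=27, seed_roi_um=300.0,
                           time_window_ms=(3.0, 8.0))
    c = center_of_activity(img, 5.0)
    fwd = integrate_trajectories(field, cfg, center=c)
    bwd = integrate_trajectories(rev, cfg, center=c)
    d_f = np.mean([tr.points[-1] - tr.points[0] for tr in fwd], axis=0)
    d_b = np.mean([tr.points[-1] - tr.points[0] for tr in bwd], axis=0)
    cos = d_f @ d_b / (np.linalg.norm(d_f) * np.linalg.norm(d_b))
    assert cos < -0.8


# ----------------------------------------------------------------------
# depth-connection profile

def synthetic_trajectory(points, dt=1.0):
    points = np.asarray(points, dtype=float)
    return type("T", (), {})  # placeholder, replaced below


def test_vertical_trajectories_give_empty_profile():
    from neuroeit.trajectories import Trajectory
    trajs = [Trajectory(np.arange(5.0),
                        np.column_stack([np.zeros(5), np.zeros(5),
                                         np.linspace(0, 0.2, 5)]),
                        np.zeros(3), Termination.TIME_END)]
    edges, counts, argmax = depth_connection_profile(trajs)
    assert counts.sum() == 0
    assert np.isnan(argmax)


def test_lateral_band_argmax():
    """Lateral motion confined to 400-500 um depth -> argmax bin there."""
    from neuroeit.trajectories import Trajectory
    rng = np.random.default_rng(0)
    trajs = []
    for _ in range(30):
        z = rng.uniform(0.41, 0.49)
        xs = np.cumsum(rng.uniform(0.02, 0.04, 6))
        pts = np.column_stack([xs, np.zeros(6), np.full(6, z)])
        trajs.append(Trajectory(np.arange(6.0), pts, pts[0],
                                Termination.TIME_END))
        # plus a vertical distractor elsewhere
        pts2 = np.column_stack([np.zeros(4), np.zeros(4),
                                np.linspace(0.8, 1.0, 4)])
        trajs.append(Trajectory(np.arange(4.0), pts2, pts2[0],
                                Termination.TIME_END))
    edges, counts, argmax = depth_connection_profile(
        trajs, depth_range_mm=(0.0, 1.2))
    assert 0.40 <= argmax <= 0.50


def test_phantom_confined_lateral_spread_recovered():
    """A phantom whose activity (and lateral spread) is confined to the
    400-500 um band yields a connection profile peaking in that band."""
    from neuroeit import build_slab_mesh, make_activity_phantom
    mesh = build_slab_mesh((5, 4, 2), 0.25)
    ph = make_activity_phantom(mesh, onset_depth_um=450.0,
                               depth_upper_um=400.0, depth_lower_um=500.0,
                               sigma_z_mm=0.03,
                               lateral_band_um=(400.0, 500.0),
                               lateral_fraction=1.0)
    grid = InverseGrid.covering(mesh, 0.2)
    img = ph.truth_image(grid)
    field = velocity_field(img)
    com = center_of_activity(img, 10.0)
    trajs = integrate_trajectories(
        field, TrajectoryConfig(n_trajectories=125,
                                time_window_ms=(8.0, 18.0)), center=com)
    _, _, argmax = depth_connection_profile(trajs, bin_um=50.0)
    assert 0.40 <= argmax <= 0.50


def test_counts_double_with_trajectory_count():
    from neuroeit.trajectories import Trajectory
    pts = np.column_stack([np.linspace(0, 0.3, 7), np.zeros(7),
                           np.full(7, 0.45)])
    one = [Trajectory(np.arange(7.0), pts, pts[0], Termination.TIME_END)]
    _, c1, _ = depth_connection_profile(one, depth_range_mm=(0, 1))
    _, c2, _ = depth_connection_profile(one * 2, depth_range_mm=(0, 1))
    assert np.array_equal(c2, 2 * c1)


def test_empty_trajectory_set_rejected():
    with pytest.raises(ValueError):
        depth_connection_profile([])
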