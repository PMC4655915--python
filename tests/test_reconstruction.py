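"""Tikhonov inversion, difference-data assembly, population statistics."""

import numpy as np
import pytest
from scipy import stats

from neuroeit import (ConductivityImage, InverseGrid, TikhonovSolver,
                      activity_flags, binomial_activity_mask, grand_average,
                      tikhonov_reconstruct, tscore_map)
from neuroeit.reconstruction import assemble_difference_data
from neuroeit.signals import QCMask


@pytest.fixture(scope="module")
def toy_problem(request):
    rng = np.random.default_rng(0)
    m, n = 60, 200
    J = rng.normal(size=(m, n)) * np.exp(-np.linspace(0, 4, n))[None, :]
    x = np.zeros(n)
    x[40:44] = 1.0
    noise_sd = np.full(m, 0.05)
    d = J @ x + rng.normal(0, 0.05, m)
    return {"J": J, "x": x, "d": d, "noise": noise_sd}


def test_zero_data_gives_zero_image(toy_problem):
    solver = TikhonovSolver(toy_problem["J"], toy_problem["noise"])
    assert np.allclose(solver.solve(np.zeros(60), 1.0), 0.0)


def test_image_norm_monotone_in_lambda(toy_problem):
    solver = TikhonovSolver(toy_problem["J"], toy_problem["noise"])
    lams = np.logspace(-4, 6, 12)
    norms = [np.linalg.norm(solver.solve(toy_problem["d"], l)) for l in lams]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
    assert norms[-1] < 1e-3 * norms[0]      # lambda -> inf: image -> 0


def test_solution_linear_in_data(toy_problem):
    solver = TikhonovSolver(toy_problem["J"], toy_problem["noise"])
    x1 = solver.solve(toy_problem["d"], 2.0)
    x3 = solver.solve(3.0 * toy_problem["d"], 2.0)
    assert np.allclose(x3, 3.0 * x1)


def test_discrepancy_lambda_matches_brute_force_scan(toy_problem):
    solver = TikhonovSolver(toy_problem["J"], toy_problem["noise"])
    lam = solver.discrepancy_lambda(toy_problem["d"])
    target = 1.05 * np.sqrt(60)
    grid = np.logspace(np.log10(lam) - 2, np.log10(lam) + 2, 4001)
    resid = np.array([solver.residual_norm(toy_problem["d"], l) for l in grid])
    best = grid[np.argmin(np.abs(resid - target))]
    assert lam == pytest.approx(best, rel=0.10)


def test_zero_noise_disables_weighting(toy_problem):
    with pytest.warns(UserWarning):
        solver = TikhonovSolver(toy_problem["J"], np.zeros(60))
    assert np.allclose(solver.w, 1.0)


def test_row_mismatch_rejected(small_forward):
    jac = small_forward["jacobian"]
    with pytest.raises(ValueError):
        tikhonov_reconstruct(jac, np.zeros(3))


def test_noiseless_sphere_recovered_within_one_voxel(slab_study):
    """Noiseless single-sphere perturbation on the slab, 30-electrode
    protocol: reconstructed centre of mass within 0.2 mm of truth."""
    from neuroeit.resolution import (PerturbationSpec, localization_error,
                                     simulate_measurement)
    solver = TikhonovSolver(slab_study.jacobian.percent_scaled(), None)
    lam = solver.s[0] ** 2 * 1e-5
    for loc in [(3.5, 2.5, 0.8), (2.5, 1.9, 1.2)]:
        spec = PerturbationSpec(np.array(loc))
        d = simulate_measurement(slab_study.model, spec, slab_study.protocol,
                                 noise_sd_uv=0.0, seed=0)
        img = solver.solve(d, lam)
        res = localization_error(spec, img, slab_study.grid)
        assert res.error_mm <= 0.2


# ----------------------------------------------------------------------
# difference-data assembly

def test_baseline_window_yields_near_zero_vector(end_to_end_run):
    rec = end_to_end_run
    diff = assemble_difference_data(rec.records, rec.qc,
                                    t_start_ms=340, t_stop_ms=350)
    scale = np.abs(np.concatenate([r.baseline_v for r in rec.records])).max()
    assert np.abs(diff.matrix).max() < 1e-3 * scale


def test_channel_bookkeeping(end_to_end_run):
    rec = end_to_end_run
    n_total = sum(r.n_channels for r in rec.records)
    flags = rec.qc.flags.copy()
    keep = np.flatnonzero(flags == 0)
    flags[keep[:40]] = 2   # reject 40 more channels
    diff = assemble_difference_data(rec.records, QCMask(flags))
    assert diff.matrix.shape[1] == (flags == 0).sum() == rec.qc.n_retained - 40
    assert n_total == 840


def test_all_channels_rejected_aborts(end_to_end_run):
    rec = end_to_end_run
    bad = QCMask(np.ones(840, dtype=int))
    with pytest.raises(ValueError):
        assemble_difference_data(rec.records, bad)


# ----------------------------------------------------------------------
# population statistics

def make_image(values, grid):
    return ConductivityImage(values, np.arange(values.shape[0]), grid)


@pytest.fixture(scope="module")
def stat_grid():
    return InverseGrid((0, 0, 0), 0.2, (6, 5, 4))


def test_tscore_matches_closed_form(stat_grid, rng):
    n = 16
    peaks = rng.normal(0.3, 0.1, size=(n,) + stat_grid.shape)
    images = [make_image(p[None], stat_grid) for p in peaks]
    ts = tscore_map(images)
    assert ts.df == 15
    expected = peaks.mean(0) / (peaks.std(0, ddof=1) / np.sqrt(n))
    assert np.allclose(ts.t, expected)


def test_tscore_sign_flip_antisymmetric(stat_grid, rng):
    vals = rng.normal(0.1, 0.05, size=(4, 2) + stat_grid.shape)
    imgs = [make_image(v, stat_grid) for v in vals]
    neg = [make_image(-v, stat_grid) for v in vals]
    assert np.allclose(tscore_map(neg).t, -tscore_map(imgs).t)


def test_tscore_degenerate_voxels_flagged(stat_grid):
    same = np.full((1,) + stat_grid.shape, 0.5)
    imgs = [make_image(same.copy(), stat_grid) for _ in range(3)]
    ts = tscore_map(imgs)
    assert ts.degenerate.all()
    assert np.isinf(ts.t).all()


def test_binomial_mask_all_recordings_active():
    flags = np.ones((16, 10), dtype=bool)
    mask = binomial_activity_mask(flags, alpha_voxel=0.05, p_threshold=1e-4)
    assert np.allclose(mask.tail_p, 0.05 ** 16)
    assert mask.active.all()


def test_binomial_mask_no_recordings_active():
    flags = np.zeros((16, 10), dtype=bool)
    mask = binomial_activity_mask(flags)
    assert np.allclose(mask.tail_p, 1.0)
    assert not mask.active.any()


def test_binomial_tail_matches_scipy(rng):
    flags = rng.random((8, 50)) < 0.3
    mask = binomial_activity_mask(flags, alpha_voxel=0.05)
    k = flags.sum(axis=0)
    assert np.allclose(mask.tail_p, stats.binom.sf(k - 1, 8, 0.05))


def test_grand_average_identical_recordings(stat_grid):
    v = np.zeros((2,) + stat_grid.shape)
    v[1, 3, 2, 1] = 0.04
    imgs = [make_image(v.copy(), stat_grid) for _ in range(5)]
    g = grand_average(imgs)
    assert np.abs(g.values).max() == pytest.approx(1.0)
    assert np.allclose(g.values, v / 0.04)


def test_grand_average_disjoint_foci(stat_grid):
    a = np.zeros((1,) + stat_grid.shape)
    b = np.zeros((1,) + stat_grid.shape)
    a[0, 1, 1, 1] = 0.05
    b[0, 4, 3, 2] = 0.08
    g = grand_average([make_image(a, stat_grid), make_image(b, stat_grid)])
    assert g.values[0, 1, 1, 1] == pytest.approx(0.5)
    assert g.values[0, 4, 3, 2] == pytest.approx(0.5)


def test_grand_average_recovers_common_focus(stat_grid, rng):
    """n=16 noisy recordings sharing one focus: the average's CoM lies
    within one voxel of the focus."""
    from neuroeit.trajectories import center_of_activity
    focus = np.zeros(stat_grid.shape)
    focus[3, 2, 1] = 1.0
    imgs = []
    for _ in range(16):
        v = 0.05 * focus + rng.normal(0, 0.01, stat_grid.shape)
        imgs.append(make_image(v[None], stat_grid))
    g = grand_average(imgs)
    com = center_of_activity(g, 0)
    truth = stat_grid.voxel_centers.reshape(*stat_grid.shape, 3)[3, 2, 1]
    assert np.linalg.norm(com - truth) <= stat_grid.pitch


def test_activity_flags_null_rate(stat_grid, rng):
    """Pure-noise recordings: the per-recording flag rate stays near alpha."""
    imgs = [make_image(rng.normal(0, 0.01, (6,) + stat_grid.shape), stat_grid)
            for _ in range(6)]
    flags = activity_flags(imgs, alpha_voxel=0.05, null_window_ms=(0.0, 3.0))
    assert 0.0 < flags.mean() < 0.15
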