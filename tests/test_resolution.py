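"""Localization-accuracy machinery: perturbations, measurements, errors."""

import numpy as np
import pytest

from neuroeit import (InverseGrid, PerturbationSpec, apply_perturbation,
                      build_slab_mesh, localization_error,
                      simulate_measurement)
from neuroeit.resolution import candidate_locations, error_map


def test_one_percent_perturbation_gives_0303(small_forward):
    mesh = small_forward["mesh"]
    spec = PerturbationSpec(np.array([1.2, 1.2, 0.6]), 0.5, 0.01)
    out = apply_perturbation(mesh, spec)
    changed = out.conductivity != mesh.conductivity
    assert changed.any()
    assert out.conductivity.max() <= 0.303 + 1e-12
    # fully-inside elements carry exactly the +1% value
    d = np.linalg.norm(mesh.element_centroids - spec.center_mm, axis=1)
    full = d < 0.08
    if full.any():
        assert np.allclose(out.conductivity[full], 0.303)


def test_zero_fraction_leaves_mesh_unchanged(small_forward):
    mesh = small_forward["mesh"]
    spec = PerturbationSpec(np.array([1.2, 1.2, 0.6]), 0.5, 0.0)
    out = apply_perturbation(mesh, spec)
    assert np.array_equal(out.conductivity, mesh.conductivity)


def test_tiny_sphere_fallback_flagged():
    mesh = build_slab_mesh((2, 2, 2), 1.0)   # elements far larger than sphere
    spec = PerturbationSpec(np.array([0.9, 0.2, 0.9]), 0.05, 0.01)
    with pytest.warns(UserWarning):
        out = apply_perturbation(mesh, spec)
    assert (out.conductivity != mesh.conductivity).sum() >= 1


def test_sphere_outside_mesh_rejected(small_forward):
    with pytest.raises(ValueError):
        apply_perturbation(small_forward["mesh"],
                           PerturbationSpec(np.array([50.0, 0, 0])))


def test_zero_perturbation_zero_noise_zero_data(small_forward):
    spec = PerturbationSpec(np.array([1.2, 1.2, 0.6]), 0.5, 0.0)
    d = simulate_measurement(small_forward["model"], spec,
                             small_forward["protocol"], 0.0, seed=0)
    assert np.allclose(d, 0.0, atol=1e-15)


def test_fixed_seed_bit_identical(small_forward):
    spec = PerturbationSpec(np.array([1.2, 1.2, 0.6]))
    d1 = simulate_measurement(small_forward["model"], spec,
                              small_forward["protocol"], 0.5, seed=42)
    d2 = simulate_measurement(small_forward["model"], spec,
                              small_forward["protocol"], 0.5, seed=42)
    assert np.array_equal(d1, d2)


def test_negative_noise_rejected(small_forward):
    with pytest.raises(ValueError):
        simulate_measurement(small_forward["model"],
                             PerturbationSpec(np.array([1.2, 1.2, 0.6])),
                             small_forward["protocol"], -1.0)


def test_localization_of_rasterized_truth(small_forward):
    grid = small_forward["grid"]
    img = np.zeros(grid.n_voxels)
    vox = grid.point_to_voxel(np.array([[1.2, 1.2, 0.6]]))[0]
    img[vox] = 1.0
    spec = PerturbationSpec(grid.voxel_centers[vox])
    res = localization_error(spec, img, grid)
    assert res.error_mm <= grid.pitch / 2


def test_shift_by_one_voxel_gives_pitch_error(small_forward):
    grid = small_forward["grid"]
    vox = grid.point_to_voxel(np.array([[1.2, 1.2, 0.6]]))[0]
    img = np.zeros(grid.n_voxels)
    img[vox] = 1.0
    shifted = PerturbationSpec(grid.voxel_centers[vox]
                               + np.array([grid.pitch, 0, 0]))
    res = localization_error(shifted, img, grid)
    assert res.error_mm == pytest.approx(grid.pitch, rel=1e-9)


def test_all_zero_image_sentinel(small_forward):
    grid = small_forward["grid"]
    res = localization_error(PerturbationSpec(np.array([1.2, 1.2, 0.6])),
                             np.zeros(grid.n_voxels), grid)
    assert np.isnan(res.error_mm)


def test_error_invariant_under_rigid_translation():
    """Translating the whole setup (mesh, electrodes, grid, sphere) leaves
    the localization error unchanged."""
    from neuroeit import ForwardModel, InjectionProtocol, compute_jacobian
    from neuroeit.electrodes import ElectrodeArray
    from neuroeit.reconstruction import TikhonovSolver

    # electrode sites fixed by coordinates relative to the mesh, so the
    # translated setup is exactly equivalent (no data-dependent snapping)
    sites = np.array([[0.4, 0.4, 0], [1.2, 0.4, 0], [2.0, 0.4, 0],
                      [0.4, 2.0, 0], [1.2, 2.0, 0], [2.0, 2.0, 0]])

    def run(shift):
        mesh = build_slab_mesh((2.4, 2.4, 1.2), 0.4)
        mesh.nodes = mesh.nodes + shift
        mesh._cache.clear()
        nodes = [int(np.argmin(np.linalg.norm(mesh.nodes - (p + shift),
                                              axis=1))) for p in sites]
        array = ElectrodeArray(mesh.nodes[nodes], nodes, 0.4, 0.8)
        model = ForwardModel(mesh, array, ground_node=0)
        protocol = InjectionProtocol([(0, 5), (1, 4), (2, 3), (0, 4)])
        grid = InverseGrid.covering(mesh, 0.4)
        jac = compute_jacobian(model, protocol, grid)
        spec = PerturbationSpec(np.array([1.2, 1.2, 0.6]) + shift)
        d = simulate_measurement(model, spec, protocol, 0.0, seed=0)
        solver = TikhonovSolver(jac.percent_scaled(), None)
        img = solver.solve(d, solver.s[0] ** 2 * 1e-5)
        return localization_error(spec, img, grid).error_mm

    e0 = run(np.zeros(3))
    e1 = run(np.array([5.0, -3.0, 2.0]))
    assert e1 == pytest.approx(e0, abs=1e-6)


def test_error_decreases_with_noise(slab_study):
    """Median error over seeds is non-increasing as noise SD -> 0 on a
    fixed central perturbation under the full planar array."""
    from neuroeit.reconstruction import TikhonovSolver
    spec = PerturbationSpec(np.array([3.5, 2.5, 0.6]))
    dv = simulate_measurement(slab_study.model, spec, slab_study.protocol,
                              noise_sd_uv=0.0, seed=0)
    solver = TikhonovSolver(slab_study.jacobian.percent_scaled(), None)
    lam = solver.s[0] ** 2 * 1e-4
    rng = np.random.default_rng(2024)
    medians = []
    for noise_uv in (5.0, 0.5, 0.0):
        errs = []
        for _ in range(9):
            d = dv + rng.normal(0, noise_uv * 1e-6, dv.shape)
            img = solver.solve(d, lam)
            errs.append(localization_error(spec, img,
                                           slab_study.grid).error_mm)
        medians.append(np.median(errs))
    assert medians[0] >= medians[1] >= medians[2] - 1e-9


def test_deep_errors_exceed_shallow_under_planar_array(slab_study):
    """Noisy localization degrades away from the array plane."""
    locs = np.array([[x, y, z] for x in (2.5, 3.5, 4.5) for y in (2.0, 3.0)
                     for z in (0.4, 1.6)])
    labels = np.zeros(len(locs), dtype=int)
    df = error_map(slab_study.model, slab_study.protocol, slab_study.grid,
                   locs, labels, jac=slab_study.jacobian,
                   noise_sd_uv=0.5, seed=11)
    shallow = df[df.z == 0.4]["error_mm"].median()
    deep = df[df.z == 1.6]["error_mm"].median()
    assert deep >= shallow


def test_single_location_grid(small_forward):
    df = error_map(small_forward["model"], small_forward["protocol"],
                   small_forward["grid"], np.array([[1.2, 1.2, 0.6]]),
                   noise_sd_uv=0.0, seed=0, lam=1e-4)
    assert len(df) == 1


def test_empty_location_grid_rejected(small_forward):
    with pytest.raises(ValueError):
        error_map(small_forward["model"], small_forward["protocol"],
                  small_forward["grid"], np.empty((0, 3)))


def test_candidate_locations_inside_tissue():
    from neuroeit import build_brain_mesh
    mesh = build_brain_mesh(target_element_size=1.0)
    locs, labels = candidate_locations(mesh, step_mm=1.0, margin_mm=0.8,
                                       exclude_near_csf_mm=1.0,
                                       exclude_below_frac=0.2)
    assert len(locs) > 10
    lo, hi = mesh.bounding_box
    assert (locs[:, 2] < lo[2] + 0.8 * (hi[2] - lo[2])).all()
    from scipy.spatial import cKDTree
    csf = mesh.element_centroids[mesh.labels == 2]
    if len(csf):
        d, _ = cKDTree(csf).query(locs)
        assert (d > 1.0).all()
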