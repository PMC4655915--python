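"""Shared fixtures.

Expensive geometry (full slab study, its Jacobian, one processed
end-to-end recording) is session-scoped; small meshes for forward-model
unit tests are built fresh per module.
"""

import numpy as np
import pytest

from neuroeit import (ForwardModel, InverseGrid, SlabStudy, compute_jacobian,
                      build_slab_mesh, make_activity_phantom,
                      place_planar_array, process_recording,
                      simulate_recording, spiral_protocol)


@pytest.fixture(scope="session")
def slab_study():
    """Full experimental-scale slab study (7x5x2 mm, 30 electrodes)."""
    return SlabStudy()


@pytest.fixture(scope="session")
def slab_jacobian(slab_study):
    return slab_study.jacobian


@pytest.fixture(scope="session")
def default_phantom(slab_study):
    return make_activity_phantom(slab_study.mesh)


@pytest.fixture(scope="session")
def end_to_end_run(slab_study, default_phantom):
    """One full simulate->demodulate->QC->reconstruct recording (seed 1)."""
    raws = simulate_recording(slab_study, default_phantom, seed=1)
    return process_recording(slab_study, raws,
                             roi_center=default_phantom.center_xy)


@pytest.fixture(scope="session")
def small_forward():
    """Small slab + 8-electrode array + forward model (<2k elements)."""
    mesh = build_slab_mesh((2.4, 2.4, 1.2), 0.4)
    array = place_planar_array(mesh, 8, 0.8, 0.4)
    model = ForwardModel(mesh, array)
    protocol = spiral_protocol(array, 8)
    grid = InverseGrid.covering(mesh, 0.4)
    return {"mesh": mesh, "array": array, "model": model,
            "protocol": protocol, "grid": grid,
            "jacobian": compute_jacobian(model, protocol, grid)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
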