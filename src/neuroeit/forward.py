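"""EIT forward problem: P1 tetrahedral FEM, lead fields and sensitivity.

The quasi-static forward problem is the generalized Laplace equation
``div(sigma grad u) = 0`` with point current sources at electrode nodes and
one boundary node designated ground (Dirichlet, u = 0); all boundary
voltages are reported relative to that ground.  Lead fields — the potential
produced by a unit current driven from each electrode to ground — are the
workhorse: every injection-pair solution is a superposition of two lead
fields, and the sensitivity (Jacobian) of a measurement to a conductivity
change follows from the adjoint identity

    dV(meas) = - integral_voxel  grad(u_inj) . grad(u_meas_lead)  dV

so one linear solve per electrode suffices for the whole sensitivity
matrix, instead of one solve per (pair, voxel).

Units: node coordinates mm, conductivity S/m, currents A, potentials V.
The mm/m mismatch contributes a single factor 1e-3 in assembly and in the
sensitivity integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .electrodes import ElectrodeArray
from .mesh import Mesh

_MM = 1e-3  # converts mm-unit FEM integrals to SI


def _basis_gradients(mesh: Mesh) -> np.ndarray:
    """Gradients of the four P1 basis functions per element, (m, 4, 3), 1/mm."""
    p = mesh.nodes[mesh.elements]
    J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=1)
    Jinv = np.linalg.inv(J)                     # (m, 3, 3)
    g123 = np.transpose(Jinv, (0, 2, 1))        # rows = grad lambda_1..3
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1)


def assemble_stiffness(mesh: Mesh) -> sp.csc_matrix:
    """Global FEM stiffness matrix, SI units (entries in siemens)."""
    g = _basis_gradients(mesh)                  # (m, 4, 3)
    vol = mesh.element_volumes                  # mm^3
    coef = (mesh.conductivity * vol * _MM)      # S * mm -> S after 1e-3
    ke = np.einsum("e,eik,ejk->eij", coef, g, g)
    rows = np.repeat(mesh.elements, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.elements, (1, 4)).reshape(-1)
    K = sp.coo_matrix((ke.reshape(-1), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return K.tocsc()


@dataclass
class ForwardSolution:
    """Potentials and boundary voltages for one current injection."""

    potentials: np.ndarray          # (n_nodes,) V
    electrode_voltages: np.ndarray  # (n_electrodes,) V, relative to ground
    pair: tuple[int, int]
    current_a: float                # injected current, A
    ground_current_a: float         # net current through the ground node

    def measured(self, exclude_injecting: bool = True) -> np.ndarray:
        """Voltages at non-injecting electrodes (the recorded channels)."""
        if not exclude_injecting:
            return self.electrode_voltages
        keep = np.ones(len(self.electrode_voltages), dtype=bool)
        keep[list(self.pair)] = False
        return self.electrode_voltages[keep]


class ForwardModel:
    """Factorized FEM system for a mesh + electrode array.

    Parameters
    ----------
    mesh, array
        Geometry; electrodes are point contacts at mesh nodes.
    ground_node : int, optional
        Node held at zero potential and absorbing return current (the
        distant ground electrode).  Default: the boundary node farthest
        from the array centre.
    """

    def __init__(self, mesh: Mesh, array: ElectrodeArray, ground_node: int | None = None):
        self.mesh = mesh
        self.array = array
        if ground_node is None:
            bn = mesh.boundary_nodes()
            bn = bn[~np.isin(bn, array.node_indices)]
            d = np.linalg.norm(mesh.nodes[bn] - array.center, axis=1)
            ground_node = int(bn[np.argmax(d)])
        if ground_node in array.node_indices:
            raise ValueError("ground node coincides with an electrode")
        self.ground_node = int(ground_node)

        self._K = assemble_stiffness(mesh)
        Kd = self._K.tolil()
        Kd[self.ground_node, :] = 0.0
        Kd[:, self.ground_node] = 0.0
        Kd[self.ground_node, self.ground_node] = 1.0
        try:
            self._lu = splu(Kd.tocsc())
        except RuntimeError as exc:  # pragma: no cover - singular mesh
            raise RuntimeError(f"singular forward system (disconnected mesh?): {exc}")
        self._grad = _basis_gradients(mesh)
        self._leads: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def lead_fields(self) -> np.ndarray:
        """(n_electrodes, n_nodes) potentials for 1 A electrode->ground."""
        if self._leads is None:
            rhs = np.zeros((self.mesh.n_nodes, self.array.n_electrodes))
            rhs[self.array.node_indices, np.arange(self.array.n_electrodes)] = 1.0
            rhs[self.ground_node, :] = 0.0
            self._leads = self._lu.solve(rhs).T
        return self._leads

    def solve(self, pair: tuple[int, int], current_ua: float) -> ForwardSolution:
        """Potential field for ``current_ua`` injected source -> sink."""
        a, b = pair
        n = self.array.n_electrodes
        if not (0 <= a < n and 0 <= b < n) or a == b:
            raise ValueError(f"invalid injection pair {pair} for {n} electrodes")
        cur = current_ua * 1e-6
        u = cur * (self.lead_fields[a] - self.lead_fields[b])
        ground_i = float((self._K[self.ground_node, :] @ u).item())
        return ForwardSolution(
            potentials=u,
            electrode_voltages=u[self.array.node_indices],
            pair=(a, b),
            current_a=cur,
            ground_current_a=ground_i,
        )

    def transfer_impedance(self, inj_pair, meas_pair) -> float:
        """V(meas pair) per unit current on the injection pair, ohms."""
        sol = self.solve(inj_pair, 1e6)  # 1 A
        return float(sol.electrode_voltages[meas_pair[0]]
                     - sol.electrode_voltages[meas_pair[1]])

    def element_gradients(self, u: np.ndarray) -> np.ndarray:
        """Piecewise-constant gradient of a nodal field, (m, 3), V/mm."""
        return np.einsum("eik,ei->ek", self._grad, u[self.mesh.elements])

    # ------------------------------------------------------------------
    def boundary_voltage_changes(self, perturbed: Mesh, protocol) -> np.ndarray:
        """Exact (re-solved) voltage differences perturbed - baseline.

        Returns a flat vector over protocol channels (pair-major, then
        measurement electrodes in index order excluding the pair).  Used
        both by the localization simulations and as the oracle for the
        linearized Jacobian.
        """
        pm = ForwardModel(perturbed, self.array, self.ground_node)
        out = []
        for k, (a, b) in enumerate(protocol.pairs):
            cur = protocol.amplitude_ua
            v0 = self.solve((a, b), cur).measured()
            v1 = pm.solve((a, b), cur).measured()
            out.append(v1 - v0)
        return np.concatenate(out)


def solve_forward(mesh: Mesh, array: ElectrodeArray, pair, current_ua: float,
                  ground_node: int | None = None) -> ForwardSolution:
    """One-shot forward solve (see :class:`ForwardModel` for batch use)."""
    return ForwardModel(mesh, array, ground_node).solve(tuple(pair), current_ua)


# ----------------------------------------------------------------------
# distributed (plate) injection — used for analytic benchmarks where the
# closed form assumes uniform current density over a whole face

def face_nodes(mesh: Mesh, axis: int, value: float, tol: float = 1e-6) -> np.ndarray:
    """Mesh nodes lying on the plane ``coordinate[axis] == value``."""
    sel = np.flatnonzero(np.abs(mesh.nodes[:, axis] - value) < tol)
    if sel.size == 0:
        raise ValueError(f"no nodes on plane axis {axis} = {value}")
    return sel


def nodal_face_weights(mesh: Mesh, nodes: np.ndarray) -> np.ndarray:
    """Area weights of boundary-face nodes (1/3 of each adjacent triangle)."""
    faces, _ = mesh.boundary_faces()
    node_set = np.zeros(mesh.n_nodes, dtype=bool)
    node_set[nodes] = True
    on = node_set[faces].all(axis=1)
    w = np.zeros(mesh.n_nodes)
    p = mesh.nodes[faces[on]]
    area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    for k in range(3):
        np.add.at(w, faces[on][:, k], area / 3.0)
    out = w[nodes]
    return out / out.sum()


def solve_nodal_currents(mesh: Mesh, rhs_a: np.ndarray,
                         ground_node: int = 0) -> np.ndarray:
    """Solve the FEM system for an arbitrary balanced nodal current vector."""
    K = assemble_stiffness(mesh).tolil()
    K[ground_node, :] = 0.0
    K[:, ground_node] = 0.0
    K[ground_node, ground_node] = 1.0
    rhs = rhs_a.copy()
    rhs[ground_node] = 0.0
    return splu(K.tocsc()).solve(rhs)


def bar_resistance(mesh: Mesh, axis: int = 0) -> float:
    """End-to-end resistance (ohms) with plate electrodes on both end faces.

    Unit current is injected with area-uniform density on one face and
    extracted on the opposite face; the resistance is the area-weighted
    mean potential difference.  For a uniform bar this converges to the
    analytic R = L / (sigma A).
    """
    lo, hi = mesh.bounding_box
    na = face_nodes(mesh, axis, lo[axis])
    nb = face_nodes(mesh, axis, hi[axis])
    wa = nodal_face_weights(mesh, na)
    wb = nodal_face_weights(mesh, nb)
    rhs = np.zeros(mesh.n_nodes)
    rhs[na] += wa
    rhs[nb] -= wb
    u = solve_nodal_currents(mesh, rhs, ground_node=int(nb[0]))
    return float(wa @ u[na] - wb @ u[nb])


# ----------------------------------------------------------------------
# inverse grid and sensitivity matrix

@dataclass
class InverseGrid:
    """Regular hexahedral voxelization used as the reconstruction basis."""

    origin: np.ndarray      # (3,) mm, corner of voxel (0,0,0)
    pitch: float            # mm, isotropic
    shape: tuple[int, int, int]

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.shape = tuple(int(s) for s in self.shape)

    @classmethod
    def covering(cls, mesh: Mesh, pitch: float) -> "InverseGrid":
        lo, hi = mesh.bounding_box
        shape = np.maximum(1, np.ceil((hi - lo) / pitch - 1e-9).astype(int))
        return cls(lo, pitch, tuple(shape))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_centers(self) -> np.ndarray:
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + (idx + 0.5) * self.pitch

    def point_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Flat voxel index per point, -1 outside the grid."""
        q = np.floor((np.atleast_2d(points) - self.origin) / self.pitch).astype(int)
        ok = ((q >= 0) & (q < np.array(self.shape))).all(axis=1)
        flat = np.ravel_multi_index(np.clip(q, 0, np.array(self.shape) - 1).T, self.shape)
        return np.where(ok, flat, -1)

    @property
    def affine(self) -> np.ndarray:
        """Voxel-index -> mm affine (for NIfTI export)."""
        A = np.eye(4)
        A[:3, :3] *= self.pitch
        A[:3, 3] = self.origin + 0.5 * self.pitch
        return A

    def unflatten(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values).reshape(self.shape)


@dataclass
class SensitivityMatrix:
    """Linearized map from voxel conductivity changes to channel voltages.

    ``matrix[r, v]`` is dV_r / d(sigma_v) in volts per (S/m), at the
    protocol's injection current; rows are (injection pair, measurement
    electrode) channels in pair-major order, columns inverse-grid voxels.
    ``voxel_sigma`` is the volume-weighted background conductivity per
    voxel (0 where no element intersects; those columns are zero and
    listed in ``empty_voxels``).
    """

    matrix: np.ndarray
    channels: np.ndarray        # structured: pair_index, source, sink, electrode
    grid: InverseGrid
    voxel_sigma: np.ndarray
    voxel_volume: np.ndarray    # mm^3 of mesh actually inside each voxel
    empty_voxels: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.empty_voxels is None:
            self.empty_voxels = np.flatnonzero(self.voxel_volume <= 0)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def percent_scaled(self) -> np.ndarray:
        """Matrix mapping voxel dsigma in % of background to volts."""
        return self.matrix * (self.voxel_sigma / 100.0)[None, :]


CHANNEL_DTYPE = np.dtype([("pair", np.int64), ("source", np.int64),
                          ("sink", np.int64), ("electrode", np.int64)])


def protocol_channels(protocol, n_electrodes: int) -> np.ndarray:
    """Channel table: every non-injecting electrode for every pair."""
    rows = []
    for k, (a, b) in enumerate(protocol.pairs):
        for m in range(n_electrodes):
            if m != a and m != b:
                rows.append((k, a, b, m))
    return np.array(rows, dtype=CHANNEL_DTYPE)


def compute_jacobian(model: ForwardModel, protocol, grid: InverseGrid) -> SensitivityMatrix:
    """Adjoint-field sensitivity matrix on the inverse grid.

    One lead-field solve per electrode; element-level sensitivities are
    aggregated to voxels by centroid membership, weighted by element
    volume.  Entries are exact derivatives of the FEM model (verified
    against direct-perturbation re-solves in the test-suite).
    """
    mesh = model.mesh
    leads = model.lead_fields
    n_el = model.array.n_electrodes
    # per-electrode element gradients of the lead fields
    G = np.stack([model.element_gradients(leads[e]) for e in range(n_el)])  # (n_el, m, 3)

    vox = grid.point_to_voxel(mesh.element_centroids)
    inside = vox >= 0
    vol = mesh.element_volumes
    nv = grid.n_voxels
    P = sp.csr_matrix((vol[inside], (vox[inside], np.flatnonzero(inside))),
                      shape=(nv, mesh.n_elements))
    voxel_volume = np.asarray(P.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        voxel_sigma = np.where(
            voxel_volume > 0,
            np.asarray(P @ mesh.conductivity).ravel() / np.maximum(voxel_volume, 1e-300),
            0.0)

    channels = protocol_channels(protocol, n_el)
    cur = protocol.amplitude_ua * 1e-6
    blocks = []
    for k, (a, b) in enumerate(protocol.pairs):
        gab = G[a] - G[b]                               # (m, 3)
        meas = channels["electrode"][channels["pair"] == k]
        dots = np.einsum("nmk,mk->nm", G[meas], gab)    # (n_meas, m)
        block = -(_MM * cur) * (P @ dots.T).T           # (n_meas, nv)
        blocks.append(block)
    J = np.vstack(blocks)
    return SensitivityMatrix(J, channels, grid, voxel_sigma, voxel_volume)
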