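"""Epicortical electrode arrays and their placement on mesh surfaces.

The experimental array is 30 circular contacts, 0.6 mm in diameter, arranged
hexagonally at a 1.2 mm centre-to-centre pitch, covering 5 x 7 mm of cortex.
A point-electrode model is used: each contact is snapped to the nearest
surface node of the mesh and currents/voltages are applied/read at that
node.  The contact diameter is retained as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Mesh


@dataclass
class ElectrodeArray:
    """Electrode contacts attached to mesh surface nodes.

    Attributes
    ----------
    positions : (n, 3) float array, mm — snapped contact centres.
    node_indices : (n,) int array — mesh node of each contact.
    diameter : float, mm — contact diameter (metadata; point model).
    pitch : float, mm — nominal centre-to-centre distance.
    layout : str — descriptor, e.g. ``"hexagonal"``.
    max_snap_mm : float — largest displacement applied when snapping.
    """

    positions: np.ndarray
    node_indices: np.ndarray
    diameter: float
    pitch: float
    layout: str = "hexagonal"
    max_snap_mm: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.node_indices = np.asarray(self.node_indices, dtype=np.int64)
        if len(np.unique(self.node_indices)) != len(self.node_indices):
            raise ValueError("electrodes must occupy distinct mesh nodes")

    @property
    def n_electrodes(self) -> int:
        return len(self.node_indices)

    @property
    def center(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def min_separation(self) -> float:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        return float(dist.min())


def hexagonal_layout(n: int, pitch: float) -> np.ndarray:
    """(x, y) positions of ``n`` contacts on a hexagonal lattice, centred.

    Rows are offset by half a pitch and spaced ``pitch * sqrt(3)/2`` apart;
    the ``n`` lattice points closest to the origin of a compact block are
    kept, so the footprint is as round as the lattice allows.  Deterministic.
    """
    if n < 1:
        raise ValueError("need at least one electrode")
    # rectangular block of offset rows, slightly wider than tall (the
    # experimental 30-contact array is 6 columns x 5 rows over 7 x 5 mm)
    ncols = int(np.ceil(np.sqrt(n / (np.sqrt(3) / 2))))
    nrows = int(np.ceil(n / ncols))
    pts = []
    for r in range(nrows):
        for c in range(ncols):
            x = c * pitch + (0.5 * pitch if r % 2 else 0.0)
            y = r * pitch * np.sqrt(3) / 2
            pts.append((x, y))
    sel = np.array(pts[:n])
    return sel - sel.mean(axis=0)


def _snap_to_nodes(targets_xy: np.ndarray, cand_nodes: np.ndarray,
                   cand_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy unique assignment of layout points to candidate surface nodes.

    Distance is lateral (x, y) so the same routine drapes a layout over a
    curved surface (brain apex) or a flat one (slab top).
    """
    d = np.linalg.norm(cand_xyz[None, :, :2] - targets_xy[:, None, :], axis=-1)
    node_of = np.full(len(targets_xy), -1, dtype=np.int64)
    pos = np.zeros((len(targets_xy), 3))
    taken = np.zeros(d.shape[1], dtype=bool)
    max_snap = 0.0
    # assign in order of best available match to keep the worst snap small
    for _ in range(len(targets_xy)):
        dm = np.where(taken[None, :] | (node_of[:, None] >= 0), np.inf, d)
        i, j = np.unravel_index(np.argmin(dm), dm.shape)
        node_of[i] = cand_nodes[j]
        pos[i] = cand_xyz[j]
        taken[j] = True
        max_snap = max(max_snap, float(d[i, j]))
    return pos, node_of, max_snap


def place_planar_array(
    mesh: Mesh,
    n_electrodes: int,
    pitch: float,
    diameter: float,
    center_xy=None,
) -> ElectrodeArray:
    """Place a hexagonal array on the mesh's upper surface.

    Contacts are snapped to the nearest upper-surface node (point-electrode
    model); the maximum snap displacement is recorded on the returned array.
    Raises ``ValueError`` when the array footprint exceeds the surface.
    """
    if diameter > pitch:
        raise ValueError("contact diameter exceeds pitch: contacts overlap")
    surf = mesh.surface_nodes()
    surf_xyz = mesh.nodes[surf]
    lo, hi = surf_xyz[:, :2].min(axis=0), surf_xyz[:, :2].max(axis=0)
    if center_xy is None:
        center_xy = (lo + hi) / 2
    layout = hexagonal_layout(n_electrodes, pitch) + np.asarray(center_xy)
    pad = 0.55 * pitch  # half a lattice step of slack for snapping
    if (layout.min(axis=0) < lo - pad).any() or (layout.max(axis=0) > hi + pad).any():
        raise ValueError(
            f"array footprint {layout.min(axis=0)}..{layout.max(axis=0)} "
            f"exceeds surface {lo}..{hi}")
    pos, nodes, max_snap = _snap_to_nodes(layout, surf, surf_xyz)
    return ElectrodeArray(pos, nodes, diameter, pitch, "hexagonal", max_snap)


def place_bilateral_arrays(
    mesh: Mesh,
    n_per_array: int,
    pitch: float,
    diameter: float,
    centers_y: tuple[float, float],
) -> ElectrodeArray:
    """Two hexagonal arrays draped over the two hemisphere apices.

    Returns a single combined :class:`ElectrodeArray` (electrodes
    ``0..n-1`` on the first hemisphere, ``n..2n-1`` on the second) so that
    protocols and Jacobians treat the union as one measurement system.
    """
    surf = mesh.surface_nodes()
    surf_xyz = mesh.nodes[surf]
    all_pos, all_nodes = [], []
    max_snap = 0.0
    for cy in centers_y:
        # restrict candidates to the hemisphere around this centre-line
        side = surf_xyz[:, 1] * np.sign(cy) > 0
        cand_nodes, cand_xyz = surf[side], surf_xyz[side]
        layout = hexagonal_layout(n_per_array, pitch) + np.array([0.0, cy])
        pos, nodes, snap = _snap_to_nodes(layout, cand_nodes, cand_xyz)
        all_pos.append(pos)
        all_nodes.append(nodes)
        max_snap = max(max_snap, snap)
    return ElectrodeArray(
        np.concatenate(all_pos), np.concatenate(all_nodes),
        diameter, pitch, "bilateral-hexagonal", max_snap)
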