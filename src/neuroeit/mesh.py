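"""Tetrahedral volume meshes for epicortical EIT geometry.

Coordinate convention (used throughout the package): right-handed axes in
millimetres with ``z`` the depth below the electrode-array surface, positive
downward, ``z = 0`` at the pial plane.  Conductivities are in S/m.

Two parametric geometries are provided: a rectangular cortical slab with a
flat top surface for planar-array placement, and a simplified two-hemisphere
brain (ellipsoidal gray shell, white core, CSF ventricle cavities) for
whole-brain localization simulations.  Both are produced by Kuhn subdivision
of a structured hexahedral grid, which yields a conforming tetrahedral mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# background tissue conductivities, S/m
GRAY_S_M = 0.3
WHITE_S_M = 0.15
CSF_S_M = 1.75

#: tissue label codes used by :func:`build_brain_mesh`
LABEL_GRAY, LABEL_WHITE, LABEL_CSF = 0, 1, 2

TISSUE_CONDUCTIVITY = {
    LABEL_GRAY: GRAY_S_M,
    LABEL_WHITE: WHITE_S_M,
    LABEL_CSF: CSF_S_M,
}


@dataclass
class Mesh:
    """Tetrahedral mesh with per-element tissue label and conductivity.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, mm
    elements : (n_elements, 4) int array
        Node indices; all elements positively oriented.
    labels : (n_elements,) int array
        Tissue label per element; labeled regions partition the element set.
    conductivity : (n_elements,) float array, S/m, strictly positive.
    """

    nodes: np.ndarray
    elements: np.ndarray
    labels: np.ndarray
    conductivity: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.conductivity = np.asarray(self.conductivity, dtype=float)
        if self.conductivity.min(initial=np.inf) <= 0:
            raise ValueError("conductivity must be positive everywhere")
        self._orient_positively()

    # ------------------------------------------------------------------
    def _signed_volumes(self) -> np.ndarray:
        p = self.nodes[self.elements]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def _orient_positively(self) -> None:
        vol = self._signed_volumes()
        flip = vol < 0
        if flip.any():
            self.elements[flip, 2], self.elements[flip, 3] = (
                self.elements[flip, 3].copy(),
                self.elements[flip, 2].copy(),
            )
        self._cache.clear()

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_volumes(self) -> np.ndarray:
        """Element volumes in mm^3 (positive)."""
        if "volumes" not in self._cache:
            self._cache["volumes"] = self._signed_volumes()
        return self._cache["volumes"]

    @property
    def element_centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.nodes[self.elements].mean(axis=1)
        return self._cache["centroids"]

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.nodes.min(axis=0), self.nodes.max(axis=0)

    # ------------------------------------------------------------------
    def boundary_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary triangles and the element each belongs to.

        Returns ``(faces, owners)`` where ``faces`` is (n_bf, 3) node
        indices (unordered) and ``owners`` the owning element index.
        """
        if "boundary" in self._cache:
            return self._cache["boundary"]
        # the four faces of a tet, as local index triples
        local = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
        faces = self.elements[:, local].reshape(-1, 3)
        owners = np.repeat(np.arange(self.n_elements), 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T[::-1])
        key_sorted = key[order]
        # faces appearing exactly once are boundary faces
        new = np.ones(len(key_sorted), dtype=bool)
        dup_next = (key_sorted[1:] == key_sorted[:-1]).all(axis=1)
        new[1:] &= ~dup_next
        new[:-1] &= ~dup_next
        sel = order[new]
        out = (faces[sel], owners[sel])
        self._cache["boundary"] = out
        return out

    def boundary_nodes(self) -> np.ndarray:
        faces, _ = self.boundary_faces()
        return np.unique(faces)

    def surface_nodes(self, direction=(0.0, 0.0, -1.0), min_cos: float = 0.5) -> np.ndarray:
        """Nodes of boundary faces whose outward normal points along ``direction``.

        With the package's depth-down convention the top (pial) surface has
        outward normal (0, 0, -1).
        """
        faces, owners = self.boundary_faces()
        p = self.nodes[faces]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        # orient outward: away from the owning element centroid
        to_face = p.mean(axis=1) - self.element_centroids[owners]
        sign = np.sign(np.einsum("ij,ij->i", n, to_face))
        n *= sign[:, None]
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        keep = n @ d > min_cos
        return np.unique(faces[keep])

    # ------------------------------------------------------------------
    def with_conductivity(self, conductivity: np.ndarray) -> "Mesh":
        """Copy of the mesh with a replaced per-element conductivity."""
        return Mesh(self.nodes, self.elements.copy(), self.labels.copy(),
                    np.asarray(conductivity, dtype=float).copy())


# ----------------------------------------------------------------------
# structured-grid tetrahedralization

def _kuhn_connectivity() -> np.ndarray:
    """Six-tet Kuhn split of the unit cube, local corner codes i+2j+4k.

    Every tet is a monotone path 000 -> 111, so all cells share the same
    main diagonal and the subdivision is conforming across cells.
    """
    from itertools import permutations

    unit = {0: 1, 1: 2, 2: 4}  # axis -> corner-code increment
    tets = []
    for perm in sorted(permutations(range(3))):
        code = 0
        path = [0]
        for ax in perm:
            code += unit[ax]
            path.append(code)
        tets.append(path)
    return np.array(tets, dtype=np.int64)


_KUHN = _kuhn_connectivity()


def _structured_tets(nx: int, ny: int, nz: int) -> np.ndarray:
    """Tet connectivity of an (nx, ny, nz)-cell structured grid."""

    def nid(i, j, k):
        return (k * (ny + 1) + j) * (nx + 1) + i

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    base = nid(i, j, k).ravel()
    # corner-code offsets in node numbering
    off = np.array([nid(c & 1, (c >> 1) & 1, (c >> 2) & 1) for c in range(8)])
    cells = base[:, None] + off[None, :]          # (n_cells, 8)
    tets = cells[:, _KUHN.reshape(-1)].reshape(-1, 4)
    return tets


def _grid_nodes(origin, spacing, nx, ny, nz) -> np.ndarray:
    xs = origin[0] + spacing[0] * np.arange(nx + 1)
    ys = origin[1] + spacing[1] * np.arange(ny + 1)
    zs = origin[2] + spacing[2] * np.arange(nz + 1)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def build_slab_mesh(
    extent,
    target_element_size: float = 0.2,
    conductivity: float = GRAY_S_M,
    labeler=None,
) -> Mesh:
    """Rectangular cortical-slab mesh with a flat top surface at z = 0.

    Parameters
    ----------
    extent : (3,) floats, mm
        Slab size along (x, y, depth); e.g. ``(7, 5, 2)`` for the 70 mm^3
        imaging volume under a 7 x 5 mm array.
    target_element_size : float, mm
        Requested edge length of the structured cells.
    conductivity : float, S/m
        Uniform background conductivity (gray matter by default).
    labeler : callable, optional
        ``labeler(centroids) -> labels`` for multi-region slabs; labels map
        to conductivity through :data:`TISSUE_CONDUCTIVITY` only if the
        caller replaces the conductivity afterwards — here labels are
        bookkeeping only.
    """
    extent = np.asarray(extent, dtype=float)
    if extent.shape != (3,) or (extent <= 0).any():
        raise ValueError(f"slab extent must be three positive lengths, got {extent}")
    if target_element_size <= 0:
        raise ValueError("target_element_size must be positive")
    ncell = np.maximum(1, np.round(extent / target_element_size).astype(int))
    spacing = extent / ncell
    nodes = _grid_nodes((0.0, 0.0, 0.0), spacing, *ncell)
    tets = _structured_tets(*ncell)
    labels = np.zeros(len(tets), dtype=np.int64)
    mesh = Mesh(nodes, tets, labels, np.full(len(tets), conductivity))
    if labeler is not None:
        mesh.labels = np.asarray(labeler(mesh.element_centroids), dtype=np.int64)
    return mesh


def _inside_ellipsoid(points, center, radii) -> np.ndarray:
    q = (points - np.asarray(center)) / np.asarray(radii)
    return (q ** 2).sum(axis=1) <= 1.0


def build_brain_mesh(
    hemisphere_radii=(6.0, 4.5, 4.0),
    hemisphere_offset: float = 2.2,
    gray_thickness: float = 1.5,
    ventricle_radii=(1.2, 0.8, 0.8),
    ventricle_depth_frac: float = 0.55,
    target_element_size: float = 0.5,
) -> Mesh:
    """Simplified two-hemisphere brain: gray shell, white core, CSF ventricles.

    Each hemisphere is an ellipsoid with semi-axes ``hemisphere_radii``
    (x: rostro-caudal, y: medio-lateral, z: depth), centred at
    ``y = +-hemisphere_offset``, apex at z = 0.  The white core is the
    ellipsoid shrunk inward by ``gray_thickness``; a CSF ventricle ellipsoid
    sits inside each white core at fractional depth ``ventricle_depth_frac``.
    Conductivities: gray 0.3, white 0.15, CSF 1.75 S/m.

    Raises ``ValueError`` if the shells overlap improperly (gray shell
    thicker than the smallest semi-axis, or ventricle not inside the core).
    """
    radii = np.asarray(hemisphere_radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("hemisphere radii must be positive")
    core = radii - gray_thickness
    if gray_thickness < 0 or (core <= 0).any():
        raise ValueError("gray shell overlaps the hemisphere centre: "
                         f"thickness {gray_thickness} vs radii {radii}")
    vent = np.asarray(ventricle_radii, dtype=float)
    if (vent < 0).any():
        raise ValueError("ventricle radii must be non-negative")
    if (vent >= core).any():
        raise ValueError("ventricle shell overlaps the white core")

    centers = np.array([
        [0.0, +hemisphere_offset, radii[2]],
        [0.0, -hemisphere_offset, radii[2]],
    ])
    lo = np.array([-radii[0], -hemisphere_offset - radii[1], 0.0])
    hi = np.array([+radii[0], +hemisphere_offset + radii[1], 2 * radii[2]])
    extent = hi - lo
    ncell = np.maximum(1, np.round(extent / target_element_size).astype(int))
    spacing = extent / ncell
    nodes = _grid_nodes(lo, spacing, *ncell)
    tets = _structured_tets(*ncell)
    cent = nodes[tets].mean(axis=1)

    inside = np.zeros(len(tets), dtype=bool)
    in_core = np.zeros(len(tets), dtype=bool)
    in_vent = np.zeros(len(tets), dtype=bool)
    for c in centers:
        inside |= _inside_ellipsoid(cent, c, radii)
        in_core |= _inside_ellipsoid(cent, c, core)
        if (vent > 0).all():
            vc = np.array([c[0], c[1], ventricle_depth_frac * 2 * radii[2]])
            in_vent |= _inside_ellipsoid(cent, vc, vent) & _inside_ellipsoid(vc[None, :], c, core)[0]

    keep = np.flatnonzero(inside)
    if keep.size == 0:
        raise ValueError("brain geometry produced an empty mesh")
    tets = tets[keep]
    labels = np.full(len(tets), LABEL_GRAY, dtype=np.int64)
    labels[in_core[keep]] = LABEL_WHITE
    labels[in_vent[keep] & in_core[keep]] = LABEL_CSF

    # drop unused nodes, renumber
    used, inv = np.unique(tets, return_inverse=True)
    tets = inv.reshape(tets.shape)
    nodes = nodes[used]
    cond = np.array([TISSUE_CONDUCTIVITY[l] for l in labels])
    mesh = Mesh(nodes, tets, labels, cond)
    _drop_disconnected(mesh)
    return mesh


def _drop_disconnected(mesh: Mesh) -> None:
    """Keep only the largest node-connected element component (in place)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    e = mesh.elements
    n = mesh.n_nodes
    # graph on nodes through element edges (6 edges per tet)
    pairs = np.concatenate([e[:, [0, 1]], e[:, [0, 2]], e[:, [0, 3]],
                            e[:, [1, 2]], e[:, [1, 3]], e[:, [2, 3]]])
    g = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    ncomp, comp = connected_components(g + g.T, directed=False)
    if ncomp == 1:
        return
    main = np.bincount(comp).argmax()
    keep = comp[e[:, 0]] == main
    mesh.elements = e[keep]
    mesh.labels = mesh.labels[keep]
    mesh.conductivity = mesh.conductivity[keep]
    used, inv = np.unique(mesh.elements, return_inverse=True)
    mesh.elements = inv.reshape(mesh.elements.shape)
    mesh.nodes = mesh.nodes[used]
    mesh._cache.clear()
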