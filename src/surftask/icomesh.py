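"""Icosphere hierarchy: vertices, faces, one-rings and inter-level pooling maps.

An icosphere at subdivision level ``L`` has ``10 * 4**L + 2`` vertices,
``20 * 4**L`` faces and ``30 * 4**L`` edges.  Vertex ordering is canonical:
the 12 base icosahedron vertices come first, and each subdivision appends the
midpoints of the parent mesh's edges in sorted ``(min_index, max_index)``
order.  As a consequence the level-``L`` vertices are an index prefix of the
level-``L+1`` vertices, which makes pooling between levels a plain index
restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SphereMesh", "PoolingMap", "build_icosphere", "pooling_map"]


@dataclass(frozen=True)
class SphereMesh:
    """Triangulated unit sphere obtained by recursive icosahedron subdivision.

    Attributes
    ----------
    level : int
        Subdivision level; 0 is the base icosahedron.
    vertices : (V, 3) float64 array
        Unit-length vertex positions.
    faces : (F, 3) int array
        Counter-clockwise triangles (as seen from outside the sphere).
    one_ring : tuple of int arrays
        Per-vertex neighbour indices, ordered counter-clockwise.
    coarser_count : int
        Number of leading vertices shared with the level-1 coarser mesh
        (0 at level 0).
    midpoint_parents : (V - coarser_count, 2) int array
        For each vertex introduced at this level, the two parent-edge
        endpoints it bisected.  Empty at level 0.
    """

    level: int
    vertices: np.ndarray
    faces: np.ndarray
    one_ring: tuple = field(repr=False)
    coarser_count: int = 0
    midpoint_parents: np.ndarray = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def n_edges(self) -> int:
        # V - E + F = 2 on the sphere
        return self.n_vertices + self.n_faces - 2

    def degrees(self) -> np.ndarray:
        return np.array([len(r) for r in self.one_ring])


@dataclass(frozen=True)
class PoolingMap:
    """Index maps between two consecutive icosphere levels.

    The coarse vertices are the index prefix of the fine vertices; every
    fine-only vertex is the midpoint of exactly one coarse edge and stores its
    two endpoint indices.
    """

    fine_level: int
    coarse_level: int
    n_coarse: int
    n_fine: int
    midpoint_parents: np.ndarray  # (n_fine - n_coarse, 2)


def _base_icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """12 vertices / 20 faces of a regular icosahedron in a fixed order."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _orient_faces_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip triangles whose normal points into the sphere."""
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    normals = np.cross(v1 - v0, v2 - v0)
    centers = (v0 + v1 + v2) / 3.0
    flip = np.einsum("ij,ij->i", normals, centers) < 0
    out = faces.copy()
    out[flip] = out[flip][:, [0, 2, 1]]
    return out


def _subdivide(vertices: np.ndarray, faces: np.ndarray):
    """One 4-to-1 subdivision; returns (verts, faces, midpoint_parents)."""
    edges = set()
    for a, b, c in faces:
        edges.add((min(a, b), max(a, b)))
        edges.add((min(b, c), max(b, c)))
        edges.add((min(a, c), max(a, c)))
    edge_list = sorted(edges)
    n_old = vertices.shape[0]
    mid_index = {e: n_old + i for i, e in enumerate(edge_list)}

    mids = (vertices[[e[0] for e in edge_list]] + vertices[[e[1] for e in edge_list]]) / 2.0
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    new_verts = np.vstack([vertices, mids])

    new_faces = np.empty((4 * faces.shape[0], 3), dtype=np.int64)
    for i, (a, b, c) in enumerate(faces):
        ab = mid_index[(min(a, b), max(a, b))]
        bc = mid_index[(min(b, c), max(b, c))]
        ca = mid_index[(min(a, c), max(a, c))]
        new_faces[4 * i: 4 * i + 4] = [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]

    parents = np.array(edge_list, dtype=np.int64)
    return new_verts, new_faces, parents


def _ordered_one_ring(vertices: np.ndarray, faces: np.ndarray) -> tuple:
    """Counter-clockwise (seen from outside) neighbour ring of every vertex."""
    V = vertices.shape[0]
    neighbors = [set() for _ in range(V)]
    for a, b, c in faces:
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))

    rings = []
    for v in range(V):
        p = vertices[v]
        ring = np.fromiter(neighbors[v], dtype=np.int64)
        # tangent-plane angles; orientation: e1 x e2 aligned with outward normal p
        ref = vertices[ring[0]] - p
        ref -= np.dot(ref, p) * p
        ref /= np.linalg.norm(ref)
        e2 = np.cross(p, ref)
        d = vertices[ring] - p
        d -= np.outer(d @ p, p)
        ang = np.arctan2(d @ e2, d @ ref)
        order = np.argsort(ang, kind="stable")
        ring = ring[order]
        # canonical start: smallest index first, rotation preserved
        start = int(np.argmin(ring))
        rings.append(np.roll(ring, -start))
    return tuple(rings)


def build_icosphere(level: int) -> SphereMesh:
    """Build the canonical icosphere at ``level``.

    Deterministic: repeated calls return bit-identical vertex arrays.  Levels
    above ~7 (163,842 vertices) are possible but slow and rarely useful here.

    Raises
    ------
    ValueError
        If ``level`` is negative.
    """
    if level < 0:
        raise ValueError(f"icosphere level must be >= 0, got {level}")
    verts, faces = _base_icosahedron()
    coarser_count = 0
    parents = np.empty((0, 2), dtype=np.int64)
    for _ in range(level):
        coarser_count = verts.shape[0]
        verts, faces, parents = _subdivide(verts, faces)
    faces = _orient_faces_outward(verts, faces)
    rings = _ordered_one_ring(verts, faces)
    return SphereMesh(
        level=level,
        vertices=verts,
        faces=faces,
        one_ring=rings,
        coarser_count=coarser_count,
        midpoint_parents=parents,
    )


def pooling_map(fine: SphereMesh, coarse: SphereMesh) -> PoolingMap:
    """Pooling map between consecutive levels (fine = coarse + 1).

    Raises
    ------
    ValueError
        If the two meshes are not consecutive levels of the hierarchy.
    """
    if fine.level != coarse.level + 1:
        raise ValueError(
            f"pooling_map needs fine.level == coarse.level + 1, "
            f"got {fine.level} and {coarse.level}"
        )
    if fine.coarser_count != coarse.n_vertices:
        raise ValueError("meshes are not from the same hierarchy")
    return PoolingMap(
        fine_level=fine.level,
        coarse_level=coarse.level,
        n_coarse=coarse.n_vertices,
        n_fine=fine.n_vertices,
        midpoint_parents=fine.midpoint_parents,
    )


def save_gifti_surface(mesh: SphereMesh, path) -> None:
    """Export vertices/faces as a GIFTI .surf.gii file."""
    import nibabel as nib

    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))
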