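"""Triangle-mesh container, STL input/output and adjacency.

Dental arch scans arrive as STL surface meshes in millimetres.  STL
duplicates every vertex once per facet, so loading merges coincident
vertices (tolerance 1e-6 mm) — without that step there is no edge
connectivity and none of the region-growing stages can run.  Non-manifold
edges (common on imperfect scans) are recorded but tolerated; traversals
treat them as boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import EmptyMeshError, MeshParseError

MERGE_TOL = 1e-6  # mm


@dataclass
class TriangleMesh:
    """A triangle surface mesh of one dental arch, coordinates in mm."""

    vertices: np.ndarray  # (V, 3) float64
    faces: np.ndarray     # (F, 3) int64
    _face_normals: np.ndarray | None = field(default=None, repr=False)
    _face_centroids: np.ndarray | None = field(default=None, repr=False)
    _face_areas: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if len(self.faces) == 0:
            raise EmptyMeshError("mesh has no faces")
        if self.faces.max() >= len(self.vertices) or self.faces.min() < 0:
            raise ValueError("face index out of range")

    # -- derived per-face quantities (lazy) --------------------------------

    def _cross(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        return np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])

    @property
    def face_normals(self) -> np.ndarray:
        if self._face_normals is None:
            c = self._cross()
            norm = np.linalg.norm(c, axis=1)
            norm[norm == 0] = 1.0
            self._face_normals = c / norm[:, None]
        return self._face_normals

    @property
    def face_areas(self) -> np.ndarray:
        if self._face_areas is None:
            self._face_areas = 0.5 * np.linalg.norm(self._cross(), axis=1)
        return self._face_areas

    @property
    def face_centroids(self) -> np.ndarray:
        if self._face_centroids is None:
            self._face_centroids = self.vertices[self.faces].mean(axis=1)
        return self._face_centroids

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Rigidly transformed copy: x -> R x + t."""
        r = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return TriangleMesh(self.vertices @ r.T + t, self.faces.copy())


def _clean(vertices: np.ndarray, faces: np.ndarray, tol: float = MERGE_TOL):
    """Merge duplicate vertices within ``tol`` and drop degenerate faces."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    vertices = vertices[first]
    faces = inverse[faces]
    # drop faces with repeated vertices or (near) zero area
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[ok]
    if len(faces):
        cross = np.cross(
            vertices[faces[:, 1]] - vertices[faces[:, 0]],
            vertices[faces[:, 2]] - vertices[faces[:, 0]],
        )
        faces = faces[np.linalg.norm(cross, axis=1) > 1e-14]
    return vertices, faces


def make_mesh(vertices, faces) -> TriangleMesh:
    """Build a cleaned TriangleMesh from raw arrays (merging duplicates)."""
    v, f = _clean(np.asarray(vertices, dtype=float), np.asarray(faces, dtype=np.int64))
    if len(f) == 0:
        raise EmptyMeshError("mesh has no non-degenerate faces")
    return TriangleMesh(v, f)


def load_stl(path) -> TriangleMesh:
    """Load a binary or ASCII STL file (units: mm)."""
    try:
        tm = trimesh.load(str(path), file_type="stl", force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise MeshParseError(f"cannot parse STL file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise EmptyMeshError(f"STL file {path} contains no triangles")
    return make_mesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def save_stl(mesh: TriangleMesh, path, ascii: bool = False) -> None:
    """Write a mesh to STL (binary by default)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path), file_type="stl_ascii" if ascii else "stl")


@dataclass
class AdjacencyIndex:
    """Edge/face/vertex adjacency of a TriangleMesh.

    ``edges`` is (E, 2) with sorted vertex pairs; ``edge_faces[e]`` lists the
    incident faces of edge ``e`` (more than two marks a non-manifold edge).
    ``face_edges`` is (F, 3).  Vertex neighbourhoods are stored in CSR form
    for fast ring propagation, with dict-free accessors.
    """

    edges: np.ndarray                  # (E, 2) int64
    edge_faces: list                   # E lists of face indices
    face_edges: np.ndarray             # (F, 3) int64
    face_neighbors: list               # F lists of neighbouring faces
    vert_nbr_indptr: np.ndarray        # CSR over vertices -> neighbour verts
    vert_nbr_indices: np.ndarray
    vert_face_indptr: np.ndarray       # CSR over vertices -> incident faces
    vert_face_indices: np.ndarray
    nonmanifold_edges: np.ndarray      # edge ids with >2 incident faces

    def vertex_neighbors(self, v: int) -> np.ndarray:
        return self.vert_nbr_indices[self.vert_nbr_indptr[v]:self.vert_nbr_indptr[v + 1]]

    def vertex_faces(self, v: int) -> np.ndarray:
        return self.vert_face_indices[self.vert_face_indptr[v]:self.vert_face_indptr[v + 1]]


def _csr(rows: np.ndarray, cols: np.ndarray, nrows: int):
    order = np.argsort(rows, kind="stable")
    rows, cols = rows[order], cols[order]
    indptr = np.zeros(nrows + 1, dtype=np.int64)
    np.add.at(indptr, rows + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, cols


def build_adjacency(mesh: TriangleMesh) -> AdjacencyIndex:
    """Build the complete adjacency index for a mesh."""
    faces = mesh.faces
    nf = len(faces)
    nv = len(mesh.vertices)

    raw = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    raw_face = np.tile(np.arange(nf, dtype=np.int64), 3)
    raw_sorted = np.sort(raw, axis=1)
    edges, inverse = np.unique(raw_sorted, axis=0, return_inverse=True)
    ne = len(edges)

    edge_faces: list = [[] for _ in range(ne)]
    for e, f in zip(inverse, raw_face):
        edge_faces[e].append(int(f))

    face_edges = np.empty((nf, 3), dtype=np.int64)
    face_edges[:, 0] = inverse[:nf]
    face_edges[:, 1] = inverse[nf:2 * nf]
    face_edges[:, 2] = inverse[2 * nf:]

    nonmanifold = np.array([e for e in range(ne) if len(edge_faces[e]) > 2], dtype=np.int64)
    nm = set(nonmanifold.tolist())

    face_neighbors: list = [[] for _ in range(nf)]
    for e in range(ne):
        fs = edge_faces[e]
        if len(fs) == 2 and e not in nm:
            a, b = fs
            face_neighbors[a].append(b)
            face_neighbors[b].append(a)

    # vertex -> neighbour vertices (undirected, deduplicated by unique edges)
    vr = np.concatenate([edges[:, 0], edges[:, 1]])
    vc = np.concatenate([edges[:, 1], edges[:, 0]])
    vn_indptr, vn_indices = _csr(vr, vc, nv)

    # vertex -> incident faces
    fr = faces.reshape(-1)
    fc = np.repeat(np.arange(nf, dtype=np.int64), 3)
    vf_indptr, vf_indices = _csr(fr, fc, nv)

    return AdjacencyIndex(
        edges=edges,
        edge_faces=edge_faces,
        face_edges=face_edges,
        face_neighbors=face_neighbors,
        vert_nbr_indptr=vn_indptr,
        vert_nbr_indices=vn_indices,
        vert_face_indptr=vf_indptr,
        vert_face_indices=vf_indices,
        nonmanifold_edges=nonmanifold,
    )


def surface_area(mesh: TriangleMesh, face_subset=None) -> float:
    """Total area (mm^2) of the given faces (all faces when ``None``)."""
    if face_subset is None:
        return float(mesh.face_areas.sum())
    idx = np.asarray(sorted(face_subset), dtype=np.int64)
    if len(idx) == 0:
        return 0.0
    if idx.min() < 0 or idx.max() >= len(mesh.faces):
        raise IndexError("face index out of bounds")
    return float(mesh.face_areas[idx].sum())
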