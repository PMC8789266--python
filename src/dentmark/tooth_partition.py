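"""Curvature-bounded tooth partitioning.

The junction between a tooth and the gingivae is a concave crease, so a
signed curvature field over mesh edges (dihedral deviation: positive on
convex folds, negative in creases) bounds each tooth.  Region growing from
every peak point floods faces breadth-first and refuses to cross edges of
considerable negative curvature; regions that instead hit a maximum-travel
cap never met a tooth boundary and are flagged "spilled" and discarded.
Overlapping regions (several cusps of one tooth) and disjoint regions at the
same position along the jawline (buccal/lingual halves) are merged, and the
surviving blobs are ordered along the quadratic jawline fitted to the
non-spilled peaks.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError
from .mesh_core import AdjacencyIndex, TriangleMesh
from .orientation import ArchFrame
from .peak_detection import PeakPoint

STOP_CURVATURE = -0.6        # rad; tooth-gingiva creases are sharper than this
MAX_TRAVEL_PERMANENT = 12.0  # mm; "a tooth's width" for permanent dentition
MAX_TRAVEL_DECIDUOUS = 9.0   # mm


@dataclass
class CurvatureField:
    """Per-edge signed curvature (radians of dihedral deviation)."""

    values: np.ndarray  # (E,) float64, aligned with AdjacencyIndex.edges


@dataclass
class Blob:
    """A candidate tooth: a connected set of faces grown from peak points."""

    faces: frozenset
    peaks: list  # list[PeakPoint]
    spilled: bool = False
    jaw_parameter: float | None = None  # arc length along the jawline, mm

    @property
    def highest_peak(self) -> PeakPoint:
        return max(self.peaks, key=lambda p: (p.height, -p.vertex_index))


@dataclass
class Jawline:
    """Quadratic arch curve AP = a T^2 + b T + c in frame coordinates (mm)."""

    a: float
    b: float
    c: float
    rms_residual: float = 0.0

    def ap(self, t):
        return self.a * np.asarray(t) ** 2 + self.b * np.asarray(t) + self.c

    def arc_length(self, t: float) -> float:
        """Arc length along the curve from T=0 to T=t (signed), mm."""
        # closed form of \int sqrt(1 + (2aT + b)^2) dT
        def antideriv(u):
            s = np.sqrt(1.0 + u * u)
            return 0.5 * (u * s + np.arcsinh(u))

        if abs(self.a) < 1e-12:
            return float(t * np.sqrt(1.0 + self.b * self.b))
        u1 = 2.0 * self.a * t + self.b
        u0 = self.b
        return float((antideriv(u1) - antideriv(u0)) / (2.0 * self.a))

    def tangent(self, t: float) -> np.ndarray:
        """Unit tangent (dT, dAP) of the curve at T=t."""
        v = np.array([1.0, 2.0 * self.a * t + self.b])
        return v / np.linalg.norm(v)

    def project_t(self, point: np.ndarray, span: float = 80.0) -> float:
        """T of the curve point closest to a horizontal point (T, AP).

        Projection (rather than reading off the point's own T) keeps the
        arch position of a buccally or lingually displaced tooth stable.
        """
        ts = np.arange(point[0] - span, point[0] + span, 0.25)
        d2 = (ts - point[0]) ** 2 + (self.ap(ts) - point[1]) ** 2
        k = int(np.argmin(d2))
        lo, hi = ts[max(k - 1, 0)], ts[min(k + 1, len(ts) - 1)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda t: (t - point[0]) ** 2 + (self.ap(t) - point[1]) ** 2,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        return float(res.x)


def edge_curvature(mesh: TriangleMesh, adj: AdjacencyIndex) -> CurvatureField:
    """Signed dihedral angle per edge: + convex fold, - concave crease, 0 flat.

    Boundary and non-manifold edges get 0 (region growing treats them as
    walls only when the curvature test says so; non-manifold edges already
    have no face adjacency).
    """
    normals = mesh.face_normals
    centroids = mesh.face_centroids
    values = np.zeros(len(adj.edges))
    for e, fs in enumerate(adj.edge_faces):
        if len(fs) != 2:
            continue
        f1, f2 = fs
        n1, n2 = normals[f1], normals[f2]
        cosang = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
        angle = float(np.arccos(cosang))
        if angle < 1e-12:
            continue
        # convex when the neighbouring centroid lies behind this face's plane
        side = float(np.dot(n1, centroids[f2] - centroids[f1]))
        values[e] = angle if side <= 0 else -angle
    return CurvatureField(values)


def grow_tooth_region(
    mesh: TriangleMesh,
    adj: AdjacencyIndex,
    curv: CurvatureField,
    peak: PeakPoint,
    frame: ArchFrame,
    stop_curvature: float = STOP_CURVATURE,
    max_travel: float = MAX_TRAVEL_PERMANENT,
) -> Blob:
    """Breadth-first face growth from a peak, bounded by concave creases.

    Growth never crosses an edge with curvature <= ``stop_curvature``.  A face
    whose centroid lies farther than ``max_travel`` (horizontally) from the
    peak is not entered; if that cap is ever invoked the blob is flagged
    spilled — it met no tooth boundary and is not a tooth.
    """
    v = peak.vertex_index
    if v < 0 or v >= len(mesh.vertices):
        raise IndexError(f"peak vertex {v} not in mesh")
    blocked = crease_blocked_edges(mesh, adj, curv, stop_curvature)
    horiz = frame.to_local(mesh.face_centroids)[:, :2]
    peak_h = frame.to_local(peak.position)[0, :2]
    dist2 = ((horiz - peak_h) ** 2).sum(axis=1)
    cap2 = max_travel * max_travel

    seeds = sorted(int(f) for f in adj.vertex_faces(v))
    visited: set[int] = set()
    spilled = False
    frontier: list[int] = []
    for f in seeds:
        if dist2[f] <= cap2:
            heapq.heappush(frontier, f)
            visited.add(f)
        else:
            spilled = True
    while frontier:
        f = heapq.heappop(frontier)
        for e, g in _neighbors_with_edges(adj, f):
            if g in visited:
                continue
            if blocked[e]:
                continue
            if dist2[g] > cap2:
                spilled = True
                continue
            visited.add(g)
            heapq.heappush(frontier, g)
    return Blob(faces=frozenset(visited), peaks=[peak], spilled=spilled)


def crease_blocked_edges(
    mesh: TriangleMesh,
    adj: AdjacencyIndex,
    curv: CurvatureField,
    stop_curvature: float,
) -> np.ndarray:
    """Boolean mask of edges region growing must not cross.

    An edge is blocked when its own curvature is <= ``stop_curvature``, or
    when both its endpoints already lie on such crease edges.  The second
    rule closes one-edge staircase gaps: surface triangulations split a fold
    that runs diagonally to the sampling into alternating edge rows, and
    without the closure a traversal can slip between two crease edges that
    share only vertices.  Cached on the curvature field per threshold.
    """
    cache = getattr(curv, "_blocked_cache", None)
    if cache is not None and cache[0] == stop_curvature:
        return cache[1]
    strong = curv.values <= stop_curvature
    crease_vertex = np.zeros(len(mesh.vertices), dtype=bool)
    crease_vertex[adj.edges[strong].ravel()] = True
    blocked = strong | (
        crease_vertex[adj.edges[:, 0]] & crease_vertex[adj.edges[:, 1]]
    )
    curv._blocked_cache = (stop_curvature, blocked)
    return blocked


def _neighbors_with_edges(adj: AdjacencyIndex, f: int):
    for e in adj.face_edges[f]:
        fs = adj.edge_faces[e]
        if len(fs) == 2:
            g = fs[0] if fs[1] == f else fs[1]
            if g != f:
                yield int(e), int(g)


def fit_jawline(peaks, frame: ArchFrame) -> Jawline:
    """Least-squares quadratic AP(T) through the non-spilled peak points."""
    pts = [p for p in peaks if not p.spilled]
    if len(pts) < 3:
        raise DegenerateGeometryError("need >= 3 non-spilled peaks for the jawline")
    local = frame.to_local(np.array([p.position for p in pts]))
    t, ap = local[:, 0], local[:, 1]
    if np.ptp(t) < 1e-9:
        raise DegenerateGeometryError("peak transverse coordinates are not distinct")
    coeffs = np.polyfit(t, ap, 2)
    resid = ap - np.polyval(coeffs, t)
    return Jawline(
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        c=float(coeffs[2]),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def _jaw_parameter(blob: Blob, jawline: Jawline, frame: ArchFrame) -> float:
    local = frame.to_local(blob.highest_peak.position)[0, :2]
    return jawline.arc_length(jawline.project_t(local))


def merge_blobs(
    blobs,
    jawline: Jawline,
    frame: ArchFrame,
    merge_distance: float = MAX_TRAVEL_PERMANENT / 2,
):
    """Discard spilled blobs, merge duplicates, and order along the jawline.

    Merging happens in two passes: blobs sharing at least one face are
    unioned (several cusp regions of one tooth overlap), then disjoint blobs
    closer than ``merge_distance`` along the jawline are unioned (buccal and
    lingual halves of a molar sit at the same arch position without
    touching).  The result is sorted by jaw parameter.
    """
    alive = [b for b in blobs if not b.spilled]
    if not alive:
        return []

    # union-find over blobs sharing faces
    parent = list(range(len(alive)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    owner: dict[int, int] = {}
    for i, b in enumerate(alive):
        for f in b.faces:
            if f in owner:
                union(owner[f], i)
            else:
                owner[f] = i
    groups: dict[int, list[int]] = {}
    for i in range(len(alive)):
        groups.setdefault(find(i), []).append(i)

    merged = [
        Blob(
            faces=frozenset().union(*[alive[i].faces for i in idxs]),
            peaks=[p for i in idxs for p in alive[i].peaks],
        )
        for idxs in groups.values()
    ]
    for b in merged:
        b.jaw_parameter = _jaw_parameter(b, jawline, frame)
    merged.sort(key=lambda b: b.jaw_parameter)

    # second pass: chain-merge neighbours at (nearly) the same arch position
    out: list[Blob] = []
    for b in merged:
        if out and abs(b.jaw_parameter - out[-1].jaw_parameter) < merge_distance:
            prev = out.pop()
            u = Blob(faces=prev.faces | b.faces, peaks=prev.peaks + b.peaks)
            u.jaw_parameter = _jaw_parameter(u, jawline, frame)
            out.append(u)
        else:
            out.append(b)
    out.sort(key=lambda b: b.jaw_parameter)
    return out
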