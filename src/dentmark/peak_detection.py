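"""Occlusal peak-point detection.

Cusp tips and incisal edges are the highest parts of teeth, so candidate
landmarks are local maxima of the mesh in the occlusal direction.  Only the
top band of the model is searched — a vertex must lie within a depth
threshold (default 6 mm) of the global maximum — which is shallow enough to
exclude gingiva and base yet deep enough to keep worn or partially erupted
teeth.  Duplicate and non-tooth peaks are allowed here; the partition stage
filters them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMeshError
from .mesh_core import AdjacencyIndex, TriangleMesh
from .orientation import ArchFrame

DEPTH_THRESHOLD_MM = 6.0
RING = 2


@dataclass
class PeakPoint:
    """A local occlusal maximum: a candidate cusp tip."""

    vertex_index: int
    position: np.ndarray  # (3,) mm
    height: float         # projection onto the occlusal axis, mm
    spilled: bool = field(default=False)


def _ring_max(heights: np.ndarray, adj: AdjacencyIndex, rings: int) -> np.ndarray:
    """max over the closed r-ring neighbourhood of every vertex."""
    m = heights.copy()
    indptr, indices = adj.vert_nbr_indptr, adj.vert_nbr_indices
    counts = np.diff(indptr)
    has_nbr = counts > 0
    for _ in range(rings):
        nbr_max = np.full_like(m, -np.inf)
        # segment max of m[indices] grouped by vertex
        seg = np.maximum.reduceat(m[indices], indptr[:-1][has_nbr])
        nbr_max[has_nbr] = seg
        m = np.maximum(m, nbr_max)
    return m


def _ring_neighbors(adj: AdjacencyIndex, v: int, rings: int) -> set:
    """Open r-ring vertex neighbourhood of ``v`` (excludes ``v``)."""
    seen = {v}
    frontier = {v}
    for _ in range(rings):
        nxt = set()
        for u in frontier:
            nxt.update(int(w) for w in adj.vertex_neighbors(u))
        nxt -= seen
        seen |= nxt
        frontier = nxt
    seen.discard(v)
    return seen


def find_peaks(
    mesh: TriangleMesh,
    adj: AdjacencyIndex,
    frame: ArchFrame,
    depth_threshold: float = DEPTH_THRESHOLD_MM,
    ring: int = RING,
) -> list[PeakPoint]:
    """Local occlusal maxima within ``depth_threshold`` of the highest point.

    A vertex is a peak when its height is >= every vertex in its ``ring``-ring
    neighbourhood and > at least one of them; flat plateaus keep a single
    representative, the lowest vertex index.  The result is sorted by
    descending height, ties broken toward the lowest index.
    """
    if len(mesh.faces) == 0:
        raise EmptyMeshError("cannot find peaks on an empty mesh")
    h = frame.heights(mesh.vertices)
    hmax = float(h.max())
    in_band = h >= hmax - depth_threshold

    closed_max = _ring_max(h, adj, ring)
    candidates = np.nonzero(in_band & (h >= closed_max))[0]

    peaks: list[int] = []
    claimed_plateaus: set[int] = set()
    for v in candidates.tolist():
        nbrs = _ring_neighbors(adj, v, ring)
        if not nbrs:
            continue
        nb_h = h[list(nbrs)]
        if np.any(nb_h > h[v] + 1e-12):
            continue  # defensive; closed_max filter should have caught it
        equal = [u for u in nbrs if abs(h[u] - h[v]) <= 1e-12]
        if len(equal) == len(nbrs):
            # interior of a flat plateau: skip, a boundary vertex represents it
            continue
        if equal:
            # plateau: keep only the lowest-index member of the level set
            if v in claimed_plateaus:
                continue
            level = _plateau(adj, v, h, ring)
            rep = min(level)
            claimed_plateaus.update(level)
            if v != rep:
                continue
        peaks.append(v)

    peaks.sort(key=lambda v: (-h[v], v))
    return [
        PeakPoint(int(v), mesh.vertices[v].copy(), float(h[v])) for v in peaks
    ]


def _plateau(adj: AdjacencyIndex, v: int, h: np.ndarray, ring: int) -> set:
    """Connected set of vertices at the same height as ``v`` (via ring hops)."""
    level = {v}
    frontier = [v]
    while frontier:
        u = frontier.pop()
        for w in _ring_neighbors(adj, u, ring):
            if w not in level and abs(h[w] - h[u]) <= 1e-12:
                level.add(w)
                frontier.append(w)
    return level
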