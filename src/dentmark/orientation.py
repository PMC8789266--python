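"""Anatomical orientation of an arch mesh.

A dental arch is wider (transverse) than it is long (antero-posterior) and
longer than it is tall, so the principal axes of the vertex cloud order as
transverse > antero-posterior > occlusal.  PCA fixes the axes only up to
sign; the signs are resolved by two shape heuristics (crown tips taper
relative to the base; the arch parabola opens posteriorly) and the occlusal
direction is then refined by a least-squares plane through the detected
tooth tips — the vertical direction is the one that must be accurate, the
horizontal pair may stay approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometryError, RefinementSkipped
from .mesh_core import TriangleMesh

TAPER_RATIO = 1.05  # footprint ratio below which up/down is ambiguous


@dataclass
class ArchFrame:
    """Right-handed orthonormal anatomical frame of one arch.

    ``transverse_axis x anteroposterior_axis = occlusal_axis``.  The occlusal
    axis points out of the crowns (up for a mandibular arch, down for a
    maxillary arch scanned in occlusion).
    """

    origin: np.ndarray
    transverse_axis: np.ndarray
    anteroposterior_axis: np.ndarray
    occlusal_axis: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.transverse_axis = np.asarray(self.transverse_axis, dtype=float)
        self.anteroposterior_axis = np.asarray(self.anteroposterior_axis, dtype=float)
        self.occlusal_axis = np.asarray(self.occlusal_axis, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        """(3,3) matrix whose rows are (T, AP, O)."""
        return np.vstack(
            [self.transverse_axis, self.anteroposterior_axis, self.occlusal_axis]
        )

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """World points -> (T, AP, O) coordinates about the origin."""
        return (np.atleast_2d(points) - self.origin) @ self.rotation.T

    def heights(self, points: np.ndarray) -> np.ndarray:
        """Scalar projection of points onto the occlusal axis."""
        return np.atleast_2d(points) @ self.occlusal_axis

    def is_orthonormal(self, tol: float = 1e-9) -> bool:
        r = self.rotation
        return (
            np.allclose(r @ r.T, np.eye(3), atol=tol)
            and np.linalg.det(r) > 0
        )

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "transverse_axis": self.transverse_axis.tolist(),
            "anteroposterior_axis": self.anteroposterior_axis.tolist(),
            "occlusal_axis": self.occlusal_axis.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchFrame":
        return cls(
            np.array(d["origin"]),
            np.array(d["transverse_axis"]),
            np.array(d["anteroposterior_axis"]),
            np.array(d["occlusal_axis"]),
        )


def _right_handed(t: np.ndarray, ap: np.ndarray, o: np.ndarray):
    """Flip the transverse axis if needed so T x AP = O."""
    if np.dot(np.cross(t, ap), o) < 0:
        t = -t
    return t, ap, o


def pca_axes(mesh: TriangleMesh) -> ArchFrame:
    """Principal axes of the vertex cloud, ordered transverse/AP/occlusal.

    Signs are provisional; see :func:`disambiguate_signs`.
    """
    v = mesh.vertices
    if len(v) < 3:
        raise DegenerateGeometryError("need at least 3 vertices for PCA")
    centre = v.mean(axis=0)
    cov = np.cov((v - centre).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[-1], 1.0):
        raise DegenerateGeometryError("covariance is rank-deficient")
    # eigh returns ascending eigenvalues: smallest = occlusal, largest = transverse
    o, ap, t = evecs[:, 0], evecs[:, 1], evecs[:, 2]
    t, ap, o = _right_handed(t, ap, o)
    return ArchFrame(centre, t, ap, o)


def _slab_footprint(local: np.ndarray, lo: float, hi: float) -> float:
    """Convex-hull area of the horizontal (T, AP) projection of one height slab."""
    sel = (local[:, 2] >= lo) & (local[:, 2] <= hi)
    pts = local[sel][:, :2]
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D hull: .volume is area
    except QhullError:
        return 0.0


def disambiguate_signs(mesh: TriangleMesh, frame: ArchFrame) -> ArchFrame:
    """Resolve the up/down and anterior/posterior sign ambiguities.

    Up/down: crowns taper toward the tips while the base (cast bottom or
    gingival roll) is broad, so the top decile slab along the occlusal axis
    has the smaller horizontal convex-hull footprint.  Anterior/posterior:
    the arch is a parabola with its apex at the incisors, so the quadratic
    fitted to the crown-level vertex cloud must open toward posterior.
    The transverse axis is then flipped as needed to keep the frame
    right-handed.  Idempotent for a correctly signed frame.
    """
    t = frame.transverse_axis.copy()
    ap = frame.anteroposterior_axis.copy()
    o = frame.occlusal_axis.copy()

    local = frame.to_local(mesh.vertices)
    h = local[:, 2]
    hmin, hmax = float(h.min()), float(h.max())
    decile = 0.1 * (hmax - hmin)
    top = _slab_footprint(local, hmax - decile, hmax)
    bottom = _slab_footprint(local, hmin, hmin + decile)

    flipped_o = False
    if bottom > 0 and top > 0:
        ratio = max(top, bottom) / min(top, bottom)
        if ratio < TAPER_RATIO:
            warnings.warn(
                "up/down footprint ratio within 5% of 1: keeping provisional "
                "occlusal sign",
                stacklevel=2,
            )
        elif top > bottom:
            o = -o
            flipped_o = True
    if flipped_o:
        local = np.column_stack([local[:, 0], local[:, 1], -local[:, 2]])

    # anterior/posterior from arch concavity: fit AP = a T^2 + b T + c to the
    # crown-level slab (top 40% of the height range — stays on teeth for casts
    # with tall bases) and require the parabola to open toward -AP (posterior).
    hh = local[:, 2]
    crown = local[hh >= hh.min() + 0.6 * (hh.max() - hh.min())]
    if len(crown) < 10:
        crown = local
    a = np.polyfit(crown[:, 0], crown[:, 1], 2)[0]
    if a > 0:
        ap = -ap

    t, ap, o = _right_handed(t, ap, o)
    return ArchFrame(frame.origin.copy(), t, ap, o)


def refine_occlusal(frame: ArchFrame, peak_positions) -> ArchFrame:
    """Refine the occlusal axis to the normal of the tooth-tip plane.

    Fits a total-least-squares plane through the peak positions and
    re-orthogonalizes the horizontal axes against its normal.  Raises
    :class:`RefinementSkipped` when fewer than three non-collinear peaks are
    available, in which case the caller keeps the prior frame.
    """
    pts = np.atleast_2d(np.asarray(peak_positions, dtype=float))
    if len(pts) < 3:
        raise RefinementSkipped("need at least 3 peak positions")
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise RefinementSkipped("peak positions are collinear")
    n = vt[2]
    if np.dot(n, frame.occlusal_axis) < 0:
        n = -n
    ap = frame.anteroposterior_axis - np.dot(frame.anteroposterior_axis, n) * n
    norm = np.linalg.norm(ap)
    if norm < 1e-12:
        raise RefinementSkipped("anteroposterior axis parallel to refined normal")
    ap = ap / norm
    t = np.cross(ap, n)
    t /= np.linalg.norm(t)
    t, ap, n = _right_handed(t, ap, n)
    return ArchFrame(frame.origin.copy(), t, ap, n)
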