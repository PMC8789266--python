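"""Modified Huddart-Bodenham (MHB) occlusal scoring.

The MHB index scores maxillary arch constriction tooth by tooth on an
ordinal scale: each maxillary cusp landmark is compared against a cubic
spline through the mandibular cusp landmarks, the in-plane (horizontal)
component of the shortest landmark-to-curve vector is signed along the
local buccal direction (positive = buccal, negative = lingual/crossbite),
and a monotone step mapping converts the signed displacement into the
ordinal score.  Both arches must share one coordinate frame, as produced
by an intra-oral scanner's occlusion registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .errors import ConfigError, DegenerateGeometryError
from .mesh_core import TriangleMesh
from .orientation import ArchFrame
from .tooth_assignment import Assignment, ToothType, parse_tooth_type
from .tooth_partition import Blob, Jawline

CURVE_SAMPLING_MM = 0.05


@dataclass
class Landmark:
    """A cusp-tip landmark: a mesh vertex chosen to represent one tooth."""

    tooth: ToothType
    position: np.ndarray  # (3,) mm
    vertex_index: int = -1


@dataclass
class MandibularCurve:
    """Interpolating cubic spline through ordered mandibular landmarks,
    parameterized by cumulative chord length (mm)."""

    spline: CubicSpline
    total_length: float
    knots: np.ndarray  # chord-length parameter of each landmark

    def point(self, s):
        return self.spline(np.clip(s, 0.0, self.total_length))

    def tangent(self, s: float) -> np.ndarray:
        d = self.spline(np.clip(s, 0.0, self.total_length), 1)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise DegenerateGeometryError("degenerate curve tangent")
        return d / n


@dataclass
class ReferencePlane:
    """Least-squares horizontal plane through the mandibular landmarks."""

    normal: np.ndarray  # unit
    offset: float       # plane: normal . x = offset

    def project(self, vec: np.ndarray) -> np.ndarray:
        """Project a direction vector into the plane."""
        return vec - np.dot(vec, self.normal) * self.normal


@dataclass
class MHBMapping:
    """Configurable displacement -> ordinal score step functions.

    Each segment maps a signed transverse displacement d (mm, positive =
    buccal) through a monotone non-increasing step function given as
    descending ``(threshold, score)`` pairs: the score of the first
    threshold with d >= threshold, else ``floor_score``.
    """

    buccal: tuple = ((1.0, 0), (-1.0, -1))
    buccal_floor: int = -2
    labial: tuple = ((6.0, 1), (1.0, 0), (-1.0, -1), (-3.0, -2))
    labial_floor: int = -3
    canine_segment: str = "labial"

    def __post_init__(self):
        for steps, floor in ((self.buccal, self.buccal_floor), (self.labial, self.labial_floor)):
            thresholds = [t for t, _ in steps]
            scores = [s for _, s in steps] + [floor]
            if sorted(thresholds, reverse=True) != list(thresholds):
                raise ConfigError("mapping thresholds must be descending")
            if sorted(scores, reverse=True) != list(scores):
                raise ConfigError("mapping scores must be non-increasing as d decreases")

    def segment_for(self, tooth: ToothType) -> str:
        cls = tooth.tooth_class
        if cls == "I":
            return "labial"
        if cls == "C":
            return self.canine_segment
        return "buccal"

    def breakpoints(self) -> list:
        return sorted({t for t, _ in self.buccal} | {t for t, _ in self.labial})


def mhb_score(displacement: float, segment: str, mapping: MHBMapping) -> int:
    """Ordinal MHB score of one signed displacement (mm)."""
    if segment == "buccal":
        steps, floor = mapping.buccal, mapping.buccal_floor
    elif segment == "labial":
        steps, floor = mapping.labial, mapping.labial_floor
    else:
        raise ConfigError(f"unknown segment {segment!r}")
    for threshold, score in steps:
        if displacement >= threshold:
            return score
    return floor


@dataclass
class ToothScore:
    tooth: ToothType
    displacement: float
    segment: str
    score: int


@dataclass
class MHBScoreCard:
    """Per-tooth signed displacements and ordinal scores, with arch total."""

    scores: list = field(default_factory=list)      # list[ToothScore]
    unscored: list = field(default_factory=list)    # (ToothType, reason)

    @property
    def total(self) -> int:
        return sum(s.score for s in self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tooth_type": str(s.tooth),
                    "displacement_mm": s.displacement,
                    "segment": s.segment,
                    "score": s.score,
                }
                for s in self.scores
            ]
        )

    def to_dict(self) -> dict:
        return {
            "scores": self.to_frame().to_dict(orient="records"),
            "unscored": [{"tooth_type": str(t), "reason": r} for t, r in self.unscored],
            "total": self.total,
        }


# ---------------------------------------------------------------------------
# landmark extraction


def select_scored_teeth(assignment: Assignment, dentition: str) -> list:
    """Tooth types of an assignment that MHB scores.

    Permanent dentition: positions 1-6 per quadrant (second and third molars
    are excluded), at most 12 per arch.  Deciduous: every position, at most
    10.  A molar segmented as a half-type pair counts once.
    """
    seen = []
    limit = 5 if dentition == "deciduous" else 6
    for t in assignment.labels:
        if t is None or t.position > limit:
            continue
        whole = t.with_half(None)
        if whole not in seen:
            seen.append(whole)
    return seen


def extract_landmark(
    mesh: TriangleMesh,
    blob: Blob,
    tooth: ToothType,
    frame: ArchFrame,
    jawline: Jawline,
) -> Landmark:
    """Cusp landmark of one labelled blob.

    Incisors and canines: the highest peak.  Premolars and molars: the peak
    on the buccal side of the jawline with maximal buccal offset (the buccal
    cusp), falling back to the highest peak when no peak lies buccally.
    Ties break toward the lowest vertex index.
    """
    if not blob.peaks:
        raise DegenerateGeometryError(f"blob for {tooth} has no peaks")
    peaks = sorted(blob.peaks, key=lambda p: p.vertex_index)
    if tooth.tooth_class in ("I", "C"):
        chosen = max(peaks, key=lambda p: (p.height, -p.vertex_index))
    else:
        offsets = []
        for p in peaks:
            local = frame.to_local(p.position)[0]
            t = jawline.project_t(local[:2])
            tanv = jawline.tangent(t)
            # normal pointing away from the parabola's concave side (buccal)
            nrm = np.array([-tanv[1], tanv[0]])
            if nrm[1] * (2.0 * jawline.a) > 0:
                nrm = -nrm
            delta = local[:2] - np.array([t, jawline.ap(t)])
            offsets.append(float(delta @ nrm))
        buccal = [(o, p) for o, p in zip(offsets, peaks) if o > 0]
        if buccal:
            chosen = max(buccal, key=lambda op: (op[0], -op[1].vertex_index))[1]
        else:
            chosen = max(peaks, key=lambda p: (p.height, -p.vertex_index))
    return Landmark(tooth=tooth, position=chosen.position.copy(), vertex_index=chosen.vertex_index)


# ---------------------------------------------------------------------------
# curve / plane fits


def fit_mandibular_curve(landmarks) -> MandibularCurve:
    """Natural cubic spline through >= 4 ordered landmarks (chord-length)."""
    if len(landmarks) < 4:
        raise DegenerateGeometryError("need >= 4 landmarks for the mandibular curve")
    pts = np.array([lm.position for lm in landmarks], dtype=float)
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chord < 1e-9):
        raise DegenerateGeometryError("coincident consecutive landmarks")
    s = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(s, pts, bc_type="natural")
    return MandibularCurve(spline=spline, total_length=float(s[-1]), knots=s)


def fit_reference_plane(landmarks, frame: ArchFrame) -> ReferencePlane:
    """Total-least-squares plane through the landmarks, normal along occlusal."""
    pts = np.array([lm.position for lm in landmarks], dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError("need >= 3 landmarks for the reference plane")
    centre = pts.mean(axis=0)
    _, sv, vt = np.linalg.svd(pts - centre, full_matrices=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("landmarks are collinear")
    n = vt[2]
    if np.dot(n, frame.occlusal_axis) < 0:
        n = -n
    return ReferencePlane(normal=n, offset=float(np.dot(n, centre)))


def _closest_parameter(curve: MandibularCurve, point: np.ndarray) -> float:
    """Curve parameter minimizing 3-D distance: dense scan + local refinement."""
    ns = max(int(np.ceil(curve.total_length / CURVE_SAMPLING_MM)), 2)
    s = np.linspace(0.0, curve.total_length, ns)
    d2 = ((curve.point(s) - point) ** 2).sum(axis=1)
    k = int(np.argmin(d2))
    lo = s[max(k - 1, 0)]
    hi = s[min(k + 1, ns - 1)]
    if hi - lo < 1e-12:
        return float(s[k])
    res = minimize_scalar(
        lambda u: float(((curve.point(u) - point) ** 2).sum()),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


def transverse_displacement(
    landmark: Landmark,
    curve: MandibularCurve,
    plane: ReferencePlane,
    arch_centre: np.ndarray,
) -> float:
    """Signed horizontal distance (mm) from the mandibular curve to a
    maxillary landmark; positive points buccally (away from the arch
    interior at ``arch_centre``)."""
    s = _closest_parameter(curve, landmark.position)
    cp = curve.point(s)
    tangent = curve.tangent(s)
    in_plane = plane.project(landmark.position - cp)

    t_proj = plane.project(tangent)
    norm = np.linalg.norm(t_proj)
    if norm < 1e-9:
        raise DegenerateGeometryError("curve tangent perpendicular to plane")
    t_proj /= norm
    buccal = np.cross(plane.normal, t_proj)
    outward = plane.project(cp - arch_centre)
    if np.dot(buccal, outward) < 0:
        buccal = -buccal
    return float(np.dot(in_plane, buccal))


# ---------------------------------------------------------------------------
# arch-pair scoring


def _antagonist(tooth: ToothType) -> ToothType:
    """Same position and patient side on the opposite jaw."""
    q = ("L" if tooth.jaw == "U" else "U") + tooth.side
    return ToothType(q, tooth.position, tooth.deciduous)


def score_arch_pair(
    maxillary_landmarks: dict,
    mandibular_landmarks: dict,
    maxillary_assignment: Assignment,
    mandibular_frame: ArchFrame,
    dentition: str,
    mapping: MHBMapping | None = None,
) -> MHBScoreCard:
    """MHB scorecard for an occlusion-registered arch pair.

    ``*_landmarks`` map ToothType -> Landmark (whole-tooth types).  Each
    scored maxillary tooth needs its mandibular antagonist present; teeth
    missing from either arch are reported unscored.
    """
    mapping = mapping or MHBMapping()
    mand = sorted(mandibular_landmarks.values(), key=_arch_order_key)
    if len(mand) < 4:
        raise DegenerateGeometryError(
            "need >= 4 mandibular landmarks to fit the mandibular curve"
        )
    curve = fit_mandibular_curve(mand)
    plane = fit_reference_plane(mand, mandibular_frame)
    centre = np.array([lm.position for lm in mand]).mean(axis=0)

    card = MHBScoreCard()
    for tooth in select_scored_teeth(maxillary_assignment, dentition):
        if tooth not in maxillary_landmarks:
            card.unscored.append((tooth, "no maxillary landmark"))
            continue
        if _antagonist(tooth) not in mandibular_landmarks:
            card.unscored.append((tooth, "antagonist missing from mandibular arch"))
            continue
        lm = maxillary_landmarks[tooth]
        d = transverse_displacement(lm, curve, plane, centre)
        segment = mapping.segment_for(tooth)
        card.scores.append(
            ToothScore(tooth=tooth, displacement=d, segment=segment,
                       score=mhb_score(d, segment, mapping))
        )
    return card


def _arch_order_key(lm: Landmark):
    t = lm.tooth
    side = 0 if t.side == "R" else 1
    return (side, -t.position if side == 0 else t.position)


# ---------------------------------------------------------------------------
# landmark CSV exchange


def landmarks_to_csv(landmarks: dict, path) -> None:
    df = pd.DataFrame(
        [
            {"tooth_type": str(t), "x": lm.position[0], "y": lm.position[1], "z": lm.position[2]}
            for t, lm in sorted(landmarks.items(), key=lambda kv: str(kv[0]))
        ]
    )
    df.to_csv(path, index=False)


def landmarks_from_csv(path) -> dict:
    df = pd.read_csv(path)
    missing = {"tooth_type", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ConfigError(f"landmark CSV missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        t = parse_tooth_type(str(row["tooth_type"]))
        out[t] = Landmark(t, np.array([row["x"], row["y"], row["z"]], dtype=float))
    return out
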