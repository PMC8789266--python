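"""Template-constrained tooth labelling.

Blobs ordered round the jaw are labelled with Palmer-style tooth types by
minimizing the total mismatch between each blob's dimensional features and
the per-type statistics of a training set, subject to an arch template:
MMMPPCIIIICPPMMM for a permanent arch, mmciiiicmm for a deciduous one.
Template slots may be skipped (missing tooth), blobs may be discarded
(non-tooth residue), and a molar slot may absorb two consecutive blobs as
its mesial/distal half-types (e.g. UR6.0 and UR6.1).  The optimum over all
monotone alignments is found by dynamic programming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateGeometryError
from .mesh_core import TriangleMesh, surface_area
from .orientation import ArchFrame
from .tooth_partition import Blob, Jawline

GAP_PENALTY = 6.0      # cost of leaving a template slot empty (squared-z units)
DISCARD_PENALTY = 9.0  # cost of dropping a blob as non-tooth residue

FEATURE_NAMES = (
    "surface_area",
    "mesiodistal_width",
    "buccolingual_width",
    "crown_height",
    "peak_count",
)

_DECID_LETTERS = "abcde"


@dataclass(frozen=True)
class ToothType:
    """Palmer-style tooth identifier.

    ``quadrant`` is UR/UL/LR/LL; ``position`` counts 1-8 from the midline for
    permanent teeth and 1-5 (rendered a-e) for deciduous; ``half`` is None
    for a whole tooth, 0 for the mesial and 1 for the distal half of a molar
    segmented as two blobs.
    """

    quadrant: str
    position: int
    deciduous: bool = False
    half: int | None = None

    def __post_init__(self):
        if self.quadrant not in ("UR", "UL", "LR", "LL"):
            raise ValueError(f"bad quadrant {self.quadrant!r}")
        limit = 5 if self.deciduous else 8
        if not 1 <= self.position <= limit:
            raise ValueError(f"bad position {self.position}")
        if self.half is not None and self.tooth_class != "M":
            raise ValueError("half suffix only valid on molar positions")

    @property
    def jaw(self) -> str:
        return "U" if self.quadrant[0] == "U" else "L"

    @property
    def side(self) -> str:
        return self.quadrant[1]

    @property
    def tooth_class(self) -> str:
        """I (incisor), C (canine), P (premolar) or M (molar)."""
        p = self.position
        if self.deciduous:
            return {1: "I", 2: "I", 3: "C", 4: "M", 5: "M"}[p]
        return {1: "I", 2: "I", 3: "C", 4: "P", 5: "P", 6: "M", 7: "M", 8: "M"}[p]

    @property
    def is_molar(self) -> bool:
        return self.tooth_class == "M"

    def with_half(self, half: int | None) -> "ToothType":
        return ToothType(self.quadrant, self.position, self.deciduous, half)

    def mirrored(self) -> "ToothType":
        q = self.quadrant[0] + ("L" if self.side == "R" else "R")
        return ToothType(q, self.position, self.deciduous, self.half)

    @property
    def training_key(self) -> str:
        """Side-collapsed class key (left/right share statistics)."""
        pos = _DECID_LETTERS[self.position - 1] if self.deciduous else str(self.position)
        suffix = "" if self.half is None else f".{self.half}"
        return f"{self.jaw}{pos}{suffix}"

    def __str__(self) -> str:
        pos = _DECID_LETTERS[self.position - 1] if self.deciduous else str(self.position)
        suffix = "" if self.half is None else f".{self.half}"
        return f"{self.quadrant}{pos}{suffix}"


def parse_tooth_type(code: str) -> ToothType:
    """Parse strings like 'UR6', 'LLb', 'UR6.0'."""
    code = code.strip()
    if len(code) < 3:
        raise ValueError(f"bad tooth code {code!r}")
    quadrant, rest = code[:2].upper(), code[2:]
    half = None
    if "." in rest:
        rest, h = rest.split(".", 1)
        half = int(h)
    if rest.lower() in _DECID_LETTERS:
        return ToothType(quadrant, _DECID_LETTERS.index(rest.lower()) + 1, True, half)
    return ToothType(quadrant, int(rest), False, half)


# ---------------------------------------------------------------------------
# arch templates


@dataclass(frozen=True)
class ArchTemplate:
    """Ordered tooth-type sequence of one arch, patient-right to patient-left."""

    jaw: str              # 'U' | 'L'
    dentition: str        # 'permanent' | 'deciduous'
    slots: tuple = field(default=None)

    def pattern(self) -> str:
        return "".join(
            t.tooth_class if not t.deciduous else t.tooth_class.lower()
            for t in self.slots
        )


def build_template(jaw: str, dentition: str) -> ArchTemplate:
    """Template for (jaw, dentition): 16 permanent or 10 deciduous slots."""
    if jaw not in ("U", "L"):
        raise ConfigError(f"jaw must be 'U' or 'L', got {jaw!r}")
    if dentition not in ("permanent", "deciduous"):
        raise ConfigError(f"bad dentition {dentition!r}")
    decid = dentition == "deciduous"
    npos = 5 if decid else 8
    right_q = jaw + "R"
    left_q = jaw + "L"
    slots = tuple(
        [ToothType(right_q, p, decid) for p in range(npos, 0, -1)]
        + [ToothType(left_q, p, decid) for p in range(1, npos + 1)]
    )
    return ArchTemplate(jaw=jaw, dentition=dentition, slots=slots)


# ---------------------------------------------------------------------------
# features


@dataclass
class ToothFeatures:
    """Per-blob dimensional descriptors (mm, mm^2, count)."""

    surface_area: float
    mesiodistal_width: float
    buccolingual_width: float
    crown_height: float
    peak_count: int

    def vector(self) -> np.ndarray:
        return np.array(
            [
                self.surface_area,
                self.mesiodistal_width,
                self.buccolingual_width,
                self.crown_height,
                float(self.peak_count),
            ]
        )


PEAK_DEDUP_MM = 2.5


def distinct_peak_count(blob: Blob, min_separation: float = PEAK_DEDUP_MM) -> int:
    """Number of distinct cusp peaks in a blob.

    Peak detection may return several local maxima on one cusp (noise
    duplicates are expected and filtered here): peaks closer than
    ``min_separation`` to an already-kept higher peak count once.
    """
    kept: list[np.ndarray] = []
    for p in sorted(blob.peaks, key=lambda p: (-p.height, p.vertex_index)):
        if all(np.linalg.norm(p.position - q) >= min_separation for q in kept):
            kept.append(p.position)
    return len(kept)


def compute_features(
    mesh: TriangleMesh, blob: Blob, frame: ArchFrame, jawline: Jawline
) -> ToothFeatures:
    """Dimensional features of one blob in the oriented frame.

    Mesiodistal width is the blob's extent along the local jawline tangent,
    buccolingual width the horizontal extent perpendicular to it, crown
    height the occlusal extent.  Peak count is deduplicated (see
    :func:`distinct_peak_count`).
    """
    if not blob.faces:
        raise ValueError("blob has no faces")
    faces = np.array(sorted(blob.faces), dtype=np.int64)
    verts = np.unique(mesh.faces[faces].reshape(-1))
    local = frame.to_local(mesh.vertices[verts])

    peak_local = frame.to_local(blob.highest_peak.position)[0, :2]
    tan = jawline.tangent(jawline.project_t(peak_local))  # (dT, dAP) unit
    nrm = np.array([-tan[1], tan[0]])

    along = local[:, :2] @ tan
    across = local[:, :2] @ nrm
    return ToothFeatures(
        surface_area=surface_area(mesh, faces),
        mesiodistal_width=float(np.ptp(along)),
        buccolingual_width=float(np.ptp(across)),
        crown_height=float(np.ptp(local[:, 2])),
        peak_count=distinct_peak_count(blob),
    )


# ---------------------------------------------------------------------------
# training set


STD_FLOOR_ABS = 1e-3
STD_FLOOR_REL = 0.05     # 5% of |mean|: guards degenerate synthetic spreads
PEAK_COUNT_STD_FLOOR = 0.75


class TrainingSet:
    """Per-type feature statistics from labelled example blobs.

    Types are side-collapsed (UR6 and UL6 share a class, mirror-invariant
    features make this lossless).  Standard deviations are floored so that a
    single discrete feature (peak count) can never dominate the mismatch.
    """

    def __init__(self, samples: dict[str, list[np.ndarray]]):
        self.samples = {k: [np.asarray(v, dtype=float) for v in vs] for k, vs in samples.items()}
        self.stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for key, vecs in self.samples.items():
            if len(vecs) < 2:
                raise ConfigError(f"training type {key} has fewer than 2 samples")
            arr = np.vstack(vecs)
            mean = arr.mean(axis=0)
            std = arr.std(axis=0, ddof=1)
            floor = np.maximum(STD_FLOOR_ABS, STD_FLOOR_REL * np.abs(mean))
            floor[4] = max(floor[4], PEAK_COUNT_STD_FLOOR)
            self.stats[key] = (mean, np.maximum(std, floor))

    def __contains__(self, tooth: ToothType) -> bool:
        return tooth.training_key in self.stats

    def lookup(self, tooth: ToothType) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self.stats[tooth.training_key]
        except KeyError:
            raise KeyError(f"tooth type {tooth} not in training set") from None

    # -- CSV round trip ----------------------------------------------------

    def to_csv(self, path) -> None:
        rows = []
        for key, vecs in sorted(self.samples.items()):
            quadrant = ("UR" if key[0] == "U" else "LR")
            for v in vecs:
                rows.append([quadrant + key[1:], *v])
        df = pd.DataFrame(rows, columns=["tooth_type", *FEATURE_NAMES])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TrainingSet":
        df = pd.read_csv(path_or_buf)
        missing = {"tooth_type", *FEATURE_NAMES} - set(df.columns)
        if missing:
            raise ConfigError(f"training CSV missing columns: {sorted(missing)}")
        samples: dict[str, list[np.ndarray]] = {}
        for _, row in df.iterrows():
            tooth = parse_tooth_type(str(row["tooth_type"]))
            vec = np.array([float(row[n]) for n in FEATURE_NAMES])
            samples.setdefault(tooth.training_key, []).append(vec)
        return cls(samples)


def mismatch_cost(features: ToothFeatures, tooth: ToothType, training: TrainingSet) -> float:
    """Sum of squared per-feature z-scores against the type's statistics."""
    mean, std = training.lookup(tooth)
    z = (features.vector() - mean) / std
    return float(np.dot(z, z))


# ---------------------------------------------------------------------------
# assignment DP


@dataclass
class Assignment:
    """Monotone alignment of ordered blobs onto an arch template."""

    labels: list            # per blob: ToothType or None (discarded)
    total_cost: float
    skipped_slots: list = field(default_factory=list)  # ToothType of empty slots

    @property
    def n_discarded(self) -> int:
        return sum(1 for t in self.labels if t is None)

    def label_map(self) -> dict[int, "ToothType"]:
        return {i: t for i, t in enumerate(self.labels) if t is not None}


def assign_teeth(
    blobs,
    features,
    template: ArchTemplate,
    training: TrainingSet,
    gap_penalty: float = GAP_PENALTY,
    discard_penalty: float = DISCARD_PENALTY,
) -> Assignment:
    """Optimal monotone blob -> template labelling by dynamic programming.

    State (i, j): first ``i`` blobs consumed, first ``j`` template slots
    resolved.  Moves: match blob to slot (mismatch cost), skip a slot
    (missing tooth, ``gap_penalty``), discard a blob (``discard_penalty``),
    or spend two consecutive blobs on one molar slot via its mesial/distal
    half-types.  Ties break toward fewer discards, then toward the
    alignment that matches/pairs as early as possible.
    """
    n = len(blobs)
    m = len(template.slots)
    if n == 0:
        return Assignment(labels=[], total_cost=0.0,
                          skipped_slots=list(template.slots))
    feats = list(features)
    if len(feats) != n:
        raise ValueError("features must align with blobs")

    match_cost = np.full((n, m), np.inf)
    half_cost = np.full((n, m), np.inf)  # blobs i, i+1 -> slot j halves
    for j, slot in enumerate(template.slots):
        if slot in training:
            for i in range(n):
                match_cost[i, j] = mismatch_cost(feats[i], slot, training)
        if slot.is_molar:
            mesial, distal = slot.with_half(0), slot.with_half(1)
            if mesial in training and distal in training:
                for i in range(n - 1):
                    half_cost[i, j] = mismatch_cost(
                        feats[i], mesial, training
                    ) + mismatch_cost(feats[i + 1], distal, training)

    INF = np.inf
    cost = np.full((n + 1, m + 1), INF)
    disc = np.full((n + 1, m + 1), 10**9)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 match, 2 half, 3 skip, 4 discard
    cost[0, 0] = 0.0
    disc[0, 0] = 0

    # move preference encodes the tie-break: match < half-pair < skip < discard
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = (INF, 10**9, 9)
            if i >= 1 and j >= 1 and np.isfinite(match_cost[i - 1, j - 1]):
                c = cost[i - 1, j - 1] + match_cost[i - 1, j - 1]
                best = min(best, (c, disc[i - 1, j - 1], 1))
            if i >= 2 and j >= 1 and np.isfinite(half_cost[i - 2, j - 1]):
                c = cost[i - 2, j - 1] + half_cost[i - 2, j - 1]
                best = min(best, (c, disc[i - 2, j - 1], 2))
            if j >= 1:
                c = cost[i, j - 1] + gap_penalty
                best = min(best, (c, disc[i, j - 1], 3))
            if i >= 1:
                c = cost[i - 1, j] + discard_penalty
                best = min(best, (c, disc[i - 1, j] + 1, 4))
            cost[i, j], disc[i, j], move[i, j] = best[0], best[1], best[2]

    if not np.isfinite(cost[n, m]):
        raise DegenerateGeometryError("no feasible assignment")

    labels: list = [None] * n
    skipped: list = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 1:
            labels[i - 1] = template.slots[j - 1]
            i, j = i - 1, j - 1
        elif mv == 2:
            slot = template.slots[j - 1]
            labels[i - 2] = slot.with_half(0)
            labels[i - 1] = slot.with_half(1)
            i, j = i - 2, j - 1
        elif mv == 3:
            skipped.append(template.slots[j - 1])
            j -= 1
        elif mv == 4:
            i -= 1
        else:  # pragma: no cover
            raise RuntimeError("corrupt DP table")
    skipped.reverse()
    return Assignment(labels=labels, total_cost=float(cost[n, m]), skipped_slots=skipped)
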