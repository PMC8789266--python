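"""End-to-end recognition driver.

Order of stages: PCA axes -> sign disambiguation -> coarse peaks -> occlusal
refinement from the tooth-tip plane -> final peaks -> curvature field ->
region growing -> jawline fit -> blob merging -> features -> template
assignment -> landmarks.  Exactly one refinement iteration is run: the
vertical direction is the one that has to be accurate, and the tooth-tip
plane supplies it once coarse peaks exist.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np

from . import mhb_scoring
from .config import PipelineConfig
from .errors import RefinementSkipped, StageError
from .mesh_core import TriangleMesh, build_adjacency
from .orientation import ArchFrame, disambiguate_signs, pca_axes, refine_occlusal
from .peak_detection import find_peaks
from .tooth_assignment import (
    Assignment,
    TrainingSet,
    assign_teeth,
    build_template,
    compute_features,
)
from .tooth_partition import (
    edge_curvature,
    fit_jawline,
    grow_tooth_region,
    merge_blobs,
)

logger = logging.getLogger("dentmark")


@dataclass
class ResultReport:
    """Everything one recognition run produced, JSON-serializable."""

    jaw: str
    dentition: str
    frame: ArchFrame
    peak_count: int
    blob_count: int
    assignment: Assignment | None
    landmarks: dict = field(default_factory=dict)  # ToothType -> Landmark
    blobs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "jaw": self.jaw,
            "dentition": self.dentition,
            "frame": self.frame.to_dict() if self.frame else None,
            "peak_count": self.peak_count,
            "blob_count": self.blob_count,
            "labels": [str(t) if t else None for t in (self.assignment.labels if self.assignment else [])],
            "total_cost": self.assignment.total_cost if self.assignment else None,
            "skipped_slots": [str(t) for t in (self.assignment.skipped_slots if self.assignment else [])],
            "landmarks": {
                str(t): lm.position.tolist() for t, lm in self.landmarks.items()
            },
            "warnings": list(self.warnings),
            "failed_stage": self.failed_stage,
        }


def default_training_set() -> TrainingSet:
    """Packaged synthetic-derived training set (permanent + deciduous)."""
    ref = importlib.resources.files("dentmark").joinpath(
        "data/default_training_synthetic.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return TrainingSet.from_csv(path)


def load_training(config: PipelineConfig) -> TrainingSet:
    if config.training_set_path:
        return TrainingSet.from_csv(config.training_set_path)
    return default_training_set()


def patient_right_direction(frame: ArchFrame, jaw: str) -> np.ndarray:
    """Anatomical patient-right: anterior x body-up.

    Body-up equals the occlusal direction for a mandibular arch and its
    opposite for a maxillary one (whose occlusal surface faces down)."""
    body_up = frame.occlusal_axis if jaw == "L" else -frame.occlusal_axis
    return np.cross(frame.anteroposterior_axis, body_up)


def run_recognition(
    mesh: TriangleMesh,
    jaw: str,
    dentition: str,
    config: PipelineConfig | None = None,
    training: TrainingSet | None = None,
) -> ResultReport:
    """Full recognition of one arch mesh."""
    config = config or PipelineConfig()
    stage = "orientation"
    try:
        frame = disambiguate_signs(mesh, pca_axes(mesh))
        logger.info("orientation: frame %s", frame.to_dict())

        stage = "peaks"
        adj = build_adjacency(mesh)
        coarse = find_peaks(mesh, adj, frame, config.depth_threshold, config.ring)
        try:
            frame = refine_occlusal(frame, [p.position for p in coarse])
        except RefinementSkipped as exc:
            logger.warning("occlusal refinement skipped: %s", exc)
        peaks = find_peaks(mesh, adj, frame, config.depth_threshold, config.ring)
        logger.info("peaks: %d candidates", len(peaks))

        stage = "partition"
        curv = edge_curvature(mesh, adj)
        max_travel = config.max_travel(dentition)
        blobs = []
        for p in peaks:
            blob = grow_tooth_region(
                mesh, adj, curv, p, frame, config.stop_curvature, max_travel
            )
            p.spilled = blob.spilled
            blobs.append(blob)
        jawline = fit_jawline(peaks, frame)
        merged = merge_blobs(blobs, jawline, frame, config.merge_dist(dentition))
        # order along the arch from patient right to patient left
        pr = patient_right_direction(frame, jaw)
        if float(np.dot(frame.transverse_axis, pr)) > 0:
            merged = list(reversed(merged))
        logger.info("partition: %d blobs after merging", len(merged))

        stage = "assignment"
        training = training or load_training(config)
        template = build_template(jaw, dentition)
        feats = [compute_features(mesh, b, frame, jawline) for b in merged]
        assignment = assign_teeth(
            merged, feats, template, training,
            config.gap_penalty, config.discard_penalty,
        )

        stage = "landmarks"
        landmarks = {}
        i = 0
        while i < len(merged):
            t = assignment.labels[i]
            if t is None:
                i += 1
                continue
            if t.half == 0 and i + 1 < len(merged):
                # half-molar pair: landmark from the union of both halves
                from .tooth_partition import Blob

                union = Blob(
                    faces=merged[i].faces | merged[i + 1].faces,
                    peaks=merged[i].peaks + merged[i + 1].peaks,
                )
                whole = t.with_half(None)
                landmarks[whole] = mhb_scoring.extract_landmark(
                    mesh, union, whole, frame, jawline
                )
                i += 2
                continue
            landmarks[t] = mhb_scoring.extract_landmark(mesh, merged[i], t, frame, jawline)
            i += 1

        return ResultReport(
            jaw=jaw,
            dentition=dentition,
            frame=frame,
            peak_count=len(peaks),
            blob_count=len(merged),
            assignment=assignment,
            landmarks=landmarks,
            blobs=merged,
        )
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, str(exc)) from exc


def run_mhb(
    maxillary: ResultReport,
    mandibular: ResultReport,
    config: PipelineConfig | None = None,
):
    """MHB scorecard from two recognized, occlusion-registered arches."""
    config = config or PipelineConfig()
    max_lms = {t.with_half(None): lm for t, lm in maxillary.landmarks.items()}
    mand_lms = {t.with_half(None): lm for t, lm in mandibular.landmarks.items()}
    return mhb_scoring.score_arch_pair(
        max_lms,
        mand_lms,
        maxillary.assignment,
        mandibular.frame,
        maxillary.dentition,
        config.mhb,
    )
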