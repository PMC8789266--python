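"""Evaluation machinery: per-tooth outcome categories and landmark
deviation statistics.

Recognition quality is tallied per tooth into OK (found and correctly
labelled), PartitionError (not found) and WrongAssignment (found but
mislabelled), with WrongKind flagging the subset of wrong assignments where
even the tooth class (incisor/canine/premolar/molar) was wrong.  Landmark
accuracy is summarized as mean Euclidean deviation per tooth class plus a
geometric mean with a 95% confidence interval obtained by fitting a normal
distribution to log distances — the standard treatment for positive error
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .tooth_assignment import ToothType

JACCARD_FOUND_THRESHOLD = 0.3
LOG_FLOOR_MM = 1e-6


class Outcome(Enum):
    OK = "OK"
    PARTITION_ERROR = "Partition Error"
    WRONG_ASSIGNMENT = "Wrong Assignment"


@dataclass(frozen=True)
class OutcomeCategory:
    outcome: Outcome
    wrong_kind: bool = False

    def __post_init__(self):
        if self.wrong_kind and self.outcome is not Outcome.WRONG_ASSIGNMENT:
            raise ValueError("wrong_kind only valid with WrongAssignment")


def classify_outcome(true_label: ToothType | None, predicted: ToothType | None) -> OutcomeCategory:
    """Outcome of one tooth known to be present on the model.

    ``predicted`` is the label of the blob that found the tooth, or ``None``
    when no blob did.  Teeth absent from the model are excluded upstream.
    """
    if true_label is None:
        raise ValueError("true tooth absent: excluded from the tally")
    if predicted is None:
        return OutcomeCategory(Outcome.PARTITION_ERROR)
    t = true_label.with_half(None)
    p = predicted.with_half(None)
    if t == p:
        return OutcomeCategory(Outcome.OK)
    return OutcomeCategory(
        Outcome.WRONG_ASSIGNMENT, wrong_kind=t.tooth_class != p.tooth_class
    )


def match_predictions(truth, blobs, assignment, mesh=None):
    """Per truth tooth, the predicted label of the blob that found it.

    A blob "finds" a truth tooth when it contains the tooth's apex vertex
    region (any face of the blob belongs to the truth mask around the apex)
    or overlaps the truth mask with Jaccard >= 0.3.  Returns
    dict[ToothType -> ToothType | None].
    """
    labels = assignment.label_map()
    out = {}
    for t, tt in truth.teeth.items():
        mask = set(int(f) for f in tt.face_mask)
        if not mask:
            out[t] = None
            continue
        found = None
        best_overlap = 0.0
        for i, blob in enumerate(blobs):
            inter = len(mask & set(blob.faces))
            if inter == 0:
                continue
            jac = inter / len(mask | set(blob.faces))
            apex_hit = _contains_apex(blob, tt, mesh)
            if apex_hit or jac >= JACCARD_FOUND_THRESHOLD:
                score = jac + (1.0 if apex_hit else 0.0)
                if score > best_overlap:
                    best_overlap = score
                    found = i
        if found is None:
            out[t] = None
        else:
            lbl = labels.get(found)
            out[t] = lbl.with_half(None) if lbl is not None else None
    return out


def _contains_apex(blob, tt, mesh) -> bool:
    if mesh is None:
        return False
    apex = tt.top_apex.position
    faces = np.array(sorted(blob.faces), dtype=np.int64)
    d = np.linalg.norm(mesh.face_centroids[faces] - apex, axis=1)
    return bool(d.min() < 1.0)


@dataclass
class OutcomeTally:
    counts: pd.DataFrame       # rows OK/PartitionError/WrongAssignment/WrongKind
    percentages: pd.DataFrame  # same shape, % of per-group totals (1 decimal)
    totals: pd.Series


def tally_outcomes(categories, groups=None) -> OutcomeTally:
    """Counts and percentages per group and overall.

    ``categories``: iterable of OutcomeCategory; ``groups``: parallel group
    labels (``None`` for a single group).  WrongKind is reported as a
    sub-row of WrongAssignment and excluded from the total.
    """
    cats = list(categories)
    if groups is None:
        groups = ["all"] * len(cats)
    groups = list(groups)
    order = list(dict.fromkeys(groups))
    rows = ["OK", "Partition Error", "Wrong Assignment", "Wrong Kind"]
    counts = pd.DataFrame(0, index=rows, columns=order + ["Overall"])
    for cat, g in zip(cats, groups):
        counts.loc[cat.outcome.value, g] += 1
        counts.loc[cat.outcome.value, "Overall"] += 1
        if cat.wrong_kind:
            counts.loc["Wrong Kind", g] += 1
            counts.loc["Wrong Kind", "Overall"] += 1
    totals = counts.loc[rows[:3]].sum(axis=0)
    pct = counts.astype(float)
    for col in counts.columns:
        denom = totals[col]
        pct[col] = (
            np.round(100.0 * counts[col] / denom, 1) if denom else np.nan
        )
    return OutcomeTally(counts=counts, percentages=pct, totals=totals)


def tally_from_counts(ok, partition_error, wrong_assignment, wrong_kind=None,
                      group_names=None) -> OutcomeTally:
    """Tally directly from per-group count vectors (summary-table arithmetic)."""
    cats: list = []
    groups: list = []
    n = len(ok)
    names = group_names or [f"g{i}" for i in range(n)]
    wk = wrong_kind or [0] * n
    for i in range(n):
        cats += [OutcomeCategory(Outcome.OK)] * ok[i]
        cats += [OutcomeCategory(Outcome.PARTITION_ERROR)] * partition_error[i]
        nwk = wk[i]
        cats += [OutcomeCategory(Outcome.WRONG_ASSIGNMENT, wrong_kind=True)] * nwk
        cats += [OutcomeCategory(Outcome.WRONG_ASSIGNMENT)] * (wrong_assignment[i] - nwk)
        groups += [names[i]] * (ok[i] + partition_error[i] + wrong_assignment[i])
    return tally_outcomes(cats, groups)


# ---------------------------------------------------------------------------
# deviation statistics


@dataclass
class DeviationReport:
    per_class_mean: dict        # tooth class -> mean deviation, mm
    overall_mean: float         # mm
    geometric_mean: float       # mm
    ci_low: float
    ci_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "per_class_mean_mm": dict(self.per_class_mean),
            "overall_mean_mm": self.overall_mean,
            "geometric_mean_mm": self.geometric_mean,
            "ci95_mm": [self.ci_low, self.ci_high],
            "n": self.n,
        }


def geometric_mean_ci(distances, confidence_z: float = 1.96):
    """Geometric mean and CI from a normal fit to log distances."""
    d = np.maximum(np.asarray(distances, dtype=float), LOG_FLOOR_MM)
    logs = np.log(d)
    mu = logs.mean()
    se = logs.std(ddof=1) / np.sqrt(len(logs)) if len(logs) > 1 else 0.0
    return (
        float(np.exp(mu)),
        float(np.exp(mu - confidence_z * se)),
        float(np.exp(mu + confidence_z * se)),
    )


def deviation_stats(predicted_landmarks, consensus_landmarks) -> DeviationReport:
    """Deviation report between two landmark sets matched by tooth type.

    Accepts dicts ToothType -> Landmark (or any object with ``.position``).
    """
    pred = {t.with_half(None): lm for t, lm in predicted_landmarks.items()}
    cons = {t.with_half(None): lm for t, lm in consensus_landmarks.items()}
    common = sorted(set(pred) & set(cons), key=str)
    if len(common) < 2:
        raise ValueError("need >= 2 matched landmark pairs")
    dists = {}
    for t in common:
        dists[t] = float(
            np.linalg.norm(np.asarray(pred[t].position) - np.asarray(cons[t].position))
        )
    per_class: dict = {}
    for t, d in dists.items():
        per_class.setdefault(t.tooth_class, []).append(d)
    all_d = np.array(list(dists.values()))
    gm, lo, hi = geometric_mean_ci(all_d)
    return DeviationReport(
        per_class_mean={c: float(np.mean(v)) for c, v in sorted(per_class.items())},
        overall_mean=float(all_d.mean()),
        geometric_mean=gm,
        ci_low=lo,
        ci_high=hi,
        n=len(all_d),
    )
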