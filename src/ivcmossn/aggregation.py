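"""Hierarchical cell -> image -> patient aggregation and macro-average metrics.

Cell-level binary decisions are lifted to the image level by a majority
rule — an image is OSSN when at least 50% of its classified cells are
OSSN-related — and image decisions are lifted to the patient level the same
way: a patient is OSSN when at least half of their images are OSSN. Ties at
exactly one half resolve to OSSN at both levels ("at least"). The metric
suite reports per-class precision/recall/F1 from the confusion matrix and
their unweighted (macro) means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OSSN, NON_OSSN = "OSSN", "non_OSSN"

__all__ = [
    "AggregationError",
    "LevelAggregate",
    "MetricsReport",
    "aggregate_image",
    "aggregate_patient",
    "backpropagate",
    "macro_metrics",
]


class AggregationError(ValueError):
    """Raised for empty vote lists or inconsistent hierarchies."""


@dataclass(frozen=True)
class LevelAggregate:
    """Tallies behind one majority decision: ``o`` positive of ``n`` votes."""

    o: int
    n: int
    decision: bool

    @property
    def ratio(self) -> float:
        return self.o / self.n


def aggregate_image(cell_labels: Sequence[bool]) -> LevelAggregate:
    """Image-level decision: OSSN iff at least 50% of classified cells are OSSN.

    ``cell_labels`` holds one binary OSSN flag per classified cell of one
    image. An image with no classified cells has no defined label and raises.
    """
    n = len(cell_labels)
    if n == 0:
        raise AggregationError("an image with no classified cells has no defined label")
    o = int(np.count_nonzero(cell_labels))
    return LevelAggregate(o=o, n=n, decision=o / n >= 0.5)


def aggregate_patient(image_decisions: Sequence[bool]) -> LevelAggregate:
    """Patient-level decision: OSSN iff at least half the images are OSSN."""
    m = len(image_decisions)
    if m == 0:
        raise AggregationError("a patient with no labeled images has no defined label")
    p = int(np.count_nonzero(image_decisions))
    return LevelAggregate(o=p, n=m, decision=p / m >= 0.5)


@dataclass
class MetricsReport:
    """Macro-averaged classification metrics plus the per-class table.

    ``macro_accuracy`` is the unweighted mean of per-class recall (balanced
    accuracy); ``plain_accuracy`` is the usual fraction correct. Per-class
    precision/recall/F1 with a zero denominator contribute 0.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray  # rows: true, cols: predicted
    per_class: pd.DataFrame  # index: class; columns: precision, recall, f1, support
    macro_accuracy: float
    plain_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float

    @property
    def average_of_macros(self) -> float:
        """Mean of the four headline macro metrics (the fingerprint criterion)."""
        return float(
            np.mean(
                [self.macro_accuracy, self.macro_precision, self.macro_recall, self.macro_f1]
            )
        )

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="index"),
            "macro_accuracy": self.macro_accuracy,
            "plain_accuracy": self.plain_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def macro_metrics(
    true_labels: Sequence[Hashable],
    predicted_labels: Sequence[Hashable],
    classes: Sequence[Hashable] | None = None,
) -> MetricsReport:
    """Confusion matrix, per-class precision/recall/F1 and their macro means.

    ``classes`` fixes the class order (and admits classes absent from the
    records); by default the sorted union of observed labels is used.
    Predicted labels outside the class set raise a label error.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if not true_labels or len(true_labels) != len(predicted_labels):
        raise AggregationError("need equal, nonzero numbers of true and predicted labels")
    if classes is None:
        classes = sorted({str(t) for t in true_labels} | {str(p) for p in predicted_labels})
    classes = tuple(str(c) for c in classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        t, p = str(t), str(p)
        if t not in index or p not in index:
            unknown = t if t not in index else p
            raise AggregationError(f"label {unknown!r} not in class set {classes}")
        conf[index[t], index[p]] += 1

    tp = np.diag(conf).astype(float)
    pred_totals = conf.sum(axis=0).astype(float)
    true_totals = conf.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_totals > 0, tp / pred_totals, 0.0)
        recall = np.where(true_totals > 0, tp / true_totals, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": true_totals.astype(int),
        },
        index=list(classes),
    )
    return MetricsReport(
        classes=classes,
        confusion=conf,
        per_class=per_class,
        macro_accuracy=float(recall.mean()),
        plain_accuracy=float(tp.sum() / conf.sum()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


def backpropagate(
    cell_predictions: Mapping[str, Sequence[bool]],
    image_patients: Mapping[str, str],
    image_truth: Mapping[str, bool],
    patient_truth: Mapping[str, bool],
    cell_truth: Mapping[str, Sequence[bool]] | None = None,
) -> dict[str, MetricsReport]:
    """Lift per-cell binary predictions to image and patient decisions.

    ``cell_predictions`` maps image id -> predicted OSSN flag per cell;
    ``image_patients`` maps image id -> patient id. Majority aggregation is
    applied per image, then per patient, and a :class:`MetricsReport` is
    produced at each level against the supplied truth (cell level only when
    ``cell_truth`` is given). Images with zero classified cells are excluded
    from the patient tallies with a warning. Orphan images (unknown patient)
    raise a grouping error.
    """
    for image_id in cell_predictions:
        if image_id not in image_patients:
            raise AggregationError(f"image {image_id!r} has no patient assignment")

    reports: dict[str, MetricsReport] = {}
    if cell_truth is not None:
        truths, preds = [], []
        for image_id, labels in cell_predictions.items():
            t = list(cell_truth[image_id])
            if len(t) != len(labels):
                raise AggregationError(f"cell truth/prediction mismatch for {image_id!r}")
            truths += t
            preds += list(labels)
        reports["cell"] = macro_metrics(
            [OSSN if x else NON_OSSN for x in truths],
            [OSSN if x else NON_OSSN for x in preds],
            classes=(NON_OSSN, OSSN),
        )

    image_decisions: dict[str, bool] = {}
    for image_id, labels in cell_predictions.items():
        if len(labels) == 0:
            logger.warning("image %s has no classified cells; excluded from tallies", image_id)
            continue
        image_decisions[image_id] = aggregate_image(labels).decision
    if not image_decisions:
        raise AggregationError("no image has any classified cells")
    reports["image"] = macro_metrics(
        [OSSN if image_truth[i] else NON_OSSN for i in image_decisions],
        [OSSN if d else NON_OSSN for d in image_decisions.values()],
        classes=(NON_OSSN, OSSN),
    )

    per_patient: dict[str, list[bool]] = {}
    for image_id, decision in image_decisions.items():
        per_patient.setdefault(image_patients[image_id], []).append(decision)
    patient_decisions = {
        pid: aggregate_patient(decisions).decision for pid, decisions in per_patient.items()
    }
    reports["patient"] = macro_metrics(
        [OSSN if patient_truth[p] else NON_OSSN for p in patient_decisions],
        [OSSN if d else NON_OSSN for d in patient_decisions.values()],
        classes=(NON_OSSN, OSSN),
    )
    return reports
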