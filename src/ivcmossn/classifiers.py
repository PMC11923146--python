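"""Desk-scale classifiers for the five analysis tasks.

Tasks: healthy-vs-OSSN whole images, four-way sign classification of square
tiles, its merged binary variant (all OSSN signs vs other), binary cell
classification, and the patient-identity "fingerprint" experiment. All share
one small-CNN backbone (:class:`~ivcmossn.nn.SmallCNN`); the rare-sign path
adds a prototypical few-shot classifier over the CNN's penultimate
embedding with leave-one-out evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol, Sequence

import numpy as np
from skimage import transform as sktransform

from .aggregation import MetricsReport, macro_metrics
from .nn import SmallCNN, TrainHistory
from .preprocess import IvcmImage, crop_footer
from .synthetic import GroundTruth
from .tiling import OSSN_SIGN_CLASSES, extract_tile_pixels, split_rectangle

TASKS = (
    "healthy_vs_ossn",
    "sign_4class",
    "sign_binary_merged",
    "cell_binary",
    "patient_identity",
)

__all__ = [
    "TASKS",
    "TaskSpec",
    "TrainConfig",
    "LabeledSet",
    "PredictionRecord",
    "DataError",
    "merge_binary_label",
    "image_dataset",
    "sign_tile_dataset",
    "train",
    "predict",
    "few_shot_episode",
    "leave_one_out",
    "fingerprint_experiment",
]


class DataError(ValueError):
    """Raised for datasets that cannot support the requested task."""


def merge_binary_label(sign_class: str) -> str:
    """Collapse sign labels for the merged binary task: OSSN signs vs other."""
    return "OSSN" if sign_class in OSSN_SIGN_CLASSES else "other"


@dataclass(frozen=True)
class TaskSpec:
    """One classification task: its name, ordered class list and input size."""

    task: str
    classes: tuple[str, ...]
    input_side: int = 32

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise DataError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if len(self.classes) < 2:
            raise DataError("a classification task needs at least 2 classes")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (declared configuration, not clinical claims).

    ``class_weighting='inverse'`` applies inverse-frequency class weights to
    counter imbalance; ``channels`` is the small-CNN width schedule.
    """

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 3e-3
    seed: int = 0
    class_weighting: str | None = "inverse"
    channels: tuple[int, ...] = (8, 16, 32)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise DataError("epochs must be >= 1")


@dataclass
class LabeledSet:
    """A stack of square inputs with labels and grouping metadata."""

    x: np.ndarray  # (N, side, side) float in [0, 1]
    labels: list[str]
    item_ids: list[str]
    patient_ids: list[str]
    group_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, keep: Sequence[int] | np.ndarray) -> "LabeledSet":
        keep = np.asarray(keep)
        return LabeledSet(
            x=self.x[keep],
            labels=[self.labels[i] for i in keep],
            item_ids=[self.item_ids[i] for i in keep],
            patient_ids=[self.patient_ids[i] for i in keep],
            group_ids=[self.group_ids[i] for i in keep] if self.group_ids else [],
        )

    def subset_by_ids(self, ids: set[str]) -> "LabeledSet":
        return self.subset([i for i, item in enumerate(self.item_ids) if item in ids])


@dataclass(frozen=True)
class PredictionRecord:
    """One scored prediction at cell, image or patient level."""

    entity_id: str
    level: str
    true_label: str
    predicted_label: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.scores.values())
        if abs(total - 1.0) > 1e-6 or any(v < 0 for v in self.scores.values()):
            raise ValueError("scores must be nonnegative and sum to 1")


def _resize(pixels: np.ndarray, side: int) -> np.ndarray:
    img = np.asarray(pixels, dtype=float) / 255.0
    if img.shape == (side, side):
        return img
    return sktransform.resize(img, (side, side), order=1, anti_aliasing=True)


def image_dataset(
    images: Sequence[IvcmImage],
    truth: GroundTruth,
    task: TaskSpec,
) -> LabeledSet:
    """Build whole-image inputs for the image-level tasks.

    ``healthy_vs_ossn`` keeps only normal (-> ``healthy``) and OSSN images;
    ``patient_identity`` labels every image with its patient id. Footers are
    cropped on the fly; content is rescaled to ``task.input_side``.
    """
    xs, labels, ids, pids = [], [], [], []
    for image in images:
        content = image if image.footer_removed else crop_footer(image)
        if task.task == "healthy_vs_ossn":
            if image.class_label == "normal":
                label = "healthy"
            elif image.class_label == "OSSN":
                label = "OSSN"
            else:
                continue
        elif task.task == "patient_identity":
            label = image.patient_id
        else:
            raise DataError(f"image_dataset does not serve task {task.task!r}")
        xs.append(_resize(content.pixels, task.input_side))
        labels.append(label)
        ids.append(image.image_id)
        pids.append(image.patient_id)
    if not xs:
        raise DataError("no images matched the task's class filter")
    return LabeledSet(np.stack(xs), labels, ids, pids)


def sign_tile_dataset(
    images: Sequence[IvcmImage],
    truth: GroundTruth,
    input_side: int = 32,
    merged: bool = False,
) -> LabeledSet:
    """Cut every annotation into square tiles and label them by sign class.

    With ``merged=True`` the four OSSN signs collapse to ``OSSN`` and the
    distractor class to ``other``. Tiles carry their annotation id as
    ``group_id`` so grouped splitting can keep sibling tiles together.
    """
    content_by_id = {}
    for image in images:
        content_by_id[image.image_id] = (
            image if image.footer_removed else crop_footer(image)
        )
    xs, labels, ids, pids, gids = [], [], [], [], []
    for ann in truth.annotations:
        image = content_by_id.get(ann.image_id)
        if image is None:
            continue
        for tile in split_rectangle(ann):
            block = extract_tile_pixels(image.pixels, tile)
            xs.append(_resize(block, input_side))
            labels.append(merge_binary_label(ann.sign_class) if merged else ann.sign_class)
            ids.append(tile.tile_id)
            pids.append(image.patient_id)
            gids.append(tile.group_id)
    if not xs:
        raise DataError("no annotations yielded any tiles")
    return LabeledSet(np.stack(xs), labels, ids, pids, gids)


def _class_weights(labels: Sequence[str], classes: Sequence[str], mode: str | None) -> np.ndarray:
    counts = np.array([sum(1 for l in labels if l == c) for c in classes], dtype=float)
    empty = [c for c, n in zip(classes, counts) if n == 0]
    if empty:
        raise DataError(f"training data has no examples of class(es) {empty}")
    if mode == "inverse":
        w = counts.sum() / (len(classes) * counts)
        return w / w.mean()
    return np.ones(len(classes))


def train(
    train_set: LabeledSet,
    task: TaskSpec,
    config: TrainConfig,
    val_set: LabeledSet | None = None,
) -> tuple[SmallCNN, TrainHistory]:
    """Train the small CNN for ``task`` and return it with its learning curves.

    Labels must be a subset of ``task.classes`` (splitting happens upstream).
    The run is reproducible given the config seed.
    """
    unknown = set(train_set.labels) - set(task.classes)
    if unknown:
        raise DataError(f"labels {sorted(unknown)} not in task classes {task.classes}")
    class_index = {c: i for i, c in enumerate(task.classes)}
    y = np.array([class_index[l] for l in train_set.labels])
    weights = _class_weights(train_set.labels, task.classes, config.class_weighting)
    model = SmallCNN(
        task.input_side, len(task.classes), channels=config.channels, seed=config.seed
    )
    x_val = y_val = None
    if val_set is not None and len(val_set):
        x_val = val_set.x
        y_val = np.array([class_index[l] for l in val_set.labels])
    history = model.fit(
        train_set.x,
        y,
        x_val,
        y_val,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        class_weights=weights,
        seed=config.seed + 1,
    )
    return model, history


def predict(
    model: SmallCNN,
    items: LabeledSet,
    task: TaskSpec,
    level: str = "image",
) -> list[PredictionRecord]:
    """Score items with a trained model; argmax of scores is the prediction."""
    if len(items) == 0:
        return []
    if items.x.shape[-1] != task.input_side:
        raise ValueError(
            f"items have side {items.x.shape[-1]}, task expects {task.input_side}"
        )
    probs = model.predict_proba(items.x)
    records = []
    for i in range(len(items)):
        scores = {c: float(p) for c, p in zip(task.classes, probs[i])}
        records.append(
            PredictionRecord(
                entity_id=items.item_ids[i],
                level=level,
                true_label=items.labels[i],
                predicted_label=task.classes[int(probs[i].argmax())],
                scores=scores,
            )
        )
    return records


# ---------------------------------------------------------------------------
# few-shot prototypical classification
# ---------------------------------------------------------------------------


class Embedder(Protocol):
    def embed(self, x: np.ndarray) -> np.ndarray: ...


class EpisodeError(ValueError):
    """Raised for malformed few-shot episodes."""


def few_shot_episode(
    support_x: np.ndarray,
    support_labels: Sequence[str],
    query_x: np.ndarray,
    embedder: Embedder,
) -> list[str]:
    """Prototypical rule: assign each query to the nearest class-mean embedding.

    Every class present in the support set contributes one prototype (the
    Euclidean mean of its support embeddings); queries take the label of the
    nearest prototype.
    """
    support_labels = list(support_labels)
    if len(support_labels) != len(support_x):
        raise EpisodeError("support labels and inputs differ in length")
    classes = sorted(set(support_labels))
    if not classes:
        raise EpisodeError("empty support set")
    emb_support = embedder.embed(np.asarray(support_x))
    emb_query = embedder.embed(np.asarray(query_x))
    prototypes = np.stack(
        [
            emb_support[[i for i, l in enumerate(support_labels) if l == c]].mean(axis=0)
            for c in classes
        ]
    )
    d2 = ((emb_query[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    return [classes[int(i)] for i in d2.argmin(axis=1)]


def leave_one_out(
    x: np.ndarray, labels: Sequence[str], embedder: Embedder
) -> dict[str, float]:
    """Leave-one-out prototypical evaluation; per-class recall table.

    Each item is classified with all remaining items as support. Classes
    with fewer than 2 items cannot act as their own support and raise a
    protocol error.
    """
    labels = list(labels)
    counts: dict[str, int] = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    thin = sorted(c for c, n in counts.items() if n < 2)
    if thin:
        raise EpisodeError(f"leave-one-out needs >= 2 items per class; too few: {thin}")
    emb = embedder.embed(np.asarray(x))
    classes = sorted(counts)
    sums = {c: emb[[i for i, l in enumerate(labels) if l == c]].sum(axis=0) for c in classes}
    hits = {c: 0 for c in classes}
    for i, label in enumerate(labels):
        prototypes = []
        for c in classes:
            if c == label:
                prototypes.append((sums[c] - emb[i]) / (counts[c] - 1))
            else:
                prototypes.append(sums[c] / counts[c])
        d2 = ((np.stack(prototypes) - emb[i]) ** 2).sum(axis=1)
        if classes[int(d2.argmin())] == label:
            hits[label] += 1
    return {c: hits[c] / counts[c] for c in classes}


# ---------------------------------------------------------------------------
# patient-fingerprint experiment
# ---------------------------------------------------------------------------


class ExperimentError(ValueError):
    """Raised when the fingerprint experiment cannot be set up."""


def fingerprint_experiment(
    images: Sequence[IvcmImage],
    config: TrainConfig,
    input_side: int = 48,
    val_fraction: float = 0.3,
) -> tuple[MetricsReport, bool, TrainHistory]:
    """Do IVCM images carry patient-specific texture?

    Trains the patient-identity task (class label = patient id) on a
    per-patient 70/30 image split and reports validation macro metrics. The
    verdict is positive — the images hold patient-specific information —
    iff the average of macro accuracy, precision, recall and F1 exceeds 0.5.
    A patient-grouped split is impossible here (the patient *is* the label),
    so the split separates images, never pixels, across the boundary.
    """
    patients = sorted({im.patient_id for im in images})
    if len(patients) < 2:
        raise ExperimentError("fingerprint experiment needs at least 2 patients")
    task = TaskSpec("patient_identity", tuple(patients), input_side=input_side)

    rng = np.random.default_rng(config.seed)
    by_patient: dict[str, list[int]] = {p: [] for p in patients}
    for i, im in enumerate(images):
        by_patient[im.patient_id].append(i)
    train_idx, val_idx = [], []
    for p in patients:
        idx = np.array(by_patient[p])
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        if n_val >= len(idx):
            raise ExperimentError(f"patient {p} has too few images to split")
        val_idx += idx[:n_val].tolist()
        train_idx += idx[n_val:].tolist()

    xs = np.stack(
        [
            _resize((im if im.footer_removed else crop_footer(im)).pixels, input_side)
            for im in images
        ]
    )
    labels = [im.patient_id for im in images]
    ids = [im.image_id for im in images]
    full = LabeledSet(xs, labels, ids, labels)
    train_set, val_set = full.subset(train_idx), full.subset(val_idx)

    model, history = train(train_set, task, config, val_set)
    records = predict(model, val_set, task, level="image")
    report = macro_metrics(
        [r.true_label for r in records],
        [r.predicted_label for r in records],
        classes=task.classes,
    )
    verdict = report.average_of_macros > 0.5
    return report, verdict, history
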