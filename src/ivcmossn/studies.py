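"""Simulation studies: the package's headline experiments in reusable form.

Each study fixes its cohort design (the study conditions) and takes only a
seed, so the same experiment backs both the test suite and the
reproducibility script. All cohorts here are synthetic; sizes are chosen to
run on a single CPU core in minutes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .aggregation import backpropagate, macro_metrics
from .classifiers import (
    TaskSpec,
    TrainConfig,
    fingerprint_experiment,
    leave_one_out,
    predict,
    sign_tile_dataset,
    train,
)
from .split import SplitItem, grouped_split
from .synthetic import CohortConfig, generate_cohort, simulate_cell_predictions

__all__ = [
    "aggregation_study",
    "few_shot_study",
    "fingerprint_study",
    "sign_binary_study",
]


def _modal(values: list[float]) -> float:
    counts = Counter(round(v, 6) for v in values)
    return max(counts, key=lambda v: (counts[v], v))


@dataclass(frozen=True)
class AggregationStudyResult:
    """Macro F1 after lifting noisy cell predictions up the hierarchy."""

    patient_f1_modal: float  # at the reference error rate, modal over seeds
    patient_f1_per_seed: tuple[float, ...]
    image_f1_by_rate: dict[float, float]  # mean macro F1 per error rate
    image_f1_min: float


def aggregation_study(
    seed: int = 0,
    error_rates: tuple[float, ...] = (0.15, 0.12, 0.10),
    reference_rate: float = 0.12,
    n_seeds: int = 10,
) -> AggregationStudyResult:
    """Twin of the cell -> image -> patient aggregation experiment.

    Cohort: 20 patients (10 OSSN, 10 non-OSSN), 27 images each, 30 labeled
    cells per image. Each cell's true label is flipped independently at the
    given error rate (emulating a cell classifier of that accuracy), then
    the majority rules produce image and patient decisions. Image-level
    macro F1 is averaged per rate over ``n_seeds`` noise draws; the
    patient-level result at the reference rate is the modal value.
    """
    config = CohortConfig(
        n_patients=20,
        images_per_patient_mean=27,
        images_per_patient_dispersion=0,
        cells_per_image_mean=30,
        cells_per_image_dispersion=0,
        class_mix={"OSSN": 0.5, "normal": 0.5},
        stratify_classes=True,
        seed=seed,
    )
    _, truth = generate_cohort(config, render=False)
    image_truth = {i: truth.image_is_ossn(i) for i in truth.cells}
    patient_truth = {p: truth.patient_is_ossn(p) for p in truth.patients}

    image_f1_by_rate: dict[float, float] = {}
    patient_f1s: list[float] = []
    for rate in error_rates:
        image_f1s = []
        for k in range(n_seeds):
            noise_seed = (seed * 1_000 + int(rate * 100) * 17 + k) % (2**31)
            preds = dict(simulate_cell_predictions(truth, rate, noise_seed))
            cell_preds = {
                i: [preds[c.cell_id] for c in truth.cells[i]] for i in truth.cells
            }
            reports = backpropagate(cell_preds, truth.image_patients, image_truth, patient_truth)
            image_f1s.append(reports["image"].macro_f1)
            if rate == reference_rate:
                patient_f1s.append(reports["patient"].macro_f1)
        image_f1_by_rate[rate] = float(np.mean(image_f1s))
    return AggregationStudyResult(
        patient_f1_modal=_modal(patient_f1s),
        patient_f1_per_seed=tuple(patient_f1s),
        image_f1_by_rate=image_f1_by_rate,
        image_f1_min=min(image_f1_by_rate.values()),
    )


@dataclass(frozen=True)
class FewShotStudyResult:
    mitosis_recall_modal: float
    mitosis_recall_per_seed: tuple[float, ...]
    other_recall_mean: float
    n_mitosis_tiles: int
    n_tiles: int = 0


def few_shot_study(seed: int = 0, n_seeds: int = 3, epochs: int = 30) -> FewShotStudyResult:
    """Leave-one-out prototypical classification of the rarest sign.

    Cohort: 10 patients dominated by OSSN with exactly 3 mitosis annotations
    cohort-wide and tens of tiles for every other sign class. The small-CNN
    embedder is trained on the non-mitosis tiles only (mitosis stays unseen,
    as a genuinely rare class would); every tile is then classified
    leave-one-out by the nearest class-prototype rule. Reported per
    embedder seed; the headline number is the modal mitosis recall.
    """
    config = CohortConfig(
        n_patients=10,
        images_per_patient_mean=8,
        images_per_patient_dispersion=0,
        class_mix={"OSSN": 0.7, "melanoma": 0.15, "keratitis": 0.15},
        mitosis_total=3,
        seed=seed + 9,
    )
    images, truth = generate_cohort(config)
    tiles = sign_tile_dataset(images, truth, input_side=32)
    support = tiles.subset([i for i, l in enumerate(tiles.labels) if l != "mitosis"])
    task = TaskSpec("sign_4class", tuple(sorted(set(support.labels))), input_side=32)

    mitosis_recalls, other_means = [], []
    for k in range(n_seeds):
        model, _ = train(support, task, TrainConfig(epochs=epochs, seed=seed + k))
        recalls = leave_one_out(tiles.x, tiles.labels, model)
        mitosis_recalls.append(recalls["mitosis"])
        other_means.append(np.mean([v for c, v in recalls.items() if c != "mitosis"]))
    return FewShotStudyResult(
        mitosis_recall_modal=_modal(mitosis_recalls),
        mitosis_recall_per_seed=tuple(mitosis_recalls),
        other_recall_mean=float(np.mean(other_means)),
        n_mitosis_tiles=sum(l == "mitosis" for l in tiles.labels),
        n_tiles=len(tiles),
    )


@dataclass(frozen=True)
class FingerprintStudyResult:
    average_metrics_per_seed: tuple[float, ...]
    average_metrics_min: float
    verdicts: tuple[bool, ...]
    n_val_images: int = 0


def fingerprint_study(
    seed: int = 0,
    fingerprint_strength: float = 0.5,
    n_seeds: int = 3,
    epochs: int = 100,
) -> FingerprintStudyResult:
    """Patient-identity classification on planted per-patient texture.

    Cohort: 9 patients, ~15 images each; classifier trained for 100 epochs
    on a per-patient 70/30 image split. The reported quantity is the average
    of macro accuracy, precision, recall and F1 on validation; images hold
    patient-specific information when it exceeds 0.5.
    """
    averages, verdicts = [], []
    n_val = 0
    for k in range(n_seeds):
        config = CohortConfig(
            n_patients=9,
            images_per_patient_mean=15,
            images_per_patient_dispersion=0,
            class_mix={"OSSN": 0.4, "normal": 0.6},
            fingerprint_strength=fingerprint_strength,
            seed=seed + 42 + 101 * k,
        )
        images, _ = generate_cohort(config)
        report, verdict, _ = fingerprint_experiment(
            images, TrainConfig(epochs=epochs, seed=seed + k + 1), input_side=48
        )
        averages.append(report.average_of_macros)
        verdicts.append(verdict)
        n_val = int(report.per_class["support"].sum())
    return FingerprintStudyResult(
        average_metrics_per_seed=tuple(averages),
        average_metrics_min=min(averages),
        verdicts=tuple(verdicts),
        n_val_images=n_val,
    )


@dataclass(frozen=True)
class SignBinaryStudyResult:
    val_macro_f1: float
    n_train: int
    n_val: int


def sign_binary_study(seed: int = 0, epochs: int = 30) -> SignBinaryStudyResult:
    """End-to-end merged-binary sign classification on a grouped split.

    Tiles cut from OSSN sign rectangles vs non-OSSN distractor rectangles,
    split patient-wise (and annotation-group-wise) 70/30, classified by the
    small CNN; reports validation macro F1.
    """
    config = CohortConfig(
        n_patients=14,
        images_per_patient_mean=6,
        images_per_patient_dispersion=0,
        class_mix={"OSSN": 0.5, "melanoma": 0.2, "pterygium": 0.15, "keratitis": 0.15},
        sign_frequencies={
            "starry_sky": 1.1,
            "hyperkeratosis": 0.7,
            "irregular_cells": 0.9,
            "non_ossn": 2.2,
        },
        mitosis_total=3,
        stratify_classes=True,
        seed=seed + 17,
    )
    images, truth = generate_cohort(config)
    tiles = sign_tile_dataset(images, truth, input_side=32, merged=True)
    items = [
        SplitItem(t, p, g)
        for t, p, g in zip(tiles.item_ids, tiles.patient_ids, tiles.group_ids)
    ]
    plan = grouped_split(items, val_fraction=0.3, seed=seed + 7)
    train_set = tiles.subset_by_ids(set(plan.train_ids))
    val_set = tiles.subset_by_ids(set(plan.val_ids))
    task = TaskSpec("sign_binary_merged", ("OSSN", "other"), input_side=32)
    model, _ = train(train_set, task, TrainConfig(epochs=epochs, seed=seed), val_set)
    records = predict(model, val_set, task)
    report = macro_metrics(
        [r.true_label for r in records],
        [r.predicted_label for r in records],
        classes=task.classes,
    )
    return SignBinaryStudyResult(
        val_macro_f1=report.macro_f1, n_train=len(train_set), n_val=len(val_set)
    )
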