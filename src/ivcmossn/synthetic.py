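"""Synthetic IVCM cohort generator.

Stands in for a private clinical image collection: it emits per-patient
series of 384 x 484 grayscale snapshots (content mosaic plus a
meta-information footer band), rectangle annotations for the four
OSSN-related signs, per-cell ground-truth masks and binary OSSN labels, and
a per-patient texture "fingerprint" that perturbs the background mosaic.

The healthy content texture is a Voronoi-like polygonal cell mosaic with
bright, slightly blurred borders and dark interiors — segmentable by a
watershed-style segmenter. OSSN images carry planted sign regions:

* ``starry_sky``  — scattered hyperreflective nuclei on a darkened field;
* ``hyperkeratosis`` — a large bright amorphous keratinized patch;
* ``mitosis``     — a paired-nucleus figure (extremely rare; capped
  cohort-wide, 3 by default);
* ``irregular_cells`` — enlarged, high-variance polygonal cells.

Melanoma, pterygium and keratitis variants only need to be mutually
distinguishable, not photorealistic. Everything is driven by one integer
seed; regeneration with the same configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .preprocess import CONTENT_SIDE, FOOTER_HEIGHT, IMAGE_CLASSES, IvcmImage, RAW_HEIGHT
from .tiling import OSSN_SIGN_CLASSES, RectAnnotation

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "CellRecord",
    "GroundTruth",
    "ConfigurationError",
    "generate_cohort",
    "simulate_cell_predictions",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


def _paper_class_mix() -> dict[str, float]:
    # image-class composition of the study dataset (2,774 images)
    counts = {"OSSN": 745, "normal": 1559, "melanoma": 270, "pterygium": 115, "keratitis": 85}
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults mirror the clinical dataset the generator emulates: five image
    classes with OSSN a minority (~27%), 27.7 images per patient on average,
    and a cohort-wide cap of 3 mitosis annotations. ``fingerprint_strength``
    in [0, 1] scales how far each patient's texture parameters deviate from
    the cohort base; 0 makes all patients texturally identical.
    """

    n_patients: int = 20
    class_mix: dict[str, float] = field(default_factory=_paper_class_mix)
    images_per_patient_mean: float = 27.7
    images_per_patient_dispersion: float = 0.15
    cells_per_image_mean: float = 170.0
    cells_per_image_dispersion: float = 0.08
    sign_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            "starry_sky": 1.1,
            "hyperkeratosis": 0.7,
            "irregular_cells": 0.9,
            "non_ossn": 1.0,  # distractor rectangles on non-OSSN pathology images
        }
    )
    mitosis_total: int = 3
    ossn_cell_fraction: float = 0.8
    stray_ossn_cell_fraction: float = 0.1
    fingerprint_strength: float = 0.3
    cell_error_rate: float = 0.12
    #: assign patient classes by largest-remainder quota instead of sampling,
    #: so class counts match class_mix exactly (controlled designs).
    stratify_classes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix proportions must sum to 1 within 1e-9")
        if any(p < 0 for p in self.class_mix.values()):
            raise ConfigurationError("class_mix proportions must be nonnegative")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be strictly positive")
        if self.images_per_patient_mean <= 0 or self.cells_per_image_mean <= 0:
            raise ConfigurationError("mean counts must be strictly positive")
        if self.mitosis_total < 0:
            raise ConfigurationError("mitosis_total must be >= 0")
        if not 0.0 <= self.cell_error_rate <= 1.0:
            raise ConfigurationError("cell_error_rate must be a probability")
        if not 0.0 <= self.fingerprint_strength <= 1.0:
            raise ConfigurationError("fingerprint_strength must lie in [0, 1]")
        unknown = set(self.class_mix) - set(IMAGE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown image classes in class_mix: {sorted(unknown)}")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: diagnosis class plus texture fingerprint.

    The fingerprint vector is (cell-diameter scale, border-brightness scale,
    global intensity offset, anisotropy parameter); the cohort base is
    ``(1, 1, 0, 0)`` and deviations scale with ``fingerprint_strength``.
    """

    patient_id: str
    class_label: str
    fingerprint: tuple[float, float, float, float]


@dataclass(frozen=True)
class CellRecord:
    """One ground-truth cell with its binary OSSN-related label."""

    cell_id: str
    image_id: str
    label: bool  # True = OSSN-related


@dataclass
class GroundTruth:
    """Complete labels for a generated cohort."""

    patients: dict[str, PatientRecord]
    image_patients: dict[str, str]
    image_labels: dict[str, str]
    annotations: list[RectAnnotation]
    cells: dict[str, list[CellRecord]]
    #: per-image integer label map over the content area (0 = border/background,
    #: k >= 1 = cell k); present only for rendered cohorts.
    cell_label_maps: dict[str, np.ndarray] = field(default_factory=dict)

    def patient_is_ossn(self, patient_id: str) -> bool:
        return self.patients[patient_id].class_label == "OSSN"

    def image_is_ossn(self, image_id: str) -> bool:
        return self.image_labels[image_id] == "OSSN"

    def all_cells(self) -> list[CellRecord]:
        return [c for image_id in sorted(self.cells) for c in self.cells[image_id]]


# ---------------------------------------------------------------------------
# texture primitives
# ---------------------------------------------------------------------------

_BASE_FINGERPRINT = np.array([1.0, 1.0, 0.0, 0.0])
_FP_SCALES = np.array([0.22, 0.30, 25.0, 0.8])
_FOOTER_SEED = 0x5EED  # footer is patient- and class-independent by design


def _count_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Integer count around ``mean``; negative-binomial when over-dispersed.

    ``dispersion`` is the coefficient of extra variation: the count variance
    is ``mean + (dispersion * mean) ** 2``. Zero dispersion returns the
    rounded mean exactly.
    """
    if dispersion <= 0:
        return max(1, int(round(mean)))
    extra_var = (dispersion * mean) ** 2
    # negative binomial with matching mean/variance: var = mean + mean^2 / r
    r = mean**2 / extra_var
    p = r / (r + mean)
    return max(1, int(rng.negative_binomial(r, p)))


def _mosaic(
    side: int,
    n_cells: int,
    rng: np.random.Generator,
    diam_scale: float = 1.0,
    border_scale: float = 1.0,
    offset: float = 0.0,
    aniso: float = 0.0,
    interior_level: float = 55.0,
    border_level: float = 165.0,
    border_width: float = 2.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a polygonal cell mosaic and its interior label map.

    Cell centers sit on a jittered grid; per-pixel intensity follows the gap
    between the nearest and second-nearest center (bright ridges along the
    Voronoi borders, dark interiors). Returns ``(float image, int label map)``
    where label ``k >= 1`` marks the interior of cell ``k`` (pairwise
    disjoint, borders excluded).
    """
    n_eff = max(4, int(round(n_cells / (diam_scale**2))))
    g = max(2, int(round(np.sqrt(n_eff))))
    spacing = side / g
    gx, gy = np.meshgrid(np.arange(g), np.arange(g))
    centers = np.column_stack(
        [
            (gx.ravel() + 0.5) * spacing + rng.uniform(-0.45, 0.45, g * g) * spacing,
            (gy.ravel() + 0.5) * spacing + rng.uniform(-0.45, 0.45, g * g) * spacing,
        ]
    )
    theta = aniso
    m = 0.3 * np.tanh(aniso)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    stretch = np.diag([1.0 + m, 1.0 / (1.0 + m)])
    transform = rot.T @ stretch @ rot

    yy, xx = np.mgrid[0:side, 0:side]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(centers @ transform.T)
    dist, idx = tree.query(pix @ transform.T, k=2)
    ridge = np.exp(-(((dist[:, 1] - dist[:, 0]) / border_width) ** 2))
    cell_tone = rng.normal(0.0, 7.0, len(centers))
    interior = interior_level + cell_tone[idx[:, 0]]
    img = interior + (border_level * border_scale - interior) * ridge + offset
    img = img.reshape(side, side)

    labels = np.where(ridge < 0.35, idx[:, 0] + 1, 0).reshape(side, side)
    return img, labels


def _footer(rng: np.random.Generator) -> np.ndarray:
    """Pseudo-text meta-information band (constant across the cohort)."""
    footer = np.full((FOOTER_HEIGHT, CONTENT_SIDE), 18.0)
    for row in range(12, FOOTER_HEIGHT - 8, 18):
        x = 10
        while x < CONTENT_SIDE - 30:
            w = int(rng.integers(8, 28))
            if rng.random() < 0.75:
                footer[row : row + 9, x : x + w] = 205.0
            x += w + int(rng.integers(4, 12))
    return footer


def _random_rect(
    rng: np.random.Generator, lo: int, hi: int, forbid: list[tuple[int, int, int, int]]
) -> tuple[int, int, int, int] | None:
    """Draw a rectangle inside the content area avoiding existing ones."""
    for _ in range(40):
        w = int(rng.integers(lo, hi))
        h = int(rng.integers(lo, hi))
        x = int(rng.integers(0, CONTENT_SIDE - w))
        y = int(rng.integers(0, CONTENT_SIDE - h))
        clash = any(
            x < fx + fw and fx < x + w and y < fy + fh and fy < y + h
            for fx, fy, fw, fh in forbid
        )
        if not clash:
            return x, y, w, h
    return None


def _render_sign(
    content: np.ndarray, rect: tuple[int, int, int, int], sign: str, rng: np.random.Generator
) -> None:
    """Paint one sign texture into ``content`` (in place) over ``rect``."""
    x, y, w, h = rect
    patch = content[y : y + h, x : x + w]
    if sign == "starry_sky":
        patch *= 0.5
        n_dots = max(6, (w * h) // 350)
        for _ in range(n_dots):
            cx, cy = rng.uniform(2, w - 2), rng.uniform(2, h - 2)
            yy, xx = np.mgrid[0:h, 0:w]
            patch += 150.0 * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 1.8**2)))
    elif sign == "hyperkeratosis":
        blob = ndimage.gaussian_filter(rng.normal(size=(h, w)), 6.0)
        mask = blob > np.percentile(blob, 30)
        bright = ndimage.gaussian_filter(mask.astype(float), 2.0)
        patch += bright * (210.0 - patch) * 0.9
    elif sign == "mitosis":
        # a dividing cell fills its (tight) annotation box: two large paired
        # nuclei on a quiet dark background
        patch *= 0.3
        cx, cy = w / 2, h / 2
        yy, xx = np.mgrid[0:h, 0:w]
        sx, sy = 0.13 * w, 0.22 * h
        for dx in (-0.16 * w, 0.16 * w):
            patch += 185.0 * np.exp(
                -(((xx - cx - dx) ** 2) / (2 * sx**2) + ((yy - cy) ** 2) / (2 * sy**2))
            )
    elif sign == "irregular_cells":
        sub, _ = _mosaic(
            max(h, w),
            n_cells=max(4, (w * h) // 2500),
            rng=rng,
            border_scale=1.25,
            interior_level=45.0,
            border_level=190.0,
            border_width=3.4,
        )
        jitter = rng.normal(0.0, 14.0, size=(h, w))
        patch[:] = sub[:h, :w] + ndimage.gaussian_filter(jitter, 2.0)
    elif sign == "non_ossn":
        # distractor texture: fibrous / granular non-OSSN pathology region
        yy, xx = np.mgrid[0:h, 0:w]
        angle = rng.uniform(0, np.pi)
        stripes = 22.0 * np.sin(
            (xx * np.cos(angle) + yy * np.sin(angle)) / rng.uniform(3.0, 6.0)
        )
        patch *= 0.8
        patch += stripes + ndimage.gaussian_filter(rng.normal(0, 18.0, (h, w)), 1.5)
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown sign {sign!r}")


def _class_overlay(content: np.ndarray, class_label: str, rng: np.random.Generator) -> None:
    """Mild class-specific texture variation for non-OSSN pathologies."""
    side = content.shape[0]
    if class_label == "melanoma":
        content *= 0.82
        for _ in range(10):
            cx, cy = rng.uniform(10, side - 10, 2)
            yy, xx = np.mgrid[0:side, 0:side]
            content += 70.0 * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 4.0**2)))
    elif class_label == "pterygium":
        yy, xx = np.mgrid[0:side, 0:side]
        angle = rng.uniform(0, np.pi)
        content += 16.0 * np.sin((xx * np.cos(angle) + yy * np.sin(angle)) / 5.0)
    elif class_label == "keratitis":
        blob = ndimage.gaussian_filter(rng.normal(size=content.shape), 12.0)
        content += 35.0 * (blob > np.percentile(blob, 80))
        content += 12.0


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    config: CohortConfig, render: bool = True
) -> tuple[list[IvcmImage], GroundTruth]:
    """Generate a fully labeled synthetic cohort.

    With ``render=True`` each image is a 384 x 484 uint8 array (content
    mosaic plus footer band) and ground truth includes per-cell label maps;
    with ``render=False`` only the label structure (patients, image classes,
    annotations, per-cell binary labels) is produced, which is orders of
    magnitude faster and sufficient for aggregation studies. Identical
    configurations yield bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])

    patients: dict[str, PatientRecord] = {}
    raw_fp = rng.normal(size=(config.n_patients, 4))
    if config.stratify_classes:
        quota = probs * config.n_patients
        counts = np.floor(quota).astype(int)
        remainder = quota - counts
        for ci in np.argsort(-remainder)[: config.n_patients - counts.sum()]:
            counts[ci] += 1
        patient_classes = np.repeat(np.arange(len(classes)), counts)
        rng.shuffle(patient_classes)
    else:
        patient_classes = rng.choice(len(classes), size=config.n_patients, p=probs)
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        fp = _BASE_FINGERPRINT + config.fingerprint_strength * _FP_SCALES * raw_fp[i]
        patients[pid] = PatientRecord(
            patient_id=pid,
            class_label=classes[patient_classes[i]],
            fingerprint=tuple(float(v) for v in fp),
        )

    image_patients: dict[str, str] = {}
    image_labels: dict[str, str] = {}
    image_order: list[str] = []
    for pid in sorted(patients):
        n_images = _count_draw(
            rng, config.images_per_patient_mean, config.images_per_patient_dispersion
        )
        for k in range(n_images):
            image_id = f"{pid}_I{k:03d}"
            image_patients[image_id] = pid
            image_labels[image_id] = patients[pid].class_label
            image_order.append(image_id)

    # -- plant sign rectangles -------------------------------------------
    annotations: list[RectAnnotation] = []
    rects_by_image: dict[str, list[tuple[str, tuple[int, int, int, int]]]] = {
        i: [] for i in image_order
    }
    ossn_images = [i for i in image_order if image_labels[i] == "OSSN"]
    pathology_images = [
        i for i in image_order if image_labels[i] in ("melanoma", "pterygium", "keratitis")
    ]
    for image_id in ossn_images:
        occupied: list[tuple[int, int, int, int]] = []
        for sign in ("starry_sky", "hyperkeratosis", "irregular_cells"):
            rate = config.sign_frequencies.get(sign, 0.0)
            for _ in range(int(rng.poisson(rate))):
                rect = _random_rect(rng, 52, 150, occupied)
                if rect is None:
                    continue
                occupied.append(rect)
                rects_by_image[image_id].append((sign, rect))
    # mitosis: exactly `mitosis_total` annotations cohort-wide (when possible)
    if config.mitosis_total > 0 and ossn_images:
        hosts = rng.choice(
            len(ossn_images), size=config.mitosis_total, replace=len(ossn_images) < config.mitosis_total
        )
        for host_idx in np.atleast_1d(hosts):
            image_id = ossn_images[int(host_idx)]
            occupied = [r for _, r in rects_by_image[image_id]]
            rect = _random_rect(rng, 40, 78, occupied)
            if rect is None:  # pragma: no cover - 40 retries over a sparse canvas
                rect = _random_rect(rng, 40, 78, [])
            rects_by_image[image_id].append(("mitosis", rect))
    for image_id in pathology_images:
        rate = config.sign_frequencies.get("non_ossn", 0.0)
        occupied = []
        for _ in range(int(rng.poisson(rate))):
            rect = _random_rect(rng, 52, 150, occupied)
            if rect is None:
                continue
            occupied.append(rect)
            rects_by_image[image_id].append(("non_ossn", rect))
    for image_id in image_order:
        for j, (sign, (x, y, w, h)) in enumerate(rects_by_image[image_id]):
            annotations.append(
                RectAnnotation(
                    annotation_id=f"{image_id}:A{j}",
                    image_id=image_id,
                    sign_class=sign,
                    x=x,
                    y=y,
                    w=w,
                    h=h,
                )
            )

    # -- cells and rendering ---------------------------------------------
    footer = _footer(np.random.default_rng(_FOOTER_SEED))
    images: list[IvcmImage] = []
    cells: dict[str, list[CellRecord]] = {}
    cell_label_maps: dict[str, np.ndarray] = {}

    for image_id in image_order:
        pid = image_patients[image_id]
        label = image_labels[image_id]
        fp = patients[pid].fingerprint
        n_cells = _count_draw(rng, config.cells_per_image_mean, config.cells_per_image_dispersion)
        ossn_frac = (
            config.ossn_cell_fraction if label == "OSSN" else config.stray_ossn_cell_fraction
        )

        if not render:
            n_ossn = int(rng.binomial(n_cells, ossn_frac))
            flags = np.zeros(n_cells, dtype=bool)
            flags[:n_ossn] = True
            rng.shuffle(flags)
            cells[image_id] = [
                CellRecord(cell_id=f"{image_id}_C{c:04d}", image_id=image_id, label=bool(f))
                for c, f in enumerate(flags)
            ]
            continue

        content, label_map = _mosaic(
            CONTENT_SIDE,
            n_cells,
            rng,
            diam_scale=fp[0],
            border_scale=fp[1],
            offset=fp[2],
            aniso=fp[3],
        )
        _class_overlay(content, label, rng)
        for sign, rect in rects_by_image[image_id]:
            _render_sign(content, rect, sign, rng)
        content = ndimage.gaussian_filter(content, 1.0)
        content += rng.normal(0.0, 6.0, content.shape)

        # cell labels follow geometry: cells inside a sign rectangle are
        # OSSN-related; diffuse atypia tops the fraction up beyond the
        # annotated salient regions.
        ids = np.unique(label_map)
        ids = ids[ids > 0]
        centroids = ndimage.center_of_mass(label_map > 0, label_map, ids)
        in_sign = np.zeros(len(ids), dtype=bool)
        if label == "OSSN":
            for sign, (x, y, w, h) in rects_by_image[image_id]:
                for ci, (cy, cx) in enumerate(centroids):
                    if x <= cx < x + w and y <= cy < y + h:
                        in_sign[ci] = True
        target = int(rng.binomial(len(ids), ossn_frac))
        flags = in_sign.copy()
        deficit = target - int(flags.sum())
        if deficit > 0:
            candidates = np.flatnonzero(~flags)
            extra = rng.choice(candidates, size=min(deficit, len(candidates)), replace=False)
            flags[extra] = True
        cells[image_id] = [
            CellRecord(cell_id=f"{image_id}_C{int(cid):04d}", image_id=image_id, label=bool(f))
            for cid, f in zip(ids, flags)
        ]
        cell_label_maps[image_id] = label_map

        frame = np.vstack([content, footer])
        pixels = np.clip(frame, 0, 255).astype(np.uint8)
        images.append(
            IvcmImage(
                image_id=image_id,
                pixels=pixels,
                patient_id=pid,
                class_label=label,
                footer_removed=False,
            )
        )

    truth = GroundTruth(
        patients=patients,
        image_patients=image_patients,
        image_labels=image_labels,
        annotations=annotations,
        cells=cells,
        cell_label_maps=cell_label_maps,
    )
    return images, truth


def simulate_cell_predictions(
    truth: GroundTruth, error_rate: float, seed: int
) -> list[tuple[str, bool]]:
    """Simulate a cell classifier: flip each true label with ``error_rate``.

    Returns ``(cell_id, predicted OSSN flag)`` pairs in deterministic cell
    order; useful for exercising the aggregation cascade without training.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ConfigurationError("error_rate must be a probability")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, bool]] = []
    for cell in truth.all_cells():
        flip = rng.random() < error_rate
        out.append((cell.cell_id, cell.label ^ flip))
    return out


def write_cohort(
    images: Iterable[IvcmImage], truth: GroundTruth, outdir: str | Path
) -> None:
    """Write a rendered cohort to disk: PNGs, CVAT XML, cell CSV, patient JSON."""
    import json

    from .preprocess import save_image, write_cvat

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    for image in images:
        save_image(image, outdir / "images" / f"{image.image_id}.png")
    write_cvat(truth.annotations, outdir / "annotations.xml")
    with open(outdir / "cells.csv", "w") as fh:
        fh.write("image_id,cell_id,label\n")
        for cell in truth.all_cells():
            fh.write(f"{cell.image_id},{cell.cell_id},{int(cell.label)}\n")
    registry = {
        pid: {"class_label": rec.class_label, "fingerprint": list(rec.fingerprint)}
        for pid, rec in sorted(truth.patients.items())
    }
    (outdir / "patients.json").write_text(json.dumps(registry, indent=1))
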