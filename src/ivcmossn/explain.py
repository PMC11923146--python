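"""Attribution maps and their binary-metric embedding.

Three complementary views of what drives a classifier's decision:

* a Monte-Carlo Shapley estimator over square image patches ("players"),
  which inherits the efficiency property — patch contributions sum to the
  model score minus the baseline score — exactly, per sampled permutation;
* Grad-CAM over the final convolutional response of the small CNN;
* permutation feature importance over arbitrary pixel groups.

Signed attribution maps are binarized (positive contribution -> 1) and
embedded in 2-D with UMAP under binary-data metrics. The Yule and
Russell-Rao distances are written out from their 2x2 agreement-count closed
forms; :func:`embed` hands the equivalent built-in metrics to umap-learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage import transform as sktransform

__all__ = [
    "AttributionMap",
    "PairCounts",
    "mean_baseline",
    "class_score_fn",
    "shapley_attribution",
    "grad_cam",
    "permutation_importance",
    "binarize",
    "pair_counts",
    "yule_distance",
    "russell_rao_distance",
    "embed",
]

ScoreFn = Callable[[np.ndarray], np.ndarray]  # (N, H, W) -> (N,) scores


@dataclass(frozen=True)
class AttributionMap:
    """Per-pixel signed contributions aligned to the input grid."""

    values: np.ndarray
    method: str
    baseline: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribution values must be finite")


def mean_baseline(image: np.ndarray) -> np.ndarray:
    """Reference input for attribution: the mean-intensity constant image."""
    return np.full_like(np.asarray(image, dtype=float), float(np.mean(image)))


def class_score_fn(model, target_class: int) -> ScoreFn:
    """Adapt a classifier to a batch score function: P(target_class | x)."""

    def score(batch: np.ndarray) -> np.ndarray:
        return model.predict_proba(batch)[:, target_class]

    return score


def _patch_slices(shape: tuple[int, int], grid: tuple[int, int]) -> list[tuple[slice, slice]]:
    rows = np.array_split(np.arange(shape[0]), grid[0])
    cols = np.array_split(np.arange(shape[1]), grid[1])
    return [
        (slice(r[0], r[-1] + 1), slice(c[0], c[-1] + 1))
        for r in rows
        for c in cols
        if len(r) and len(c)
    ]


def shapley_attribution(
    score_fn: ScoreFn,
    image: np.ndarray,
    grid: tuple[int, int] = (8, 8),
    n_samples: int = 100,
    seed: int = 0,
    baseline: np.ndarray | None = None,
) -> AttributionMap:
    """Monte-Carlo Shapley values over square patch players.

    For each sampled permutation of the patches, patches are revealed one by
    one on top of the baseline and each patch is credited with the marginal
    change in score. Averaging over permutations estimates the Shapley
    value; the per-permutation telescoping sum makes the efficiency identity
    ``sum(contributions) = score(image) - score(baseline)`` hold up to
    Monte-Carlo symmetrisation error that shrinks with ``n_samples``.
    The per-patch value is broadcast to that patch's pixels.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    image = np.asarray(image, dtype=float)
    if baseline is None:
        baseline = mean_baseline(image)
    patches = _patch_slices(image.shape, grid)
    n_players = len(patches)
    rng = np.random.default_rng(seed)
    totals = np.zeros(n_players)
    for _ in range(n_samples):
        order = rng.permutation(n_players)
        # composite states after revealing 0, 1, ..., n patches
        states = np.empty((n_players + 1, *image.shape))
        current = baseline.copy()
        states[0] = current
        for step, player in enumerate(order, start=1):
            current[patches[player]] = image[patches[player]]
            states[step] = current
        scores = np.asarray(score_fn(states), dtype=float)
        totals[order] += np.diff(scores)
    contributions = totals / n_samples
    values = np.zeros_like(image)
    for player, sl in enumerate(patches):
        values[sl] = contributions[player]
    return AttributionMap(values=values, method="shapley", baseline="mean-intensity image")


def grad_cam(model, image: np.ndarray, target_class: int) -> np.ndarray:
    """Class activation heatmap from the final convolutional response.

    Channel maps are weighted by the gradient of the target logit with
    respect to the feature map, rectified, upsampled to the input grid and
    normalized to [0, 1]. Requires a model that exposes ``feature_map`` and
    ``class_map_gradient`` (the convolutional backbone's internals).
    """
    if not (hasattr(model, "feature_map") and hasattr(model, "class_map_gradient")):
        raise TypeError("grad_cam needs a convolutional model exposing its feature map")
    image = np.asarray(image, dtype=float)
    fmap = model.feature_map(image[None])[0]  # (C, h, w)
    weights = model.class_map_gradient(target_class)  # (C,)
    cam = np.maximum((weights[:, None, None] * fmap).sum(axis=0), 0.0)
    cam = sktransform.resize(cam, image.shape, order=1, anti_aliasing=False)
    top = cam.max()
    return cam / top if top > 0 else cam


def permutation_importance(
    score_fn: ScoreFn,
    image: np.ndarray,
    pixel_groups: Sequence[np.ndarray],
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean score drop when a pixel group's intensities are shuffled in place.

    ``pixel_groups`` are boolean masks that must partition the image grid
    (pairwise disjoint and jointly covering). Deterministic given the seed.
    """
    image = np.asarray(image, dtype=float)
    cover = np.zeros(image.shape, dtype=int)
    for g in pixel_groups:
        cover += np.asarray(g, dtype=bool).astype(int)
    if cover.max() > 1:
        raise ValueError("pixel groups overlap; they must partition the grid")
    if cover.min() < 1:
        raise ValueError("pixel groups do not cover the grid")
    rng = np.random.default_rng(seed)
    base = float(np.asarray(score_fn(image[None]))[0])
    scores = np.zeros(len(pixel_groups))
    for gi, g in enumerate(pixel_groups):
        mask = np.asarray(g, dtype=bool)
        drops = []
        for _ in range(n_repeats):
            shuffled = image.copy()
            vals = shuffled[mask]
            rng.shuffle(vals)
            shuffled[mask] = vals
            drops.append(base - float(np.asarray(score_fn(shuffled[None]))[0]))
        scores[gi] = float(np.mean(drops))
    return scores


def binarize(attribution: AttributionMap) -> np.ndarray:
    """Flatten a signed map to a row-major binary vector: 1 where value > 0."""
    return (attribution.values > 0).astype(np.uint8).ravel(order="C")


# ---------------------------------------------------------------------------
# binary-vector distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairCounts:
    """2x2 agreement counts of two equal-length binary vectors."""

    c_tt: int
    c_tf: int
    c_ft: int
    c_ff: int

    @property
    def n(self) -> int:
        return self.c_tt + self.c_tf + self.c_ft + self.c_ff


def pair_counts(u: np.ndarray, v: np.ndarray) -> PairCounts:
    u = np.asarray(u).astype(bool)
    v = np.asarray(v).astype(bool)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"need equal-length 1-D vectors, got {u.shape} and {v.shape}")
    return PairCounts(
        c_tt=int(np.count_nonzero(u & v)),
        c_tf=int(np.count_nonzero(u & ~v)),
        c_ft=int(np.count_nonzero(~u & v)),
        c_ff=int(np.count_nonzero(~u & ~v)),
    )


def yule_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Yule dissimilarity ``2 c_TF c_FT / (c_TT c_FF + c_TF c_FT)``.

    Ranges over [0, 2]; 0 for identical vectors, 2 for complementary mixed
    vectors. When the numerator vanishes the distance is 0 (0/0 convention).
    """
    c = pair_counts(u, v)
    num = 2.0 * c.c_tf * c.c_ft
    if num == 0.0:
        return 0.0
    return num / (c.c_tt * c.c_ff + c.c_tf * c.c_ft)


def russell_rao_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Russell-Rao dissimilarity ``1 - c_TT / n``: joint-presence mismatch."""
    c = pair_counts(u, v)
    if c.n == 0:
        raise ValueError("vectors must have length >= 1")
    return 1.0 - c.c_tt / c.n


_UMAP_METRICS = {
    "yule": "yule",
    "russell_rao": "russellrao",
    "hamming": "hamming",
    "jaccard": "jaccard",
}


def embed(
    vectors: np.ndarray,
    metric_name: str = "yule",
    seed: int = 0,
    n_neighbors: int = 15,
) -> np.ndarray:
    """UMAP 2-D embedding of binary vectors under a binary-data metric.

    ``metric_name`` is one of ``yule``, ``russell_rao``, ``hamming``,
    ``jaccard``; umap-learn's built-in implementations of these metrics are
    used (they share the closed forms above). Deterministic given ``seed``.
    """
    if metric_name not in _UMAP_METRICS:
        raise ValueError(
            f"unknown metric {metric_name!r}; choose from {sorted(_UMAP_METRICS)}"
        )
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or len(vectors) < 10:
        raise ValueError("embed needs a 2-D stack of at least 10 vectors")
    import umap  # deferred: numba compilation is slow to import

    reducer = umap.UMAP(
        n_components=2,
        metric=_UMAP_METRICS[metric_name],
        random_state=seed,
        n_neighbors=min(n_neighbors, len(vectors) - 1),
    )
    return np.asarray(reducer.fit_transform(vectors))
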