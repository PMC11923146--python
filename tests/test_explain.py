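"""Attribution estimators, binary distances, and the UMAP embedding."""

import itertools

import numpy as np
import pytest
from scipy.spatial import distance as sp_distance

from ivcmossn.explain import (
    AttributionMap,
    binarize,
    class_score_fn,
    embed,
    grad_cam,
    mean_baseline,
    pair_counts,
    permutation_importance,
    russell_rao_distance,
    shapley_attribution,
    yule_distance,
)
from ivcmossn.nn import SmallCNN


# ---------------------------------------------------------------------------
# Shapley
# ---------------------------------------------------------------------------


class TestShapley:
    def test_constant_model_gets_zero_everywhere(self, rng):
        image = rng.uniform(size=(8, 8))
        score = lambda batch: np.full(len(batch), 0.7)
        attr = shapley_attribution(score, image, grid=(2, 2), n_samples=20, seed=0)
        np.testing.assert_allclose(attr.values, 0.0, atol=1e-12)

    def test_two_player_additive_model_matches_exact_enumeration(self, rng):
        image = rng.uniform(size=(4, 8))
        baseline = mean_baseline(image)

        def g(half):
            return float(np.sin(half.sum()))

        def score(batch):
            return np.array([g(b[:, :4]) + g(b[:, 4:]) for b in batch])

        attr = shapley_attribution(
            score, image, grid=(1, 2), n_samples=50, seed=1, baseline=baseline
        )
        # exact Shapley by enumerating both reveal orders
        halves = [np.s_[:, :4], np.s_[:, 4:]]
        exact = np.zeros(2)
        for order in itertools.permutations(range(2)):
            current = baseline.copy()
            prev = float(score(current[None])[0])
            for player in order:
                current[halves[player]] = image[halves[player]]
                now = float(score(current[None])[0])
                exact[player] += (now - prev) / 2
                prev = now
        np.testing.assert_allclose(attr.values[:, :4], exact[0], atol=1e-12)
        np.testing.assert_allclose(attr.values[:, 4:], exact[1], atol=1e-12)

    def test_efficiency_identity_holds_and_tightens(self, rng):
        image = rng.uniform(size=(8, 8))
        baseline = mean_baseline(image)
        score = lambda batch: np.tanh(batch.reshape(len(batch), -1) ** 2).sum(axis=1)
        gap = float(score(image[None])[0] - score(baseline[None])[0])
        residuals = {}
        for n_samples in (20, 200):
            vals = []
            for seed in range(10):
                attr = shapley_attribution(
                    score, image, grid=(2, 2), n_samples=n_samples, seed=seed
                )
                patch_sum = attr.values[:4, :4].mean() + attr.values[:4, 4:].mean()
                patch_sum += attr.values[4:, :4].mean() + attr.values[4:, 4:].mean()
                vals.append(abs(patch_sum - gap))
            residuals[n_samples] = np.mean(vals)
        # the permutation estimator telescopes, so efficiency is near-exact
        assert residuals[200] <= residuals[20] + 1e-9
        assert residuals[200] < 1e-9

    def test_bad_sample_count_rejected(self, rng):
        with pytest.raises(ValueError):
            shapley_attribution(lambda b: np.zeros(len(b)), rng.uniform(size=(4, 4)), n_samples=0)

    def test_non_finite_maps_rejected(self):
        with pytest.raises(ValueError):
            AttributionMap(values=np.array([[np.inf]]), method="x")


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------


def passthrough_cnn(side=16, n_classes=2):
    """A hand-wired CNN whose first channel relays the input unchanged, so the
    class-1 activation map is (a pooled copy of) the image itself."""
    model = SmallCNN(side, n_classes, channels=(4,), seed=0)
    w = np.zeros_like(model.conv_w[0])
    w[0, 4] = 1.0  # center tap of the 3x3 kernel, input channel 0
    model.conv_w[0] = w
    model.conv_b[0] = np.zeros_like(model.conv_b[0])
    head = np.zeros_like(model.head_w)
    head[1, 0] = 1.0
    model.head_w = head
    return model


class TestGradCam:
    def test_range_and_normalization(self, rng):
        model = passthrough_cnn()
        cam = grad_cam(model, rng.uniform(0.1, 1.0, (16, 16)), target_class=1)
        assert cam.shape == (16, 16)
        assert cam.min() >= 0.0
        assert cam.max() == pytest.approx(1.0)

    def test_localizes_planted_left_half_signal(self):
        model = passthrough_cnn()
        image = np.zeros((16, 16))
        image[:, :8] = 1.0
        cam = grad_cam(model, image, target_class=1)
        left_mass = cam[:, :8].sum()
        assert left_mass / cam.sum() >= 0.8

    def test_deterministic_on_identical_inputs(self, rng):
        model = passthrough_cnn()
        image = rng.uniform(size=(16, 16))
        np.testing.assert_array_equal(
            grad_cam(model, image, 1), grad_cam(model, image.copy(), 1)
        )

    def test_model_without_conv_internals_rejected(self):
        class Headless:
            def predict_proba(self, x):
                return np.ones((len(x), 2)) / 2

        with pytest.raises(TypeError, match="convolutional"):
            grad_cam(Headless(), np.zeros((8, 8)), 0)


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------


def quadrant_masks(side=8):
    masks = []
    half = side // 2
    for r, c in itertools.product((0, 1), repeat=2):
        m = np.zeros((side, side), dtype=bool)
        m[r * half : (r + 1) * half, c * half : (c + 1) * half] = True
        masks.append(m)
    return masks


class TestPermutationImportance:
    def test_constant_model_scores_zero(self, rng):
        image = rng.uniform(size=(8, 8))
        score = lambda batch: np.ones(len(batch))
        scores = permutation_importance(score, image, quadrant_masks(), n_repeats=5, seed=0)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_model_keyed_to_one_group_ranks_it_first(self, rng):
        image = rng.uniform(size=(8, 8))
        masks = quadrant_masks()
        target = masks[2]
        # structured response: depends on the spatial arrangement inside the
        # target quadrant, so shuffling it moves the score
        weights = np.arange(16).reshape(4, 4) / 16.0

        def score(batch):
            return np.array([float((b[target.nonzero()].reshape(4, 4) * weights).sum()) for b in batch])

        scores = permutation_importance(score, image, masks, n_repeats=30, seed=1)
        assert np.argmax(np.abs(scores)) == 2
        assert all(abs(scores[2]) > abs(scores[i]) for i in (0, 1, 3))

    def test_more_repeats_reduce_estimator_variance(self, rng):
        image = rng.uniform(size=(8, 8))
        masks = quadrant_masks()
        weights = rng.normal(size=(4, 4))

        def score(batch):
            return np.array(
                [float((b[masks[0].nonzero()].reshape(4, 4) * weights).sum()) for b in batch]
            )

        def spread(n_repeats):
            vals = [
                permutation_importance(score, image, masks, n_repeats=n_repeats, seed=s)[0]
                for s in range(15)
            ]
            return np.var(vals)

        assert spread(50) < spread(1)

    def test_overlapping_groups_rejected(self, rng):
        masks = quadrant_masks()
        masks[1] = masks[0]
        with pytest.raises(ValueError, match="overlap"):
            permutation_importance(
                lambda b: np.zeros(len(b)), rng.uniform(size=(8, 8)), masks
            )

    def test_incomplete_cover_rejected(self, rng):
        masks = quadrant_masks()[:3]
        with pytest.raises(ValueError, match="cover"):
            permutation_importance(
                lambda b: np.zeros(len(b)), rng.uniform(size=(8, 8)), masks
            )


# ---------------------------------------------------------------------------
# binarization and binary distances
# ---------------------------------------------------------------------------


class TestBinarize:
    def test_all_positive_gives_ones(self):
        attr = AttributionMap(values=np.full((3, 4), 0.2), method="m")
        vec = binarize(attr)
        assert vec.shape == (12,)
        assert vec.all()

    def test_sign_symmetric_map_near_half(self, rng):
        attr = AttributionMap(values=rng.normal(size=(50, 50)), method="m")
        ones = binarize(attr).mean()
        assert abs(ones - 0.5) < 3 * np.sqrt(0.25 / 2500)

    def test_row_major_flattening(self):
        values = np.array([[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_array_equal(
            binarize(AttributionMap(values=values, method="m")), [1, 0, 0, 1]
        )


class TestDistances:
    def test_yule_closed_forms(self):
        u = np.array([1, 1, 0, 0])
        v = np.array([1, 0, 1, 0])
        c = pair_counts(u, v)
        assert (c.c_tt, c.c_tf, c.c_ft, c.c_ff) == (1, 1, 1, 1)
        assert yule_distance(u, v) == pytest.approx(1.0)
        assert yule_distance(u, u) == 0.0
        mixed = np.array([1, 0, 1, 1, 0])
        assert yule_distance(mixed, 1 - mixed) == pytest.approx(2.0)

    def test_russell_rao_closed_forms(self):
        u = np.array([1, 1, 0, 0])
        v = np.array([1, 0, 1, 0])
        assert russell_rao_distance(u, v) == pytest.approx(0.75)
        ones = np.ones(6)
        assert russell_rao_distance(ones, ones) == 0.0
        assert russell_rao_distance(np.zeros(5), np.ones(5)) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            yule_distance(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            russell_rao_distance(np.ones(3), np.ones(4))

    def test_agrees_with_scipy_on_random_pairs(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 64))
            u = rng.integers(0, 2, n).astype(bool)
            v = rng.integers(0, 2, n).astype(bool)
            assert russell_rao_distance(u, v) == pytest.approx(
                sp_distance.russellrao(u, v)
            )
            c = pair_counts(u, v)
            if c.c_tf * c.c_ft > 0:  # scipy shares our 0/0 convention implicitly
                assert yule_distance(u, v) == pytest.approx(sp_distance.yule(u, v))
            else:
                assert yule_distance(u, v) == 0.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(500):
            u = rng.integers(0, 2, 32).astype(bool)
            v = rng.integers(0, 2, 32).astype(bool)
            dy, drr = yule_distance(u, v), russell_rao_distance(u, v)
            assert dy == yule_distance(v, u)
            assert drr == russell_rao_distance(v, u)
            assert 0.0 <= dy <= 2.0
            assert 0.0 <= drr <= 1.0


# ---------------------------------------------------------------------------
# UMAP embedding
# ---------------------------------------------------------------------------


def planted_binary_clusters(rng, n_per=30, length=64, flip=0.05):
    # balanced prototypes: Yule needs both joint presences and joint
    # absences, so near-constant vectors would degenerate
    a = np.zeros(length, dtype=int)
    a[: length // 2] = 1
    b = 1 - a
    vectors, labels = [], []
    for proto, lab in ((a, 0), (b, 1)):
        for _ in range(n_per):
            noise = rng.random(length) < flip
            vectors.append(np.abs(proto - noise.astype(int)))
            labels.append(lab)
    return np.array(vectors), np.array(labels)


class TestEmbed:
    def test_shape_and_determinism(self, rng):
        vectors, _ = planted_binary_clusters(rng, n_per=12)
        a = embed(vectors, "hamming", seed=3)
        b = embed(vectors, "hamming", seed=3)
        assert a.shape == (24, 2)
        np.testing.assert_allclose(a, b)

    def test_separates_planted_clusters_under_yule(self, rng):
        from sklearn.metrics import silhouette_score

        vectors, labels = planted_binary_clusters(rng)
        for seed in range(5):
            coords = embed(vectors, "yule", seed=seed)
            assert silhouette_score(coords, labels) > 0.5

    def test_duplicates_land_near_each_other(self, rng):
        vectors, _ = planted_binary_clusters(rng, n_per=10)
        vectors[1] = vectors[0]
        coords = embed(vectors, "russell_rao", seed=0)
        d01 = np.linalg.norm(coords[0] - coords[1])
        spread = np.linalg.norm(coords.max(axis=0) - coords.min(axis=0))
        assert d01 < 0.1 * spread

    def test_unknown_metric_rejected(self, rng):
        vectors, _ = planted_binary_clusters(rng, n_per=10)
        with pytest.raises(ValueError, match="unknown metric"):
            embed(vectors, "cosine", seed=0)

    def test_too_few_vectors_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            embed(rng.integers(0, 2, (5, 16)), "yule", seed=0)
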