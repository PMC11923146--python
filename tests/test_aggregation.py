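"""Majority-vote aggregation and macro-average metrics."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import f1_score, precision_score, recall_score

from ivcmossn.aggregation import (
    AggregationError,
    aggregate_image,
    aggregate_patient,
    backpropagate,
    macro_metrics,
)


class TestImageAggregation:
    def test_exact_tie_resolves_to_ossn(self):
        agg = aggregate_image([True, False])
        assert agg.decision is True
        assert (agg.o, agg.n) == (1, 2)

    def test_minority_is_negative(self):
        assert aggregate_image([False, False, False]).decision is False

    def test_empty_image_rejected(self):
        with pytest.raises(AggregationError):
            aggregate_image([])

    def test_matches_counting_oracle(self, rng):
        for _ in range(10_000):
            labels = rng.random(int(rng.integers(1, 25))) < rng.random()
            agg = aggregate_image(labels.tolist())
            positives = sum(1 for l in labels if l)  # independent counter
            assert agg.decision == (2 * positives >= len(labels))
            assert agg.o == positives and agg.n == len(labels)


class TestPatientAggregation:
    def test_single_image(self):
        assert aggregate_patient([True]).decision is True

    def test_half_is_ossn(self):
        agg = aggregate_patient([True, True, False, False])
        assert agg.decision is True and (agg.o, agg.n) == (2, 4)

    def test_matches_counting_oracle(self, rng):
        for _ in range(5_000):
            decisions = (rng.random(int(rng.integers(1, 40))) < 0.5).tolist()
            agg = aggregate_patient(decisions)
            assert agg.decision == (2 * sum(decisions) >= len(decisions))

    def test_monotone_in_single_flip(self, rng):
        # turning one negative cell positive can never turn the image negative
        for _ in range(500):
            labels = (rng.random(int(rng.integers(2, 20))) < 0.5).tolist()
            before = aggregate_image(labels).decision
            flip_candidates = [i for i, l in enumerate(labels) if not l]
            if not flip_candidates:
                continue
            labels[flip_candidates[0]] = True
            after = aggregate_image(labels).decision
            assert not (before and not after)


class TestMacroMetrics:
    def test_perfect_predictions(self):
        report = macro_metrics(list("aabbcc"), list("aabbcc"))
        for v in (
            report.macro_accuracy,
            report.macro_precision,
            report.macro_recall,
            report.macro_f1,
            report.plain_accuracy,
        ):
            assert v == 1.0

    def test_known_confusion_matrix(self):
        # confusion [[8,2],[1,9]]: per-class F1 0.8421 and 0.8571
        truth = ["n"] * 10 + ["p"] * 10
        pred = ["n"] * 8 + ["p"] * 2 + ["n"] * 1 + ["p"] * 9
        report = macro_metrics(truth, pred, classes=("n", "p"))
        np.testing.assert_array_equal(report.confusion, [[8, 2], [1, 9]])
        assert report.macro_f1 == pytest.approx(0.8496, abs=1e-4)
        assert report.macro_precision == pytest.approx((8 / 9 + 9 / 11) / 2, abs=1e-12)
        assert report.macro_recall == pytest.approx(0.85, abs=1e-12)

    def test_agrees_with_sklearn_on_random_multiclass(self, rng):
        classes = ["a", "b", "c", "d"]
        truth = [classes[i] for i in rng.integers(0, 4, 300)]
        pred = [classes[i] for i in rng.integers(0, 4, 300)]
        report = macro_metrics(truth, pred, classes=classes)
        assert report.macro_f1 == pytest.approx(
            f1_score(truth, pred, average="macro", zero_division=0)
        )
        assert report.macro_precision == pytest.approx(
            precision_score(truth, pred, average="macro", zero_division=0)
        )
        assert report.macro_recall == pytest.approx(
            recall_score(truth, pred, average="macro", zero_division=0)
        )

    def test_invariant_to_order_and_renaming(self, rng):
        truth = [str(i) for i in rng.integers(0, 3, 100)]
        pred = [str(i) for i in rng.integers(0, 3, 100)]
        base = macro_metrics(truth, pred, classes=("0", "1", "2"))
        order = rng.permutation(100)
        shuffled = macro_metrics(
            [truth[i] for i in order], [pred[i] for i in order], classes=("0", "1", "2")
        )
        rename = {"0": "x", "1": "y", "2": "z"}
        renamed = macro_metrics(
            [rename[t] for t in truth], [rename[p] for p in pred], classes=("x", "y", "z")
        )
        for other in (shuffled, renamed):
            assert other.macro_f1 == pytest.approx(base.macro_f1)
            assert other.macro_precision == pytest.approx(base.macro_precision)

    def test_absent_class_contributes_zero(self):
        report = macro_metrics(["a", "a"], ["a", "a"], classes=("a", "b"))
        assert report.per_class.loc["b", "f1"] == 0.0
        assert report.macro_f1 == pytest.approx(0.5)

    def test_unknown_label_rejected(self):
        with pytest.raises(AggregationError, match="'q'"):
            macro_metrics(["a"], ["q"], classes=("a", "b"))


class TestBackpropagate:
    def build(self, n_patients=4, n_images=5, n_cells=9, flip=False):
        cell_preds, image_patients, image_truth, patient_truth = {}, {}, {}, {}
        for p in range(n_patients):
            pid = f"P{p}"
            is_ossn = p % 2 == 0
            patient_truth[pid] = is_ossn
            for k in range(n_images):
                image_id = f"{pid}_I{k}"
                image_patients[image_id] = pid
                image_truth[image_id] = is_ossn
                labels = [is_ossn] * n_cells  # unanimous
                cell_preds[image_id] = [l ^ flip for l in labels]
        return cell_preds, image_patients, image_truth, patient_truth

    def test_noiseless_predictions_are_perfect_at_all_levels(self):
        cell_preds, image_patients, image_truth, patient_truth = self.build()
        reports = backpropagate(
            cell_preds, image_patients, image_truth, patient_truth, cell_truth=cell_preds
        )
        assert set(reports) == {"cell", "image", "patient"}
        for level in reports.values():
            assert level.macro_f1 == 1.0

    def test_all_flipped_unanimous_images_invert_patient_decisions(self):
        cell_preds, image_patients, image_truth, patient_truth = self.build(flip=True)
        reports = backpropagate(cell_preds, image_patients, image_truth, patient_truth)
        assert reports["patient"].plain_accuracy == 0.0

    def test_orphan_image_rejected(self):
        with pytest.raises(AggregationError, match="patient"):
            backpropagate({"img": [True]}, {}, {"img": True}, {})

    def test_error_damping_respects_binomial_bound(self):
        """With unanimous per-image cell truths and independent per-cell noise
        at rate eps, the image error rate is bounded by the binomial
        majority-flip tail (within Monte-Carlo slack)."""
        from ivcmossn.synthetic import CohortConfig, generate_cohort, simulate_cell_predictions

        config = CohortConfig(
            n_patients=20,
            images_per_patient_mean=27,
            images_per_patient_dispersion=0,
            cells_per_image_mean=30,
            cells_per_image_dispersion=0,
            class_mix={"OSSN": 0.5, "normal": 0.5},
            stratify_classes=True,
            ossn_cell_fraction=1.0,
            stray_ossn_cell_fraction=0.0,
            seed=77,
        )
        _, truth = generate_cohort(config, render=False)
        eps, n = 0.12, 30
        # tail bound for a clean (unanimous-tendency) image: at least half flipped
        bound = 1.0 - stats.binom.cdf(n // 2 - 1, n, eps)
        errors, total = 0, 0
        for seed in range(5):
            preds = dict(simulate_cell_predictions(truth, eps, seed))
            for image_id, cells in truth.cells.items():
                votes = [preds[c.cell_id] for c in cells]
                decision = aggregate_image(votes).decision
                errors += decision != truth.image_is_ossn(image_id)
                total += 1
        rate = errors / total
        se = np.sqrt(bound * (1 - bound) / total)
        assert rate <= bound + 3 * se
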