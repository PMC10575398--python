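import math

import numpy as np
import pytest

from emophysio import evaluation as ev
from emophysio.synthetic import CohortConfig, generate_cohort

TABLE5_SAM_COUNTS = {1: 24, 2: 26, 3: 34, 4: 29, 5: 51, 6: 41, 7: 31, 8: 19, 9: 11}


class TestArousalToClass:
    @pytest.mark.parametrize(
        "sam,expected",
        [(1, "low"), (3, "low"), (4, "mid"), (5, "mid"), (6, "mid"), (7, "high"), (9, "high")],
    )
    def test_mapping(self, sam, expected):
        assert ev.arousal_to_class(sam) == expected

    @pytest.mark.parametrize("sam", [0, 10, -3])
    def test_out_of_range_rejected(self, sam):
        with pytest.raises(ValueError):
            ev.arousal_to_class(sam)


class TestClassWeights:
    def test_table_counts(self):
        labels = ["low"] * 84 + ["mid"] * 121 + ["high"] * 61
        w = ev.class_weights(labels)
        assert w["low"] == pytest.approx(266 / 84)
        assert w["mid"] == pytest.approx(266 / 121)
        assert w["high"] == pytest.approx(266 / 61)

    def test_balanced_classes(self):
        w = ev.class_weights(["a", "b", "c"] * 10)
        assert all(v == pytest.approx(3.0) for v in w.values())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.class_weights([])


class TestMetrics:
    def test_perfect_diagonal(self):
        cm = ev.ConfusionMatrix(np.diag([5, 7]), ("a", "b"))
        assert ev.precision_recall(cm, "a") == (1.0, 1.0)
        assert cm.accuracy() == 1.0

    def test_hand_computed_example(self):
        cm = ev.ConfusionMatrix(np.array([[8, 2], [3, 7]]), ("a", "b"))
        p, r = ev.precision_recall(cm, "a")
        assert p == pytest.approx(8 / 11)
        assert r == pytest.approx(0.8)

    def test_empty_predicted_class(self):
        cm = ev.ConfusionMatrix(np.array([[0, 3], [0, 5]]), ("a", "b"))
        p, r = ev.precision_recall(cm, "a")
        assert math.isnan(p)
        assert r == 0.0

    def test_brute_force_tally_oracle(self, rng):
        classes = ("x", "y", "z")
        for _ in range(20):
            truth = rng.choice(classes, size=60)
            pred = rng.choice(classes, size=60)
            cm = ev.ConfusionMatrix.from_predictions(truth, pred, classes)
            assert cm.total == 60
            for c in classes:
                tp = sum(1 for t, p in zip(truth, pred) if t == c and p == c)
                fp = sum(1 for t, p in zip(truth, pred) if t != c and p == c)
                fn = sum(1 for t, p in zip(truth, pred) if t == c and p != c)
                p_, r_ = ev.precision_recall(cm, c)
                if tp + fp:
                    assert p_ == pytest.approx(tp / (tp + fp))
                if tp + fn:
                    assert r_ == pytest.approx(tp / (tp + fn))

    def test_f_beta_symmetry(self):
        assert ev.f_beta(0.7, 0.7) == pytest.approx(0.7)

    def test_f_beta_hand_computed(self):
        assert ev.f_beta(0.5, 1.0) == pytest.approx(2 / 3)

    def test_f_beta_small_beta_approaches_precision(self):
        assert ev.f_beta(0.3, 0.9, beta=1e-6) == pytest.approx(0.3, abs=1e-6)

    def test_f_beta_zero_zero(self, caplog):
        assert ev.f_beta(0.0, 0.0) == 0.0


class TestMonteCarloCv:
    def test_validation_sizes(self):
        labels = ["a"] * 50 + ["b"] * 50
        for train, val in ev.monte_carlo_cv(labels, k=5, val_frac=0.2, seed=0):
            assert val.size == 20
            assert train.size == 80
            assert np.intersect1d(train, val).size == 0

    def test_class_proportions_preserved(self):
        labels = ["a"] * 60 + ["b"] * 40
        for _, val in ev.monte_carlo_cv(labels, k=5, val_frac=0.25, seed=1):
            counts = np.unique(np.asarray(labels)[val], return_counts=True)[1]
            assert abs(counts[0] - 15) <= 1 and abs(counts[1] - 10) <= 1

    def test_folds_differ(self):
        labels = ["a"] * 100
        splits = ev.monte_carlo_cv(labels, k=5, val_frac=0.2, seed=2)
        vals = [tuple(v) for _, v in splits]
        assert len(set(vals)) > 1

    def test_seed_determinism(self):
        labels = ["a"] * 30 + ["b"] * 30
        a = ev.monte_carlo_cv(labels, seed=9)
        b = ev.monte_carlo_cv(labels, seed=9)
        for (ta, va), (tb, vb) in zip(a, b):
            assert np.array_equal(va, vb)

    def test_invalid_val_frac_rejected(self):
        with pytest.raises(ValueError):
            ev.monte_carlo_cv(["a"], val_frac=1.5)


class TestStratifiedSplit:
    def _labels(self):
        out = []
        for sam, count in TABLE5_SAM_COUNTS.items():
            out.extend([sam] * count)
        return out

    def test_split_sizes_240_26(self):
        train, test = ev.stratified_split(self._labels(), train_frac=0.9, seed=0)
        assert train.size == 240
        assert test.size == 26

    def test_every_sam_class_in_test(self):
        labels = np.asarray(self._labels())
        _, test = ev.stratified_split(labels, seed=3)
        assert set(labels[test]) == set(range(1, 10))

    def test_partition(self):
        labels = self._labels()
        train, test = ev.stratified_split(labels, seed=1)
        assert np.intersect1d(train, test).size == 0
        assert train.size + test.size == len(labels)

    def test_invalid_frac_rejected(self):
        with pytest.raises(ValueError):
            ev.stratified_split([1, 2], train_frac=1.2)


class TestDatasetSummary:
    def test_19_subject_cohort_counts(self, protocol):
        cohort = generate_cohort(CohortConfig(n_subjects=19, seed=0), protocol, signals=False)
        summary = ev.dataset_summary(cohort)
        assert summary.n_emotion == 266
        assert summary.n_rest == 266
        for counts in summary.category_counts.values():
            assert counts == {"image": 19, "recall": 19}
        # one arousal observation per emotion segment (both induction methods)
        assert sum(summary.sam_counts.values()) == 266

    def test_table5_aggregation_identity(self):
        three = ev.summarize_sam_counts(TABLE5_SAM_COUNTS)
        assert three == {"low": 84, "mid": 121, "high": 61}
        assert sum(three.values()) == sum(TABLE5_SAM_COUNTS.values()) == 266

    def test_empty_cohort_all_zero(self):
        summary = ev.dataset_summary([])
        assert summary.total == 0
        assert all(v == 0 for v in summary.sam_counts.values())

    def test_reduction_percent(self):
        assert ev.reduction_percent(672, 532) == pytest.approx(20.8333, abs=1e-3)
        with pytest.raises(ValueError):
            ev.reduction_percent(0, 0)


class TestCvReport:
    def test_confusion_totals_match_observations(self, rng):
        classes = ("a", "b")
        folds = []
        n_total = 0
        for _ in range(5):
            n = int(rng.integers(10, 30))
            n_total += n
            folds.append(
                (list(rng.choice(classes, n)), list(rng.choice(classes, n)))
            )
        report = ev._report_from_folds(folds, classes)
        assert report.confusion.total == n_total

    def test_mean_consistent_with_folds(self):
        folds = [
            (["a", "a", "b", "b"], ["a", "b", "b", "b"]),
            (["a", "b", "a", "b"], ["a", "b", "a", "b"]),
        ]
        report = ev._report_from_folds(folds, ("a", "b"))
        assert report.mean_accuracy == pytest.approx(
            np.mean(report.fold_accuracy), rel=1e-12
        )


class TestCrossValidateArousal:
    def test_learnable_images_beat_chance(self, rng):
        rows = {"low": 26, "mid": 16, "high": 5}
        labels = np.array(["low"] * 20 + ["mid"] * 20 + ["high"] * 20)
        images = []
        for cls in labels:
            img = rng.uniform(0, 0.2, size=(32, 32))
            r = rows[cls] + rng.integers(-2, 3)
            img[r - 2 : r + 3, :] += 0.8
            images.append(np.clip(np.repeat(img[:, :, None], 3, axis=2), 0, 1))
        cfg = ev.PipelineConfig(seed=0)
        report = ev.cross_validate_arousal(np.stack(images), labels, cfg)
        assert report.confusion.total == 5 * 12  # 5 folds x 12 validation images
        assert report.mean_accuracy > 0.6


class TestRunSessions:
    def test_smoke_and_determinism(self, protocol, strong_cohort):
        _, cohort = strong_cohort
        cfg = ev.PipelineConfig(seed=4, image_size=32)
        a = ev.run_sessions(cohort, protocol, cfg, train_arousal=False)
        assert len(a["manifest"]["subjects"]) == 2
        for m in a["manifest"]["subjects"]:
            assert m["n_segments"] == 29
        b = ev.run_sessions(cohort, protocol, cfg, train_arousal=False)
        assert a["state_report"].fold_accuracy == b["state_report"].fold_accuracy
        assert a["state_report"].mean_accuracy > 0.8
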