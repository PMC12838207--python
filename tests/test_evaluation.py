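"""Metrics, bootstrap comparison, subclass recovery, embedding export."""

import numpy as np
import pytest

import sacssl as S
from sacssl import evaluation


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = [0, 1, 2, 1, 0]
        cm = S.confusion_matrix(y, y, 3)
        assert np.array_equal(cm.counts, np.diag([2, 2, 1]))

    def test_empty_input_zero_matrix(self):
        cm = S.confusion_matrix([], [], 3)
        assert cm.counts.sum() == 0

    def test_matches_naive_counting(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 3, 50)
        p = rng.integers(0, 3, 50)
        cm = S.confusion_matrix(t, p, 3)
        naive = np.zeros((3, 3), dtype=int)
        for a, b in zip(t, p):
            naive[a, b] += 1
        assert np.array_equal(cm.counts, naive)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            S.confusion_matrix([0, 1], [0], 2)


class TestMetrics:
    def test_perfect_three_class(self):
        cm = S.confusion_matrix([0, 1, 2] * 5, [0, 1, 2] * 5, 3)
        rep = S.metrics(cm)
        assert rep.accuracy == rep.sensitivity == rep.specificity == rep.f1 == 1.0

    def test_binary_hand_arithmetic(self):
        cm = evaluation.ConfusionMatrix(np.array([[8, 2], [3, 7]]))
        rep = S.metrics(cm)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.sensitivity == pytest.approx((0.8 + 0.7) / 2)
        assert rep.specificity == pytest.approx((0.7 + 0.8) / 2)
        assert rep.f1 == pytest.approx((16 / 21 + 14 / 19) / 2)

    def test_constant_predictor_on_balanced_data(self):
        t = [0, 1, 2] * 10
        p = [0] * 30
        rep = S.metrics(S.confusion_matrix(t, p, 3))
        assert rep.accuracy == pytest.approx(1 / 3)
        # per-class loop oracle
        f1_0 = 2 * 10 / (2 * 10 + 20 + 0)
        assert rep.f1 == pytest.approx((f1_0 + 0.0 + 0.0) / 3)

    def test_zero_support_class_warns_and_contributes_zero(self):
        # class 2 absent from truth and predictions: sensitivity/F1 undefined
        t = [0, 1, 0, 1]
        p = [0, 1, 1, 0]
        with pytest.warns(UserWarning):
            rep = S.metrics(S.confusion_matrix(t, p, 3))
        assert rep.per_class_sensitivity[2] == 0.0
        assert rep.per_class_f1[2] == 0.0

    def test_macro_equals_mean_of_per_class(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        rep = S.metrics(S.confusion_matrix(t, p, 4))
        assert rep.sensitivity == pytest.approx(rep.per_class_sensitivity.mean())
        assert rep.f1 == pytest.approx(rep.per_class_f1.mean())

    def test_accuracy_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 3, 100)
        p = rng.integers(0, 3, 100)
        perm = np.array([2, 0, 1])
        a = S.metrics(S.confusion_matrix(t, p, 3)).accuracy
        b = S.metrics(S.confusion_matrix(perm[t], perm[p], 3)).accuracy
        assert a == pytest.approx(b)

    def test_two_accuracy_readings_differ_for_multiclass(self):
        cm = S.confusion_matrix([0, 1, 2, 0], [0, 2, 2, 1], 3)
        rep = S.metrics(cm)
        assert rep.per_class_avg_accuracy != pytest.approx(rep.accuracy)


class TestBootstrap:
    def test_identical_predictions_give_zero_interval(self):
        rng = np.random.default_rng(3)
        t = rng.integers(0, 3, 40)
        p = rng.integers(0, 3, 40)
        low, high = S.bootstrap_f1_diff(p, p, t, n_boot=200, seed=0)
        assert low == 0.0 and high == 0.0

    def test_strictly_better_model_gives_positive_interval(self):
        t = np.array([0, 1] * 30)
        a = t.copy()  # perfect
        b = t.copy()
        b[::3] = 1 - b[::3]  # wrong on a third of items
        low, high = S.bootstrap_f1_diff(a, b, t, n_boot=300, seed=1)
        assert low > 0 and high > 0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        t = rng.integers(0, 2, 50)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        ci1 = S.bootstrap_f1_diff(a, b, t, n_boot=200, seed=7)
        ci2 = S.bootstrap_f1_diff(a, b, t, n_boot=200, seed=7)
        assert ci1 == ci2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            S.bootstrap_f1_diff([0], [0], [0], n_boot=0)
        with pytest.raises(ValueError):
            S.bootstrap_f1_diff([0, 1], [0], [0, 1])


class TestSubclassRecovery:
    def test_exact_agreement_is_one(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        assert S.subclass_recovery_score(y, y)["pooled"] == pytest.approx(1.0)

    def test_random_assignment_near_zero_expectation(self):
        rng = np.random.default_rng(5)
        truth = np.repeat([0, 1, 2], 60)
        scores = [
            S.subclass_recovery_score(rng.permutation(truth), truth)["pooled"]
            for _ in range(50)
        ]
        assert abs(np.mean(scores)) < 0.05

    def test_single_cluster_degenerate_is_zero(self):
        assert S.subclass_recovery_score([0, 0, 0], [0, 1, 2])["pooled"] == 0.0

    def test_within_class_pooling(self):
        cls = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        sub = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        asg = np.array([1, 1, 0, 0, 0, 1, 0, 1])  # perfect in class 0, random in 1
        out = S.subclass_recovery_score(asg, sub, class_labels=cls)
        assert out[0] == pytest.approx(1.0)
        assert out["pooled"] == pytest.approx((out[0] + out[1]) / 2)


class TestEmbeddingExport:
    def test_rows_norms_and_determinism(self, dataset_dir):
        import pandas as pd

        from sacssl.trainer import SACSSL, TrainConfig

        cfg = TrainConfig(bl=4, bu=8, epochs=1, D=16, proj_hidden=16, seed=2)
        model = SACSSL.from_manifest(dataset_dir / "manifest.csv", cfg)
        res = model.fit()
        rows = model.manifest[model.manifest["split"] == "test"].reset_index(drop=True)
        table = res.export_embeddings(rows, dataset_dir)
        assert len(table) == len(rows)
        z = table[[c for c in table.columns if c.startswith("z")]].to_numpy()
        assert np.allclose(np.linalg.norm(z, axis=1), 1.0, atol=1e-6)
        table2 = res.export_embeddings(rows, dataset_dir)
        pd.testing.assert_frame_equal(table, table2)
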