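import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score, precision_score, recall_score

from physiopipe.model import (
    CLASSIFIER_KINDS,
    ExpertiseClassifier,
    compute_metrics,
    loso_folds,
    run_experiment,
    tsne_embed,
)
from physiopipe.types import FeatureMatrix, InvalidParameterError


def random_matrix(n_subjects=10, windows=12, n_feat=6, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        label = labels[i] if labels else ("expert" if i % 2 == 0 else "novice")
        for w in range(windows):
            rows.append({"subject_id": f"s{i}", "label": label, "window_id": w,
                         **{f"f{j}": rng.normal() for j in range(n_feat)}})
    return FeatureMatrix(pd.DataFrame(rows), "ecg", True)


class TestLosoFolds:
    def test_ten_subjects_ten_folds(self):
        m = random_matrix(10)
        folds = loso_folds(m)
        assert len(folds) == 10

    def test_partition_property(self):
        m = random_matrix(7, windows=5)
        folds = loso_folds(m)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(len(m)))
        for train, test in folds:
            assert set(m.groups[train]) & set(m.groups[test]) == set()
            assert len(set(m.groups[test])) == 1

    def test_single_subject_rejected(self):
        with pytest.raises(InvalidParameterError):
            loso_folds(random_matrix(1))


class TestComputeMetrics:
    def test_hand_case(self):
        m = compute_metrics(3, 2, 1, 2)
        assert m["accuracy"] == 0.625
        assert m["precision"] == 0.75
        assert m["recall"] == 0.6
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_case(self):
        m = compute_metrics(5, 5, 0, 0)
        assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 1.0
        assert not m["zero_division"]

    def test_zero_division_flagged(self):
        m = compute_metrics(0, 3, 2, 1)
        assert m["precision"] == 0 and m["f1"] == 0
        assert m["zero_division"]

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_metrics(0, 0, 0, 0)

    def test_matches_sklearn_on_random_tallies(self):
        """Exact agreement with sklearn's confusion-based metrics on 1000
        random label/prediction pairs."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 30)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if y.sum() == 0 and p.sum() == 0:
                continue
            tp = int(np.sum((y == 1) & (p == 1)))
            tn = int(np.sum((y == 0) & (p == 0)))
            fp = int(np.sum((y == 0) & (p == 1)))
            fn = int(np.sum((y == 1) & (p == 0)))
            m = compute_metrics(tp, tn, fp, fn)
            assert m["accuracy"] == pytest.approx(np.mean(y == p))
            assert m["precision"] == pytest.approx(
                precision_score(y, p, zero_division=0))
            assert m["recall"] == pytest.approx(recall_score(y, p, zero_division=0))
            assert m["f1"] == pytest.approx(f1_score(y, p, zero_division=0))


class TestClassifiers:
    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_separable_blobs_near_perfect(self, kind):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (200, 5)), rng.normal(5, 1, (200, 5))])
        y = np.array(["expert"] * 200 + ["novice"] * 200)
        idx = rng.permutation(400)
        train, test = idx[:300], idx[300:]
        clf = ExpertiseClassifier(kind=kind, random_state=0).fit(X[train], y[train])
        assert np.mean(clf.predict(X[test]) == y[test]) >= 0.99

    def test_knn_majority_rule(self):
        X = np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [10.0], [10.1]])
        y = np.array(["expert"] * 5 + ["novice"] * 2)
        clf = ExpertiseClassifier(kind="knn", k=5).fit(X, y)
        assert clf.predict([[0.25]])[0] == "expert"

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            ExpertiseClassifier(kind="mlp").fit(np.zeros((4, 2)), ["a", "b", "a", "b"])

    def test_single_class_training_rejected(self):
        with pytest.raises(InvalidParameterError):
            ExpertiseClassifier().fit(np.zeros((4, 2)), ["a"] * 4)

    def test_sklearn_param_interface(self):
        clf = ExpertiseClassifier(kind="rf", n_trees=10)
        assert clf.get_params()["n_trees"] == 10
        clf.set_params(kind="knn")
        assert clf.kind == "knn"


class TestRunExperiment:
    def test_determinism(self):
        m = random_matrix(6, seed=3)
        r1 = run_experiment(m, ExpertiseClassifier(kind="rf", n_trees=20), seed=5)
        r2 = run_experiment(m, ExpertiseClassifier(kind="rf", n_trees=20), seed=5)
        assert r1.aggregate == r2.aggregate
        assert r1.folds.equals(r2.folds)

    def test_permutation_null_centers_on_chance(self):
        """Random subject labels: mean LOSO accuracy ≈ 0.5 over permutations."""
        rng = np.random.default_rng(7)
        accs = []
        for perm in range(20):
            labels = ["expert"] * 5 + ["novice"] * 5
            rng.shuffle(labels)
            m = random_matrix(10, windows=10, seed=100 + perm, labels=labels)
            r = run_experiment(m, ExpertiseClassifier(kind="knn"), seed=0)
            accs.append(r.aggregate["accuracy"])
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_fold_counts_sum_to_windows(self):
        m = random_matrix(5, windows=9, seed=2)
        r = run_experiment(m, ExpertiseClassifier(kind="dt"), seed=0)
        assert (r.folds[["TP", "TN", "FP", "FN"]].sum(axis=1) == 9).all()
        assert len(r.folds) == 5

    def test_pooled_aggregation(self):
        m = random_matrix(6, windows=8, seed=4)
        r = run_experiment(m, ExpertiseClassifier(kind="knn"),
                           aggregation="pooled-windows", seed=0)
        tp, tn = r.folds["TP"].sum(), r.folds["TN"].sum()
        total = r.folds[["TP", "TN", "FP", "FN"]].to_numpy().sum()
        assert r.aggregate["accuracy"] == pytest.approx((tp + tn) / total)

    def test_invalid_aggregation_rejected(self):
        with pytest.raises(InvalidParameterError):
            run_experiment(random_matrix(4), aggregation="median")


class TestTsne:
    def test_shape_and_determinism(self):
        m = random_matrix(6, windows=10, seed=1)
        df1, _ = tsne_embed(m, iterations=300, seed=3)
        df2, _ = tsne_embed(m, iterations=300, seed=3)
        assert df1.shape == (60, 4)
        assert np.allclose(df1[["dim1", "dim2"]], df2[["dim1", "dim2"]])

    def test_separated_blobs_high_silhouette(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(120):
            label = "expert" if i < 60 else "novice"
            center = 0.0 if i < 60 else 9.0
            rows.append({"subject_id": f"s{i % 10}", "label": label, "window_id": i,
                         **{f"f{j}": rng.normal(center) for j in range(4)}})
        m = FeatureMatrix(pd.DataFrame(rows), "ecg", True)
        _, sil = tsne_embed(m, iterations=500, seed=0)
        assert sil > 0.5

    def test_perplexity_reduced_with_warning(self):
        m = random_matrix(3, windows=5, seed=0)
        with pytest.warns(UserWarning, match="perplexity"):
            df, _ = tsne_embed(m, perplexity=30, iterations=260, seed=0)
        assert df.shape[0] == 15
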