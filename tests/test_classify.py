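"""KNN / MLP classifiers and the accuracy / MCC / CEN metrics."""

import math

import numpy as np
import pytest
import sklearn.metrics as skm

from crxnfp.classify import (
    ConfusionMatrix,
    CosineKNNClassifier,
    confusion_entropy,
    confusion_matrix,
    knn_classify,
    matthews_corrcoef,
    metrics,
    train_mlp,
)


@pytest.fixture(scope="module")
def clustered_embeddings():
    """Three well-separated clusters in 8 dimensions."""
    rng = np.random.default_rng(0)
    centers = np.eye(3).repeat(3, axis=1) * 5  # (3, 9) -> use 9 dims
    X, y = [], []
    for c, center in enumerate(centers):
        X.append(center + rng.normal(scale=0.3, size=(20, 9)))
        y += [f"class{c}"] * 20
    return np.vstack(X), np.array(y, dtype=object)


class TestKNN:
    def test_identical_query_k1_returns_reference_label(self, clustered_embeddings):
        X, y = clustered_embeddings
        assert knn_classify(X, y, X[5:6], k=1)[0] == y[5]

    def test_self_query_accuracy_is_one(self, clustered_embeddings):
        X, y = clustered_embeddings
        preds = knn_classify(X, y, X, k=1)
        assert np.all(preds == y)

    def test_agrees_with_brute_force_oracle(self, clustered_embeddings):
        X, y = clustered_embeddings
        rng = np.random.default_rng(1)
        Q = X + rng.normal(scale=0.5, size=X.shape)
        preds = knn_classify(X, y, Q, k=3)
        # oracle: explicit loops over normalized dot products
        for qi, q in enumerate(Q):
            sims = [(q @ x) / (np.linalg.norm(q) * np.linalg.norm(x)) for x in X]
            ranked = sorted(range(len(X)), key=lambda i: (-sims[i], i))[:3]
            votes = {}
            for i in ranked:
                votes[y[i]] = votes.get(y[i], 0) + 1
            best = max(votes.values())
            tied = {lab for lab, c in votes.items() if c == best}
            expected = next(y[i] for i in ranked if y[i] in tied)
            assert preds[qi] == expected

    def test_tie_broken_by_nearest_among_tied(self):
        X = np.array([[1.0, 0.0], [0.99, 0.14], [0.0, 1.0], [0.14, 0.99]])
        y = np.array(["a", "a", "b", "b"], dtype=object)
        # query closest to class a; k=4 gives a 2-2 vote, nearest neighbor is a
        assert knn_classify(X, y, np.array([[1.0, 0.05]]), k=4)[0] == "a"

    def test_invariant_to_common_rescaling(self, clustered_embeddings):
        X, y = clustered_embeddings
        rng = np.random.default_rng(2)
        Q = X[::3] + rng.normal(scale=0.4, size=X[::3].shape)
        assert np.all(knn_classify(X, y, Q, k=3) == knn_classify(X * 7.5, y, Q * 0.2, k=3))

    def test_k_larger_than_reference_is_error(self, clustered_embeddings):
        X, y = clustered_embeddings
        with pytest.raises(ValueError):
            CosineKNNClassifier(k=len(y) + 1).fit(X, y)


class TestMLP:
    def test_linearly_separable_classes_near_perfect(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-3, 0.5, (40, 4)), rng.normal(3, 0.5, (40, 4))])
        y = ["neg"] * 40 + ["pos"] * 40
        result = train_mlp(X, y, hidden_nodes=32, epochs=200, repeats=3, seed=0)
        assert result["mean"] >= 0.95

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 5))
        y = ["a"] * 30 + ["b"] * 30
        r1 = train_mlp(X, y, hidden_nodes=16, epochs=30, repeats=2, seed=9)
        r2 = train_mlp(X, y, hidden_nodes=16, epochs=30, repeats=2, seed=9)
        assert np.array_equal(r1["accuracies"], r2["accuracies"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_mlp(np.ones((10, 2)), ["x"] * 10)


class TestMetrics:
    def test_perfect_matrix_identities(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9]), ("a", "b", "c"))
        m = metrics(cm)
        assert m == {"accuracy": 1.0, "mcc": 1.0, "cen": 0.0}

    def test_two_class_mcc_matches_hand_computation(self):
        # [[TP, FN], [FP, TN]] = [[8, 2], [1, 9]]
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), ("pos", "neg"))
        expected = (8 * 9 - 1 * 2) / math.sqrt((8 + 1) * (8 + 2) * (9 + 1) * (9 + 2))
        assert matthews_corrcoef(cm) == pytest.approx(expected)

    def test_mcc_agrees_with_sklearn(self):
        rng = np.random.default_rng(5)
        y_true = rng.integers(0, 4, 200)
        y_pred = np.where(rng.random(200) < 0.6, y_true, rng.integers(0, 4, 200))
        cm = confusion_matrix(y_true.tolist(), y_pred.tolist())
        assert matthews_corrcoef(cm) == pytest.approx(skm.matthews_corrcoef(y_true, y_pred))

    def test_symmetric_confusion_has_zero_mcc(self):
        cm = ConfusionMatrix(np.array([[5, 5], [5, 5]]), ("a", "b"))
        assert matthews_corrcoef(cm) == pytest.approx(0.0)

    def test_cen_nonnegative_and_zero_iff_diagonal(self):
        diag = ConfusionMatrix(np.diag([3, 4]), ("a", "b"))
        assert confusion_entropy(diag) == 0.0
        off = ConfusionMatrix(np.array([[3, 1], [2, 4]]), ("a", "b"))
        assert confusion_entropy(off) > 0.0

    def test_cen_hand_computed_two_class(self):
        # C = [[2, 1], [0, 3]]; only class-pair (0,1) misclassifications:
        # denom_0 = row0+col0 = 3+2 = 5 ; P0_{01} = 1/5, P0_{10} = 0
        # denom_1 = row1+col1 = 3+4 = 7 ; P1_{10} = 0, P1_{01} = 1/7
        # base 2(N-1) = 2
        cm = ConfusionMatrix(np.array([[2, 1], [0, 3]]), ("a", "b"))
        h = lambda p: -p * math.log2(p)
        expected = (5 / 12) * h(1 / 5) + (7 / 12) * h(1 / 7)
        assert confusion_entropy(cm) == pytest.approx(expected)

    def test_mcc_invariant_under_class_relabeling(self):
        counts = np.array([[8, 2, 1], [0, 7, 3], [2, 2, 6]])
        cm = ConfusionMatrix(counts, ("a", "b", "c"))
        perm = [2, 0, 1]
        permuted = ConfusionMatrix(counts[np.ix_(perm, perm)], ("c", "a", "b"))
        assert matthews_corrcoef(cm) == pytest.approx(matthews_corrcoef(permuted))
        assert confusion_entropy(cm) == pytest.approx(confusion_entropy(permuted))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.ones((2, 3)), ("a", "b"))
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[1, -1], [0, 2]]), ("a", "b"))
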