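"""Reference creation, KNN label transfer, and is-a-aware evaluation."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import cellensemble as ce


def _clusters(rng, centers, n_per, sigma=1.0):
    dim = len(centers[0])
    points, labels = [], []
    for label, center in centers:
        points.append(rng.normal(loc=center, scale=sigma, size=(n_per, dim)))
        labels.extend([label] * n_per)
    return np.vstack(points), labels


class TestBuildReference:
    def test_query_selection_with_labels(self, small_table, small_bundle):
        ref = ce.build_reference(small_table, "organ==Heart")
        expected = ce.query_cells(small_table, "organ==Heart")
        assert ref.cids == expected
        assert len(ref.labels) == len(ref.cids)
        assert all(ref.labels)

    def test_empty_selection_is_error(self, small_table):
        with pytest.raises(ce.GroupingError):
            ce.build_reference(small_table, "organ==Atlantis")

    def test_unlabeled_cells_excluded_with_warning(self):
        table = ce.UnifiedTable(
            ["G0"], np.zeros((3, 1)),
            [{"organ": "Heart", "uhaf_name": "x"},
             {"organ": "Heart", "uhaf_name": ""},
             {"organ": "Heart", "uhaf_name": "y"}],
        )
        with pytest.warns(UserWarning, match="unlabeled"):
            ref = ce.build_reference(table, "organ==Heart")
        assert ref.cids == [0, 2]


class TestKnnTransfer:
    def test_majority_vote(self):
        ref = np.concatenate([np.zeros((7, 2)), np.ones((3, 2))])
        labels = ["T cell"] * 7 + ["B cell"] * 3
        got = ce.knn_transfer(ref, labels, np.array([[0.4, 0.4]]), k=10)
        assert got == ["T cell"]

    def test_k1_nearest_neighbor(self):
        ref = np.array([[0.0], [10.0]])
        got = ce.knn_transfer(ref, ["a", "b"], np.array([[9.0], [1.0]]), k=1)
        assert got == ["b", "a"]

    def test_tie_broken_by_summed_distance(self):
        # 1-1 tie at k=2: "B cell" neighbor is nearer -> wins
        ref = np.array([[0.0], [3.0]])
        labels = ["T cell", "B cell"]
        got = ce.knn_transfer(ref, labels, np.array([[2.0]]), k=2)
        assert got == ["B cell"]

    def test_tie_broken_lexicographically_at_equal_distance(self):
        ref = np.array([[-1.0], [1.0]])
        got = ce.knn_transfer(ref, ["zz", "aa"], np.array([[0.0]]), k=2)
        assert got == ["aa"]

    def test_separated_clusters_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        centers = [("T cell", (0.0, 0.0)), ("B cell", (20.0, 0.0)),
                   ("Neuron", (0.0, 20.0))]  # >= 10 sigma apart
        ref, ref_labels = _clusters(rng, centers, n_per=50)
        qry, truth = _clusters(rng, centers, n_per=30)
        predicted = ce.knn_transfer(ref, ref_labels, qry, k=10)
        assert ce.evaluate_transfer(predicted, truth).accuracy == 1.0

    def test_dimension_mismatch(self):
        with pytest.raises(ce.DimensionError):
            ce.knn_transfer(np.zeros((5, 3)), ["a"] * 5, np.zeros((2, 2)))

    def test_k_exceeds_reference(self):
        with pytest.raises(ce.DimensionError):
            ce.knn_transfer(np.zeros((3, 1)), ["a"] * 3, np.zeros((1, 1)), k=5)


class TestEvaluateTransfer:
    def test_perfect_agreement(self):
        res = ce.evaluate_transfer(["a", "b", "a"], ["a", "b", "a"])
        assert res.accuracy == 1.0 and res.kappa == 1.0

    def test_hand_computed_confusion(self):
        truth = ["a"] * 50 + ["b"] * 50
        predicted = ["a"] * 40 + ["b"] * 10 + ["a"] * 20 + ["b"] * 30
        res = ce.evaluate_transfer(predicted, truth)
        assert res.confusion.to_numpy().tolist() == [[40, 10], [20, 30]]
        assert res.accuracy == pytest.approx(0.7)
        assert res.kappa == pytest.approx(0.4)
        lo, hi = res.accuracy_ci
        assert lo < 0.7 < hi

    def test_kappa_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(1)
        truth = list(rng.choice(["a", "b", "c"], size=200))
        predicted = list(rng.choice(["a", "b", "c"], size=200))
        res = ce.evaluate_transfer(predicted, truth)
        assert res.kappa == pytest.approx(cohen_kappa_score(truth, predicted))

    def test_is_a_ancestor_counts_correct(self, toy_ontology):
        res = ce.evaluate_transfer(
            ["Dendritic cell"], ["cDC1"], ontology=toy_ontology, allow_is_a=True
        )
        assert res.accuracy == 1.0
        strict = ce.evaluate_transfer(["Dendritic cell"], ["cDC1"])
        assert strict.accuracy == 0.0

    def test_is_a_credit_never_decreases_accuracy(self, toy_ontology):
        rng = np.random.default_rng(2)
        labels = ["T cell", "CD4 T cell", "Treg", "B cell", "Dendritic cell", "cDC1"]
        truth = list(rng.choice(labels, size=100))
        predicted = list(rng.choice(labels, size=100))
        strict = ce.evaluate_transfer(predicted, truth)
        lenient = ce.evaluate_transfer(
            predicted, truth, ontology=toy_ontology, allow_is_a=True
        )
        assert lenient.accuracy >= strict.accuracy
        # chance correction stays on raw labels even with is-a credit
        assert lenient.kappa == strict.kappa

    def test_kappa_uses_strict_labels_under_is_a(self, toy_ontology):
        res = ce.evaluate_transfer(
            ["T cell", "T cell"], ["CD4 T cell", "T cell"],
            ontology=toy_ontology, allow_is_a=True,
        )
        assert res.accuracy == 1.0
        assert res.kappa < 1.0

    def test_confusion_sums_to_query_size(self, toy_ontology):
        res = ce.evaluate_transfer(["a", "b", "c"], ["a", "a", "b"])
        assert res.confusion.to_numpy().sum() == 3

    def test_clopper_pearson_interval(self):
        # neuron-study shape: 0.887 accuracy on n=24313 gives a tight interval
        n, acc = 24_313, 0.887
        k = round(n * acc)
        res = ce.evaluate_transfer(["x"] * k + ["y"] * (n - k), ["x"] * n)
        lo, hi = res.accuracy_ci
        assert lo == pytest.approx(0.883, abs=1e-3)
        assert hi == pytest.approx(0.891, abs=1e-3)

    def test_length_mismatch(self):
        with pytest.raises(ce.DimensionError):
            ce.evaluate_transfer(["a"], ["a", "b"])

    def test_unknown_label_under_is_a(self, toy_ontology):
        with pytest.raises(ce.NameLookupError):
            ce.evaluate_transfer(
                ["T cell"], ["Martian"], ontology=toy_ontology, allow_is_a=True
            )
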