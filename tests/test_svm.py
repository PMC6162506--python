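"""Soft-margin SVM training, prediction, evaluation and dual feasibility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swarmgate as sg
from swarmgate.errors import SchemaError
from swarmgate.kernels import gram
from swarmgate.svm import SV_RTOL

from helpers_qp import oracle_bias, random_binary_problem, solve_dual_qp


class TestTrainBinary:
    def test_two_point_closed_form(self, two_point_table):
        """Symmetric 1-D pair: alpha = 0.5 each, boundary at 0, margin 2."""
        model = sg.train_binary(two_point_table, 10.0, sg.KernelSpec("linear"))
        clf = model.classifiers[0]
        np.testing.assert_allclose(np.abs(clf.dual_weights), [0.5, 0.5])
        assert clf.bias == pytest.approx(0.0, abs=1e-9)
        assert clf.dual_objective == pytest.approx(0.5, abs=1e-9)
        # |w| = 1 so the geometric margin 2/|w| is 2
        w = float(np.sum(clf.dual_weights * clf.support_vectors.ravel()))
        assert 2 / abs(w) == pytest.approx(2.0)
        pred = sg.predict(model, sg.EventTable([[-5.0], [5.0]], ["x"]))
        assert pred.tolist() == [0, 1]

    def test_xor_separable_under_quadratic_kernel(self, xor_table):
        spec = sg.KernelSpec("polynomial", g=1.0, degree=2, coef0=1.0)
        model = sg.train_binary(xor_table, 10.0, spec)
        assert (sg.predict(model, xor_table) == xor_table.labels).all()

    def test_large_c_behaves_hard_margin(self, blobs2):
        model = sg.train_binary(blobs2, 1e6, sg.KernelSpec("linear"))
        assert (sg.predict(model, blobs2) == blobs2.labels).all()

    def test_single_class_rejected(self):
        t = sg.EventTable([[1.0], [2.0]], ["x"], [0, 0])
        with pytest.raises(ValueError):
            sg.train_binary(t, 1.0, sg.KernelSpec("linear"))


class TestMulticlass:
    def test_two_classes_reduces_to_binary(self, blobs2):
        spec = sg.KernelSpec("rbf", g=1.0)
        multi = sg.train_multiclass(blobs2, 5.0, spec)
        binary = sg.train_binary(blobs2, 5.0, spec)
        assert len(multi.classifiers) == 1
        np.testing.assert_allclose(
            multi.classifiers[0].dual_weights, binary.classifiers[0].dual_weights
        )

    def test_three_blobs_rbf_perfect_and_matches_reference(self, blobs3):
        """Cross-check one-vs-one voting against an independent SVM library."""
        model = sg.train_multiclass(blobs3, 10.0, sg.KernelSpec("rbf", g=0.5))
        ours = sg.predict(model, blobs3)
        assert (ours == blobs3.labels).all()
        sklearn_svm = pytest.importorskip("sklearn.svm")
        ref = sklearn_svm.SVC(C=10.0, kernel="rbf", gamma=0.5, decision_function_shape="ovo")
        ref.fit(blobs3.values, blobs3.labels)
        assert (ref.predict(blobs3.values) == ours).all()

    def test_four_classes_give_six_pairs(self):
        rng = np.random.default_rng(0)
        t = sg.EventTable(
            rng.normal(np.repeat(np.arange(4)[:, None] * 4, 10, axis=0), 0.2),
            ["x"],
            np.repeat(np.arange(4), 10),
        )
        model = sg.train_multiclass(t, 1.0, sg.KernelSpec("linear"))
        assert len(model.classifiers) == 6
        assert model.class_pairs == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

    def test_vote_tie_breaks_to_lowest_class(self):
        """A cyclic 3-class tie (one vote each) must return class 0."""
        model = sg.train_multiclass(
            sg.EventTable([[0.0], [1.0], [2.0]], ["x"], [0, 1, 2]),
            10.0,
            sg.KernelSpec("linear"),
        )
        # force a cycle: pair (0,1) votes 1, (1,2) votes 2, (0,2) votes 0
        for clf, (dec) in zip(model.classifiers, [-1.0, 1.0, -1.0]):
            clf.support_vectors = np.array([[0.0]])
            clf.dual_weights = np.array([0.0])
            clf.bias = dec
        # decisions: (0,1) -> -1 votes 1; (0,2) -> +1 votes 0; (1,2) -> -1 votes 2
        pred = sg.predict(model, sg.EventTable([[0.0]], ["x"]))
        assert pred.tolist() == [0]

    def test_channel_mismatch_is_schema_error(self, blobs2):
        model = sg.train_multiclass(blobs2, 1.0, sg.KernelSpec("linear"))
        with pytest.raises(SchemaError):
            sg.predict(model, sg.EventTable([[1.0]], ["other"]))


class TestDualFeasibility:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_alphas_in_box_and_equality_constraint(self, seed):
        rng = np.random.default_rng(seed)
        X, labels, c = random_binary_problem(rng)
        t = sg.EventTable(X, [f"ch{i}" for i in range(X.shape[1])], labels)
        model = sg.train_binary(t, c, sg.KernelSpec("rbf", g=0.5))
        w = model.classifiers[0].dual_weights
        assert (np.abs(w) > 0).all() and (np.abs(w) <= c + 1e-12).all()
        assert abs(w.sum()) < 1e-6  # sum alpha_i y_i = 0


class TestOracleEquivalence:
    def test_smo_matches_dense_qp_on_random_problems(self):
        """Working-set solutions must match the brute-force dual on small
        problems: objective within 1e-4 relative, identical predictions."""
        rng = np.random.default_rng(42)
        families = ["linear", "polynomial", "rbf", "sigmoid"]
        for trial in range(20):
            X, labels, c = random_binary_problem(rng)
            spec = sg.KernelSpec(
                families[trial % 4], g=float(rng.uniform(0.1, 2)), degree=2,
                coef0=1.0, beta=0.5,
            )
            t = sg.EventTable(X, [f"ch{i}" for i in range(X.shape[1])], labels)
            model = sg.train_binary(t, c, spec)
            K = gram(spec, X)
            y = np.where(np.asarray(labels) == 0, 1.0, -1.0)
            alpha, obj_qp = solve_dual_qp(K, y, c, seed=trial)
            obj_smo = model.classifiers[0].dual_objective
            assert obj_smo == pytest.approx(obj_qp, rel=1e-4, abs=1e-6)
            b = oracle_bias(K, alpha, y, c)
            probe = rng.normal(size=(20, X.shape[1]))
            dec = model.classifiers[0].decision(probe, spec)
            f = gram(spec, probe, X) @ (alpha * y) + b
            assert ((dec >= 0) == (f >= 0)).all()


class TestSoftMarginMonotonicity:
    def test_margin_violations_nonincreasing_in_c(self):
        """Raising the penalty c cannot increase margin violations."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1.2, (25, 2)), rng.normal(2.0, 1.2, (25, 2))])
        t = sg.EventTable(X, ["a", "b"], np.repeat([0, 1], 25))
        spec = sg.KernelSpec("linear")
        counts = []
        for c in [0.01, 0.1, 1.0, 10.0, 100.0]:
            clf = sg.train_binary(t, c, spec).classifiers[0]
            y = np.where(t.labels == 0, 1.0, -1.0)
            margins = y * (gram(spec, X, clf.support_vectors) @ clf.dual_weights + clf.bias)
            counts.append(int((margins < 1 - 1e-6).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestEvaluateAndSerialize:
    def test_perfect_prediction_diagonal_confusion(self, blobs3):
        model = sg.train_multiclass(blobs3, 10.0, sg.KernelSpec("rbf", g=0.5))
        rep = sg.evaluate(model, blobs3)
        assert rep.correctness == 100.0
        assert np.all(rep.confusion == np.diag(np.bincount(blobs3.labels)))

    def test_confusion_row_sums_equal_class_counts(self, blobs3):
        model = sg.train_multiclass(blobs3, 10.0, sg.KernelSpec("linear"))
        shuffled = sg.EventTable(
            blobs3.values, blobs3.channel_names, np.roll(blobs3.labels, 7)
        )
        rep = sg.evaluate(model, shuffled)
        assert rep.confusion.sum(axis=1).tolist() == np.bincount(shuffled.labels).tolist()
        assert rep.correctness == pytest.approx(100 * rep.n_correct / rep.n_total)

    def test_unlabeled_test_rejected(self, blobs2):
        model = sg.train_multiclass(blobs2, 1.0, sg.KernelSpec("linear"))
        with pytest.raises(SchemaError):
            sg.evaluate(model, sg.EventTable(blobs2.values, blobs2.channel_names))

    def test_json_round_trip_preserves_predictions(self, tmp_path, blobs3):
        model = sg.train_multiclass(blobs3, 5.0, sg.KernelSpec("polynomial", g=0.8))
        model.scaling = sg.fit_minmax(blobs3)
        path = tmp_path / "model.json"
        sg.save_model(model, path)
        back = sg.load_model(path)
        np.testing.assert_array_equal(sg.predict(back, blobs3), sg.predict(model, blobs3))
        assert back.kernel == model.kernel
        np.testing.assert_allclose(back.scaling.mins, model.scaling.mins)

    def test_support_vector_count_is_union_over_pairs(self, blobs3):
        model = sg.train_multiclass(blobs3, 10.0, sg.KernelSpec("rbf", g=0.5))
        per_pair = [len(c.support_vectors) for c in model.classifiers]
        assert model.n_support_vectors <= sum(per_pair)
        assert model.n_support_vectors >= max(per_pair)
        # every stored alpha is above the support-vector threshold
        for clf in model.classifiers:
            assert (np.abs(clf.dual_weights) > SV_RTOL * model.c).all()
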