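from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from tspred.errors import InputError, TsPredError
from tspred.model import (Prediction, TrainedModel, decision_value,
                          decision_values, feature_weights,
                          format_predictions, load_model, predict_confidence,
                          predict_label, rank_predictions, save_model,
                          svm_seq_view, top_k, train_svm)
from tspred.scorefile import FeatureMatrix

from conftest import random_feature_matrix

DATA = Path(__file__).parent / "data"


def _labelled(X, y, feature_names=None):
    n, d = X.shape
    names = feature_names or [f"f{j}" for j in range(d)]
    ids = [f"s{i:03d}" for i in range(n)]
    labels = pd.Series(np.where(np.asarray(y) > 0, "ts", "non-ts"), index=ids)
    return FeatureMatrix(pd.DataFrame(X, index=ids, columns=names), labels)


def _xor_set(rng, n=80):
    """Four balanced clusters at (±1, ±1); same-sign corners are ts.  No
    linear separator can exceed 3/4 accuracy on this layout."""
    per = n // 4
    centers = [(1, 1), (-1, -1), (1, -1), (-1, 1)]
    X = np.vstack([c + rng.normal(0, 0.15, size=(per, 2)) for c in centers])
    y = np.r_[np.ones(2 * per), -np.ones(2 * per)]
    return _labelled(X, y)


class TestTraining:
    def test_separable_set_fits_perfectly_at_large_C(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, size=(20, 2)),
                       rng.normal(2, 0.3, size=(20, 2))])
        y = np.r_[np.full(20, -1), np.full(20, 1)]
        m = _labelled(X, y)
        model = train_svm(m, kernel="linear", C=1e3, calibrate=False)
        preds = [predict_label(model, x) for x in X]
        assert preds == list(m.labels)

    def test_xor_needs_the_rbf_kernel(self, rng):
        m = _xor_set(rng)
        truth = m.labels.to_numpy()
        lin = train_svm(m, kernel="linear", C=100.0, calibrate=False)
        rbf = train_svm(m, kernel="rbf", C=100.0, gamma=2.0, calibrate=False)
        lin_acc = np.mean([predict_label(lin, x) == t
                           for x, t in zip(m.data.to_numpy(), truth)])
        rbf_acc = np.mean([predict_label(rbf, x) == t
                           for x, t in zip(m.data.to_numpy(), truth)])
        assert lin_acc <= 0.75
        assert rbf_acc == 1.0

    def test_duplicated_training_set_gives_same_decision_function(self, rng):
        m = _xor_set(rng, n=40)
        doubled = FeatureMatrix(pd.concat([m.data, m.data.set_axis(
            [f"{i}b" for i in m.sample_ids])]),
            pd.concat([m.labels, m.labels.set_axis(
                [f"{i}b" for i in m.sample_ids])]))
        a = train_svm(m, kernel="rbf", C=10.0, gamma=1.0, calibrate=False)
        b = train_svm(doubled, kernel="rbf", C=10.0, gamma=1.0, calibrate=False)
        probe = rng.uniform(-1, 1, size=(25, 2))
        np.testing.assert_allclose(decision_values(a, probe),
                                   decision_values(b, probe), atol=1e-6)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        m = _labelled(X, np.ones(10))
        with pytest.raises(TsPredError):
            train_svm(m, kernel="linear")

    def test_non_finite_features_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X[0, 0] = np.inf
        m = _labelled(X, np.r_[np.ones(5), -np.ones(5)])
        with pytest.raises(InputError):
            train_svm(m, kernel="linear")


class TestDecisionValue:
    def test_matches_sklearn_decision_function(self, rng):
        for kernel, gamma in (("linear", None), ("rbf", 0.7)):
            X = rng.normal(size=(60, 5))
            y = np.where(X[:, 0] + 0.3 * rng.normal(size=60) > 0, 1, -1)
            m = _labelled(X, y)
            model = train_svm(m, kernel=kernel, C=2.0, gamma=gamma,
                              calibrate=False)
            mins, rng_ = model.scale_min, model.scale_range
            Xs = (X - mins) / np.where(rng_ > 0, rng_, 1.0)
            svc = SVC(kernel=kernel, C=2.0,
                      gamma=gamma if gamma else "scale").fit(Xs, y)
            ours = decision_values(model, X)
            np.testing.assert_allclose(ours, svc.decision_function(Xs),
                                       rtol=1e-9, atol=1e-9)

    def test_linear_dual_primal_equivalence(self, rng):
        X = rng.normal(size=(50, 4))
        y = np.where(X @ np.array([1.0, -2.0, 0.5, 0.0]) > 0, 1, -1)
        model = train_svm(_labelled(X, y), kernel="linear", C=5.0,
                          calibrate=False)
        w = model.weight_vector()
        for x in rng.normal(size=(20, 4)):
            dual = decision_value(model, x)
            primal = float(w @ model.scale(x) + model.bias)
            assert dual == pytest.approx(primal, rel=1e-9, abs=1e-12)

    def test_point_on_hand_built_hyperplane_has_zero_margin(self):
        # w = (1, 1), b = -1: the line x1 + x2 = 1
        model = TrainedModel(
            kernel="linear", C=1.0, gamma=None, feature_names=["x1", "x2"],
            scale_min=np.zeros(2), scale_range=np.ones(2),
            support_vectors=np.array([[1.0, 0.0], [0.0, 1.0]]),
            dual_coefs=np.array([0.5, 0.5]), bias=-0.5)
        assert decision_value(model, np.array([0.5, 0.5])) == pytest.approx(0.0)

    def test_rbf_at_its_own_support_vector(self):
        model = TrainedModel(
            kernel="rbf", C=1.0, gamma=0.5, feature_names=["a"],
            scale_min=np.zeros(1), scale_range=np.ones(1),
            support_vectors=np.array([[0.3]]),
            dual_coefs=np.array([1.7]), bias=0.2)
        assert decision_value(model, np.array([0.3])) == pytest.approx(1.7 + 0.2)

    def test_dimension_mismatch_rejected(self, rng):
        m = _xor_set(rng, 20)
        model = train_svm(m, kernel="rbf", C=1.0, gamma=1.0, calibrate=False)
        with pytest.raises(InputError):
            decision_value(model, np.zeros(3))

    def test_sign_determines_label(self, rng):
        m = _xor_set(rng, 60)
        model = train_svm(m, kernel="rbf", C=10.0, gamma=1.0, calibrate=False)
        for x in m.data.to_numpy():
            margin = decision_value(model, x)
            assert predict_label(model, x) == ("ts" if margin > 0 else "non-ts")


class TestConfidence:
    def test_zero_margin_maps_to_half(self):
        model = TrainedModel(
            kernel="linear", C=1.0, gamma=None, feature_names=["x1", "x2"],
            scale_min=np.zeros(2), scale_range=np.ones(2),
            support_vectors=np.array([[1.0, 0.0], [0.0, 1.0]]),
            dual_coefs=np.array([0.5, 0.5]), bias=-0.5,
            calibration_slope=2.3)
        assert predict_confidence(model, np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_strictly_monotone_in_margin_and_sign_consistent(self, rng):
        m = _xor_set(rng, 60)
        model = train_svm(m, kernel="rbf", C=10.0, gamma=1.0, calibrate=True,
                          seed=1)
        assert model.calibration_slope > 0
        X = m.data.to_numpy()
        margins = decision_values(model, X)
        confs = np.array([predict_confidence(model, x) for x in X])
        order = np.argsort(margins)
        assert np.all(np.diff(confs[order]) >= 0)
        assert np.all((confs > 0.5) == (margins > 0))

    def test_balanced_set_gives_centered_mean_confidence(self, rng):
        X = np.vstack([rng.normal(-1, 0.7, size=(40, 2)),
                       rng.normal(1, 0.7, size=(40, 2))])
        y = np.r_[np.full(40, -1), np.full(40, 1)]
        model = train_svm(_labelled(X, y), kernel="rbf", C=2.0, gamma=0.5,
                          calibrate=True, seed=0)
        confs = [predict_confidence(model, x) for x in X]
        assert 0.4 <= float(np.mean(confs)) <= 0.6


class TestRanking:
    def _model_with_confidences(self, confs):
        ids = [f"P-A{i + 1}_GLY_Scer" for i in range(len(confs))]
        # single-feature linear model: margin = x, slope 1 → conf = σ(x)
        model = TrainedModel(
            kernel="linear", C=1.0, gamma=None, feature_names=["x"],
            scale_min=np.zeros(1), scale_range=np.ones(1),
            support_vectors=np.array([[1.0]]), dual_coefs=np.array([1.0]),
            bias=0.0)
        margins = [np.log(c / (1 - c)) for c in confs]
        cand = FeatureMatrix(pd.DataFrame({"x": margins}, index=ids))
        return model, cand, ids

    def test_distinct_confidences_rank_in_order(self):
        model, cand, ids = self._model_with_confidences([0.9, 0.2, 0.7, 0.5, 0.4])
        preds = rank_predictions(model, cand)
        assert [p.rank for p in preds] == [1, 2, 3, 4, 5]
        assert preds[0].mutation_id == ids[0]
        confs = [p.confidence for p in preds]
        assert confs == sorted(confs, reverse=True)

    def test_ties_break_lexicographically(self):
        model, cand, ids = self._model_with_confidences([0.6, 0.6, 0.6])
        preds = rank_predictions(model, cand)
        assert [p.mutation_id for p in preds] == sorted(ids)

    def test_empty_candidate_set(self):
        model, cand, _ = self._model_with_confidences([0.5])
        empty = FeatureMatrix(cand.data.iloc[:0])
        assert rank_predictions(model, empty) == []

    def test_top_k_truncates(self):
        model, cand, _ = self._model_with_confidences(
            [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3])
        assert len(top_k(rank_predictions(model, cand), 5)) == 5

    def test_output_format_matches_golden_fixture(self):
        preds = [
            Prediction("YBR109C-F140_GLY_Scer", 0.839, 1),
            Prediction("YBR109C-F140_ASP_Scer", 0.831, 2),
            Prediction("YBR109C-F140_CYS_Scer", 0.783, 3),
            Prediction("YBR109C-F140_PRO_Scer", 0.776, 4),
            Prediction("YBR109C-F140_THR_Scer", 0.769, 5),
        ]
        golden = (DATA / "golden_predictions.txt").read_bytes()
        assert format_predictions(preds).encode() == golden


class TestSeqView:
    def test_keeps_only_sequence_features(self, small_training):
        view = svm_seq_view(small_training)
        assert set(view.feature_names) <= {
            "aminochange", "aminochange2", "pssm_mut", "pssm_nat",
            "pssm_diff", "freq_mut", "freq_nat", "freq_diff", "info_cont"}
        assert len(view.feature_names) <= 9
        assert not any(n.endswith(("Q1", "Q2", "Q3")) for n in view.feature_names)
        assert "ACCP" not in view.feature_names

    def test_idempotent_on_sequence_only_matrix(self, small_training):
        view = svm_seq_view(small_training)
        assert svm_seq_view(view).equals(view)

    def test_rejects_matrix_without_sequence_features(self, rng):
        with pytest.raises(InputError):
            svm_seq_view(random_feature_matrix(rng, 4, 3))


class TestFeatureWeights:
    def test_planted_informative_feature_ranks_first(self, rng):
        X = rng.normal(size=(120, 6))
        y = np.where(X[:, 3] > 0, 1, -1)
        model = train_svm(_labelled(X, y), kernel="linear", C=10.0,
                          calibrate=False)
        ranked = feature_weights(model)
        assert ranked[0][0] == "f3"
        assert ranked[0][1] > 0

    def test_hand_model_orders_by_absolute_weight(self):
        model = TrainedModel(
            kernel="linear", C=1.0, gamma=None, feature_names=["a", "b"],
            scale_min=np.zeros(2), scale_range=np.ones(2),
            support_vectors=np.array([[0.5, -2.0]]),
            dual_coefs=np.array([1.0]), bias=0.0)
        assert [n for n, _ in feature_weights(model)] == ["b", "a"]
        assert feature_weights(model)[0][1] == pytest.approx(-2.0)

    def test_rbf_model_has_no_explicit_weights(self, rng):
        m = _xor_set(rng, 30)
        model = train_svm(m, kernel="rbf", C=1.0, gamma=1.0, calibrate=False)
        with pytest.raises(TsPredError):
            feature_weights(model)


def test_persistence_round_trip_reproduces_decisions(tmp_path, rng):
    m = _xor_set(rng, 50)
    model = train_svm(m, kernel="rbf", C=4.0, gamma=1.5, calibrate=True, seed=2)
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    probe = rng.uniform(-1, 1, size=(10, 2))
    np.testing.assert_array_equal(decision_values(model, probe),
                                  decision_values(back, probe))
    assert back.calibration_slope == model.calibration_slope
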