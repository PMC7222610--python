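import itertools
from dataclasses import dataclass

import numpy as np
import pytest

from fastrbf.classifier import (
    BinaryFastRBF,
    OvOModel,
    Standardizer,
    TrainConfig,
    accuracy,
    decision_value,
    load_ovo,
    predict_binary,
    predict_ovo,
    save_ovo,
    train_binary,
    train_ovo,
    train_rbf_baseline,
)
from fastrbf.rbf_layer import HiddenLayer, hidden_map
from fastrbf.synthetic import generate_blobs
from oracles import gradient_descent_ls


def three_class_table(n_per_class=60, sd=1.0, seed=0):
    return generate_blobs(
        n_per_class, 3,
        centers=[[0.0, 0.0, 0.0], [8.0, 0.0, 0.0], [0.0, 8.0, 0.0]],
        sd=sd, seed=seed, labels=["liver", "kidney", "other"],
    )


class TestTrainBinary:
    def test_separable_blobs_fit_perfectly(self, blob_table):
        model = train_binary(blob_table, TrainConfig(seed=0))
        pred = predict_binary(model, blob_table.X)
        assert accuracy(pred, blob_table.labels) == 1.0

    def test_direct_and_coreset_agree_on_held_out_grid(self, blob_table):
        m_dir = train_binary(blob_table, TrainConfig(seed=0, solver="direct"))
        m_cs = train_binary(blob_table, TrainConfig(seed=0, solver="coreset"))
        rng = np.random.default_rng(0)
        grid = np.zeros((500, 6))
        grid[:, :2] = rng.uniform(-3, 13, size=(500, 2))
        agree = (predict_binary(m_dir, grid) == predict_binary(m_cs, grid)).mean()
        assert agree >= 0.99

    def test_training_is_deterministic(self, blob_table):
        a = train_binary(blob_table, TrainConfig(seed=7))
        b = train_binary(blob_table, TrainConfig(seed=7))
        assert (a.expansion == b.expansion).all()
        assert (a.support_Xtilde == b.support_Xtilde).all()

    def test_single_class_rejected(self, blob_table):
        single = blob_table.restrict_labels(["liver"])
        with pytest.raises(ValueError, match="two classes"):
            train_binary(single, TrainConfig(seed=0))

    def test_train_accuracy_close_between_solvers(self):
        # overlapping classes: exact and core-set solutions may differ
        # slightly, but train accuracy stays within one point
        table = generate_blobs(
            150, 3, centers=[[0, 0, 0], [4.0, 0, 0]], sd=1.0, seed=3,
            labels=["liver", "other"],
        )
        acc = {}
        for solver in ("direct", "coreset"):
            m = train_binary(table, TrainConfig(seed=0, solver=solver))
            acc[solver] = accuracy(predict_binary(m, table.X), table.labels)
        assert abs(acc["direct"] - acc["coreset"]) <= 0.01


class TestDecisionValue:
    def _toy_model(self, expansion):
        layer = HiddenLayer(centers=np.zeros((2, 6)), widths=np.ones(2))
        return BinaryFastRBF(
            hidden=layer,
            scaler=Standardizer(mean=np.zeros(6), std=np.ones(6)),
            support_Xtilde=np.array([[0.5, 0.5], [0.2, 0.8]]),
            expansion=np.asarray(expansion, dtype=float),
            lam=1.0, mu=0.1, sigma2=1.0,
            pos_label="liver", neg_label="other",
        )

    def test_zero_expansion_gives_zero_values(self, rng):
        model = self._toy_model([0.0, 0.0])
        f = decision_value(model, rng.normal(size=(10, 6)))
        np.testing.assert_array_equal(f, 0.0)

    def test_zero_decision_maps_to_positive_class(self, rng):
        model = self._toy_model([0.0, 0.0])
        assert set(predict_binary(model, rng.normal(size=(5, 6)))) == {"liver"}

    def test_sign_rule(self, blob_table):
        model = train_binary(
            blob_table, TrainConfig(seed=0), pos_label="liver", neg_label="other"
        )
        f = decision_value(model, blob_table.X)
        pred = predict_binary(model, blob_table.X)
        assert (pred[f > 0] == "liver").all()
        assert (pred[f < 0] == "other").all()

    def test_support_point_inside_positive_class(self, blob_table):
        model = train_binary(
            blob_table, TrainConfig(seed=0), pos_label="liver", neg_label="other"
        )
        pos = blob_table.restrict_labels(["liver"]).X
        centroid = pos.mean(axis=0, keepdims=True)
        assert decision_value(model, centroid)[0] > 0

    def test_kernel_expansion_matches_manual_loops(self, rng):
        model = self._toy_model([0.7, -0.3])
        X = rng.normal(size=(6, 6))
        f = decision_value(model, X)
        Xt = hidden_map(model.hidden, model.scaler.transform(X))
        for j in range(6):
            expected = sum(
                e * np.exp(-np.sum((s - Xt[j]) ** 2) / (2 * model.sigma2))
                for e, s in zip(model.expansion, model.support_Xtilde)
            )
            assert f[j] == pytest.approx(expected, abs=1e-12)

    def test_wrong_dimension_rejected(self, blob_table):
        model = train_binary(blob_table, TrainConfig(seed=0))
        with pytest.raises(ValueError, match="features"):
            decision_value(model, np.zeros((3, 5)))


class TestOvO:
    def test_three_classifiers_with_expected_pair_sizes(self):
        table = three_class_table(100)
        model = train_ovo(table, TrainConfig(seed=0))
        for clf in model.classifiers:
            assert clf.diagnostics["n_train"] == 200
        pairs = {(c.pos_label, c.neg_label) for c in model.classifiers}
        assert pairs == {("liver", "kidney"), ("liver", "other"), ("kidney", "other")}

    def test_missing_class_is_named(self):
        table = three_class_table().restrict_labels(["liver", "other"])
        with pytest.raises(ValueError, match="missing class: kidney"):
            train_ovo(table, TrainConfig(seed=0))

    def test_deterministic_under_seed(self):
        table = three_class_table(40)
        a = train_ovo(table, TrainConfig(seed=5))
        b = train_ovo(table, TrainConfig(seed=5))
        for ca, cb in zip(a.classifiers, b.classifiers):
            assert (ca.expansion == cb.expansion).all()

    def test_separable_three_class_prediction(self):
        table = three_class_table(80)
        model = train_ovo(table, TrainConfig(seed=0))
        assert accuracy(predict_ovo(model, table.X), table.labels) >= 0.99


@dataclass
class _ConstantClassifier:
    """Stub emitting fixed decision values; used to enumerate vote patterns."""

    pos_label: str
    neg_label: str
    value: float

    def decision_values(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.value)


def _expected_vote_winner(s_ab, s_ac, s_bc, m_ab=1.0, m_ac=1.0, m_bc=1.0):
    """Hand enumeration of the voting rule for one sign pattern."""
    votes = {"liver": 0, "kidney": 0, "other": 0}
    votes["liver" if s_ab >= 0 else "kidney"] += 1
    votes["liver" if s_ac >= 0 else "other"] += 1
    votes["kidney" if s_bc >= 0 else "other"] += 1
    best = max(votes.values())
    tied = [c for c in ("liver", "kidney", "other") if votes[c] == best]
    if len(tied) == 1:
        return tied[0]
    margins = {
        "liver": abs(m_ab) + abs(m_ac),
        "kidney": abs(m_ab) + abs(m_bc),
        "other": abs(m_ac) + abs(m_bc),
    }
    top = max(margins[c] for c in tied)
    for c in ("liver", "kidney", "other"):
        if c in tied and margins[c] == top:
            return c


class TestVoting:
    @pytest.mark.parametrize(
        "signs", list(itertools.product([1.0, -1.0], repeat=3))
    )
    def test_all_eight_patterns_match_hand_enumeration(self, signs):
        s_ab, s_ac, s_bc = signs
        model = OvOModel(
            _ConstantClassifier("liver", "kidney", s_ab * 1.0),
            _ConstantClassifier("liver", "other", s_ac * 2.0),
            _ConstantClassifier("kidney", "other", s_bc * 3.0),
        )
        pred = predict_ovo(model, np.zeros((4, 6)))
        expected = _expected_vote_winner(
            s_ab, s_ac, s_bc, s_ab * 1.0, s_ac * 2.0, s_bc * 3.0
        )
        assert set(pred) == {expected}

    def test_unanimous_kidney_pattern(self):
        # B over A, B over C, A over C -> votes (A, B, C) = (1, 2, 0)
        model = OvOModel(
            _ConstantClassifier("liver", "kidney", -0.5),
            _ConstantClassifier("liver", "other", 0.5),
            _ConstantClassifier("kidney", "other", 0.5),
        )
        assert predict_ovo(model, np.zeros((1, 6)))[0] == "kidney"

    def test_cyclic_tie_resolved_by_margin(self):
        # A beats B, C beats A, B beats C: 1-1-1; 'other' has the largest
        # summed |decision| (|-5| + |-4|)
        model = OvOModel(
            _ConstantClassifier("liver", "kidney", 1.0),
            _ConstantClassifier("liver", "other", -5.0),
            _ConstantClassifier("kidney", "other", 4.0),
        )
        assert predict_ovo(model, np.zeros((1, 6)))[0] == "other"

    def test_residual_tie_falls_back_to_priority(self):
        model = OvOModel(
            _ConstantClassifier("liver", "kidney", 1.0),
            _ConstantClassifier("liver", "other", -1.0),
            _ConstantClassifier("kidney", "other", 1.0),
        )
        # margins all equal (2.0): priority says liver
        assert predict_ovo(model, np.zeros((1, 6)))[0] == "liver"


class TestAccuracy:
    def test_simple_ratios(self):
        assert accuracy(["a", "b"], ["a", "b"]) == 1.0
        assert accuracy(["a", "b", "a", "a"], ["a", "b", "b", "a"]) == 0.75

    def test_matches_brute_force_count(self, rng):
        pred = rng.choice(["x", "y", "z"], size=200)
        truth = rng.choice(["x", "y", "z"], size=200)
        manual = sum(p == t for p, t in zip(pred, truth)) / 200
        assert accuracy(pred, truth) == pytest.approx(manual)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy([], [])


class TestBaseline:
    def test_separable_blobs_fit_perfectly(self, blob_table):
        model = train_rbf_baseline(blob_table, TrainConfig(seed=0))
        assert accuracy(predict_binary(model, blob_table.X), blob_table.labels) == 1.0

    def test_normal_equation_residual_orthogonality(self, blob_table):
        cfg = TrainConfig(seed=0, baseline_ridge=1e-14)
        model = train_rbf_baseline(blob_table, cfg)
        Xt = hidden_map(model.hidden, model.scaler.transform(blob_table.X))
        y = np.where(blob_table.labels.astype(str) == "liver", 1.0, -1.0)
        resid = Xt @ model.weights - y
        assert np.abs(Xt.T @ resid).max() < 1e-6

    def test_matches_converged_gradient_descent(self, blob_table):
        cfg = TrainConfig(seed=0, baseline_ridge=1e-14)
        model = train_rbf_baseline(blob_table, cfg)
        Xt = hidden_map(model.hidden, model.scaler.transform(blob_table.X))
        y = np.where(blob_table.labels.astype(str) == "liver", 1.0, -1.0)
        w_gd = gradient_descent_ls(Xt, y)
        np.testing.assert_allclose(model.weights, w_gd, atol=1e-4)

    def test_baseline_solver_route(self, blob_table):
        model = train_binary(blob_table, TrainConfig(seed=0, solver="baseline"))
        assert model.diagnostics["solver"] == "baseline"


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        table = three_class_table(50)
        model = train_ovo(table, TrainConfig(seed=0))
        path = tmp_path / "model.npz"
        save_ovo(model, path)
        back = load_ovo(path)
        X = rng.normal(size=(40, 6)) * 3
        assert (predict_ovo(model, X) == predict_ovo(back, X)).all()
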