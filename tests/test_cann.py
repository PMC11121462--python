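"""MLP classifier: scaling, forward pass, gradients, training, evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melipact import (
    HoneySample,
    HoneyType,
    MLPModel,
    Region,
    SampleTable,
    TrainingConfig,
    evaluate_classifier,
    forward_probabilities,
    normalize_features,
    train_classifier,
)
from melipact.cann import (
    FEATURES,
    N_IN,
    N_OUT,
    loss_and_grad,
    penalized_loss_and_grad,
    stratified_split,
    _init_theta,
    _pack,
    _unpack,
)


def _table(records):
    return SampleTable(records)


def make(i, honey_type, **kw):
    base = dict(
        sample_id=f"s{i}",
        declared_type=honey_type,
        region=Region.EASTERN,
        year=2020,
        glu=30.0,
        fru=38.0,
        suc=1.0,
        hmf=5.0,
        mc=16.0,
        acid=12.0,
        dia=12.0,
        ins=0.01,
        econd=0.3,
    )
    base.update(kw)
    return HoneySample(**base)


class TestNormalization:
    def test_minmax_scaling(self):
        t = _table([make(i, HoneyType.ACACIA, glu=g) for i, g in enumerate([2.0, 4.0, 6.0])])
        x, fmin, fmax = normalize_features(t)
        gi = FEATURES.index("glu")
        assert list(x[:, gi]) == [0.0, 0.5, 1.0]

    def test_constant_feature_maps_to_zero(self):
        t = _table([make(i, HoneyType.ACACIA) for i in range(3)])
        x, _, _ = normalize_features(t)
        assert np.all(x == 0.0)

    def test_inverse_scaling_round_trip(self):
        rng = np.random.default_rng(0)
        records = [
            make(
                i,
                HoneyType.POLYFLORAL,
                glu=20 + 10 * rng.random(),
                fru=30 + 10 * rng.random(),
                acid=5 + 20 * rng.random(),
                econd=0.1 + rng.random(),
            )
            for i in range(20)
        ]
        t = _table(records)
        x, fmin, fmax = normalize_features(t)
        raw = np.array([[getattr(s, f) for f in FEATURES] for s in t])
        recovered = x * (fmax - fmin) + fmin
        span = fmax - fmin
        assert np.max(np.abs(recovered[:, span > 0] - raw[:, span > 0])) < 1e-12


def _random_model(rng):
    return MLPModel(
        w1=rng.normal(0, 2, (12, N_IN)),
        b1=rng.normal(0, 2, 12),
        w2=rng.normal(0, 2, (N_OUT, 12)),
        b2=rng.normal(0, 2, N_OUT),
        feature_min=np.zeros(N_IN),
        feature_max=np.ones(N_IN),
    )


class TestForward:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_softmax_sums_to_one_for_random_models(self, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(rng)
        x = rng.random(N_IN)
        p = forward_probabilities(model, x)
        assert abs(p.sum() - 1.0) < 1e-9
        assert np.all(p >= 0)

    def test_zero_weights_give_uniform_probabilities(self):
        model = MLPModel(
            w1=np.zeros((12, N_IN)),
            b1=np.zeros(12),
            w2=np.zeros((N_OUT, 12)),
            b2=np.zeros(N_OUT),
            feature_min=np.zeros(N_IN),
            feature_max=np.ones(N_IN),
        )
        p = forward_probabilities(model, np.random.default_rng(0).random(N_IN))
        assert np.allclose(p, 1 / 6)

    def test_small_network_matches_hand_computed_pass(self):
        """2-2-2 toy weights, propagated by explicit scalar arithmetic."""
        w1 = np.array([[0.5, -1.0], [0.25, 0.75]])
        b1 = np.array([0.1, -0.2])
        w2 = np.array([[1.0, -0.5], [-0.25, 0.5]])
        b2 = np.array([0.05, -0.05])
        x = np.array([0.3, 0.9])
        # hand arithmetic with math.exp
        z1 = [0.5 * 0.3 - 1.0 * 0.9 + 0.1, 0.25 * 0.3 + 0.75 * 0.9 - 0.2]
        h = [1 / (1 + math.exp(-z)) for z in z1]
        z2 = [
            1.0 * h[0] - 0.5 * h[1] + 0.05,
            -0.25 * h[0] + 0.5 * h[1] - 0.05,
        ]
        m = max(z2)
        e = [math.exp(z - m) for z in z2]
        expected = [v / sum(e) for v in e]

        model = MLPModel(
            w1=w1, b1=b1, w2=w2, b2=b2,
            feature_min=np.zeros(2), feature_max=np.ones(2),
        )
        p = forward_probabilities(model, x)
        assert p == pytest.approx(expected, abs=1e-6)

    def test_parameter_count_is_186(self):
        rng = np.random.default_rng(0)
        assert _random_model(rng).n_parameters == 8 * 12 + 12 + 12 * 6 + 6 == 186


class TestGradient:
    @pytest.mark.parametrize("weight_decay", [0.0, 1e-3])
    def test_analytic_gradient_matches_central_differences(self, weight_decay):
        rng = np.random.default_rng(7)
        x = rng.random((25, N_IN))
        labels = rng.integers(0, N_OUT, 25)
        y = np.eye(N_OUT)[labels]
        theta = _init_theta(rng, 12, 0.5)
        _, grad = penalized_loss_and_grad(theta, x, y, 12, weight_decay)
        eps = 1e-6
        idx = rng.choice(theta.size, 40, replace=False)
        for i in idx:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (
                penalized_loss_and_grad(tp, x, y, 12, weight_decay)[0]
                - penalized_loss_and_grad(tm, x, y, 12, weight_decay)[0]
            ) / (2 * eps)
            err = abs(grad[i] - fd)
            # absolute floor guards components at the FD noise scale
            assert err / max(abs(fd), abs(grad[i]), 1e-8) < 1e-5 or err < 1e-9

    def test_pack_unpack_round_trip(self):
        rng = np.random.default_rng(1)
        theta = rng.normal(size=186)
        assert np.array_equal(_pack(*_unpack(theta, 12)), theta)


def _blob_table(n_per_class=50, gap=4.0, seed=0):
    """Two classes separated by ~4 SD in two features."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_per_class):
        records.append(
            make(i, HoneyType.ACACIA, glu=rng.normal(25, 1), acid=rng.normal(10, 1))
        )
        records.append(
            make(
                n_per_class + i,
                HoneyType.HONEYDEW,
                glu=rng.normal(25 + gap, 1),
                acid=rng.normal(10 + gap, 1),
                econd=0.3,
            )
        )
    return _table(records)


class TestTraining:
    def test_linearly_separable_classes_reach_full_training_accuracy(self):
        table = _blob_table()
        config = TrainingConfig(
            restarts=2, max_iter=300, weight_decay=0.0, val_fraction=0.0,
            split_seed=0, init_seed=0,
        )
        _, reports = train_classifier(table, config)
        assert reports["train"].accuracy == 100.0

    def test_training_is_deterministic(self):
        table = _blob_table()
        config = TrainingConfig(restarts=2, max_iter=60, split_seed=1, init_seed=1)
        m1, _ = train_classifier(table, config)
        m2, _ = train_classifier(table, config)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.b2, m2.b2)

    def test_accepted_bfgs_steps_never_increase_loss(self):
        """Wolfe line search: the penalized loss is monotone over iterates."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(3)
        x = rng.random((60, N_IN))
        y = np.eye(N_OUT)[rng.integers(0, N_OUT, 60)]
        theta0 = _init_theta(rng, 12, 0.5)
        losses = [penalized_loss_and_grad(theta0, x, y, 12, 1e-4)[0]]
        minimize(
            penalized_loss_and_grad,
            theta0,
            args=(x, y, 12, 1e-4),
            method="BFGS",
            jac=True,
            callback=lambda tk: losses.append(
                penalized_loss_and_grad(tk, x, y, 12, 1e-4)[0]
            ),
            options={"maxiter": 120},
        )
        diffs = np.diff(losses)
        assert np.all(diffs <= 1e-10)

    def test_single_class_is_an_error(self):
        table = _table([make(i, HoneyType.ACACIA) for i in range(10)])
        with pytest.raises(ValueError):
            train_classifier(table, TrainingConfig(restarts=1, max_iter=5))

    def test_stratified_split_keeps_every_class_in_training(self):
        labels = np.array([0] * 50 + [1] * 3 + [2] * 7)
        train, test = stratified_split(labels, 0.7, seed=0, stratify=True)
        assert set(labels[train]) == {0, 1, 2}
        assert len(train) + len(test) == labels.size
        assert np.intersect1d(train, test).size == 0

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        model = _random_model(rng)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = MLPModel.from_json(path)
        assert np.allclose(loaded.w1, model.w1) and np.allclose(loaded.b2, model.b2)
        assert loaded.classes == model.classes


def test_agrees_with_independent_mlp_on_separable_data():
    """Cross-check: scikit-learn's quasi-Newton MLP reaches the same
    (perfect) solution on well-separated classes."""
    from sklearn.neural_network import MLPClassifier

    table = _blob_table(gap=8.0, seed=2)
    config = TrainingConfig(restarts=2, max_iter=300, weight_decay=0.0, val_fraction=0.0)
    model, reports = train_classifier(table, config)

    x, _, _ = normalize_features(table)
    labels = np.array([0 if s.declared_type is HoneyType.ACACIA else 1 for s in table])
    sk = MLPClassifier(
        hidden_layer_sizes=(12,), activation="logistic", solver="lbfgs",
        max_iter=300, random_state=0,
    ).fit(x, labels)
    ours = np.atleast_2d(forward_probabilities(model, x)).argmax(1)
    ours = (ours != 0).astype(int)  # acacia is class index 0
    assert sk.score(x, labels) == 1.0
    assert np.array_equal(ours, sk.predict(x))


class TestEvaluation:
    def test_perfect_predictions_give_diagonal_confusion(self):
        table = _blob_table(gap=8.0)
        config = TrainingConfig(
            restarts=2, max_iter=300, weight_decay=0.0, val_fraction=0.0
        )
        model, _ = train_classifier(table, config)
        report = evaluate_classifier(model, table)
        # separable blobs: off-diagonal mass only where classes are absent
        assert report.confusion.sum() == len(table)
        rates = report.per_class_rate
        assert rates["acacia"] == 100.0 and rates["honeydew"] == 100.0

    def test_per_class_rate_is_diagonal_over_row_sum(self, fixture_table):
        config = TrainingConfig(restarts=1, max_iter=40)
        model, _ = train_classifier(fixture_table, config)
        report = evaluate_classifier(model, fixture_table)
        conf = report.confusion
        for i, c in enumerate(model.classes):
            row = conf[i].sum()
            if row:
                assert report.per_class_rate[c.value] == pytest.approx(
                    100.0 * conf[i, i] / row
                )

    def test_empty_table_is_an_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            evaluate_classifier(_random_model(rng), _table([]))
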