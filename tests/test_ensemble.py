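import numpy as np
import pytest

import wvcnn
from wvcnn import (
    DatasetBundle,
    EnsembleWeights,
    ExpressionMatrix,
    LabelVector,
    SyntheticSpec,
    TrainingConfig,
    ValidationError,
    build_architecture,
    generate_dataset,
    predict_classes,
    train_ensemble,
    weighted_vote,
)
from wvcnn import nn
from wvcnn.ensemble import _instantiate


class TestArchitectures:
    def test_member_layer_plans(self):
        ecn1 = build_architecture("ECN1", 7)
        assert [l.kind for l in ecn1] == ["conv1d", "flatten", "dense", "dense"]
        assert (ecn1[0].filters, ecn1[0].kernel) == (4, 3)
        assert ecn1[2].neurons == 6  # hidden dense width

        ecn2 = build_architecture("ECN2", 7)
        assert [l.kind for l in ecn2] == [
            "conv1d", "flatten", "dense", "dropout", "dense",
        ]
        assert (ecn2[0].filters, ecn2[0].kernel) == (3, 3)
        assert ecn2[2].neurons == 8
        assert ecn2[3].rate == 0.3

        ecn3 = build_architecture("ECN3", 2)
        assert [l.kind for l in ecn3] == ["conv1d", "flatten", "dense"]
        assert (ecn3[0].filters, ecn3[0].kernel) == (5, 3)
        assert ecn3[-1].neurons == "len(classes)"

    def test_unknown_member_rejected(self):
        with pytest.raises(ValidationError):
            build_architecture("ECN4", 3)

    def test_instantiated_output_is_a_distribution(self):
        rng = np.random.default_rng(0)
        for member in ("ECN1", "ECN2", "ECN3"):
            net = _instantiate(build_architecture(member, 5), 20, 5, "softmax", rng)
            probs = net.predict_proba(rng.uniform(size=(6, 20)))
            assert probs.shape == (6, 5)
            assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
            assert (probs >= 0).all()


class TestBackpropagation:
    def test_gradients_match_finite_differences(self):
        """Analytic gradients of the cross-entropy loss through conv, dense
        and softmax layers agree with central finite differences."""
        rng = np.random.default_rng(3)
        net = _instantiate(build_architecture("ECN1", 3), 10, 3, "softmax", rng)
        x = rng.uniform(size=(4, 10))
        targets = np.eye(3)[rng.integers(3, size=4)]

        def loss():
            probs = net.forward(x, training=False)
            return -np.mean(np.sum(targets * np.log(probs + 1e-12), axis=1))

        probs = net.forward(x, training=False)
        net.backward((probs - targets) / len(x))
        analytic = [g.copy() for g in net.grads]

        eps = 1e-6
        for p, g in zip(net.params, analytic):
            flat_p, flat_g = p.ravel(), g.ravel()
            for idx in rng.choice(flat_p.size, size=min(10, flat_p.size), replace=False):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                hi = loss()
                flat_p[idx] = orig - eps
                lo = loss()
                flat_p[idx] = orig
                assert (hi - lo) / (2 * eps) == pytest.approx(flat_g[idx], abs=1e-5)


class TestVoting:
    def test_hand_worked_fusion_example(self):
        p1, p2, p3 = [[0.6, 0.4]], [[0.2, 0.8]], [[0.5, 0.5]]
        fused = weighted_vote([p1, p2, p3], EnsembleWeights((0.4, 0.3, 0.3)))
        assert np.allclose(fused, [[0.45, 0.55]])
        assert predict_classes(fused).labels.tolist() == [1]

    def test_identical_members_reproduce_the_member(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(4), size=8)
        fused = weighted_vote([p, p, p], EnsembleWeights())
        assert np.allclose(fused, p, atol=1e-12)

    def test_degenerate_weights_select_one_member(self):
        rng = np.random.default_rng(2)
        mats = [rng.dirichlet(np.ones(3), size=5) for _ in range(3)]
        fused = weighted_vote(mats, EnsembleWeights((1.0, 0.0, 0.0)))
        assert np.array_equal(fused, mats[0])

    def test_rows_remain_distributions_and_vote_is_linear(self):
        rng = np.random.default_rng(4)
        w = EnsembleWeights((0.4, 0.3, 0.3))
        for _ in range(50):
            mats = [rng.dirichlet(np.ones(5), size=7) for _ in range(3)]
            fused = weighted_vote(mats, w)
            assert np.allclose(fused.sum(axis=1), 1.0, atol=1e-6)
            scaled = weighted_vote([2.0 * m for m in mats], w)
            assert np.allclose(scaled, 2.0 * fused)

    def test_shape_and_weight_validation(self):
        with pytest.raises(ValidationError):
            weighted_vote([np.ones((2, 2))] * 2, EnsembleWeights())
        with pytest.raises(ValidationError):
            weighted_vote(
                [np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 2))], EnsembleWeights()
            )
        with pytest.raises(ValidationError):
            EnsembleWeights((0.5, 0.3, 0.3))
        with pytest.raises(ValidationError):
            EnsembleWeights((-0.2, 0.6, 0.6))

    def test_argmax_ties_resolve_to_lowest_class_index(self):
        probs = np.array([[0.5, 0.5], [0.45, 0.55], [1.0, 0.0]])
        assert predict_classes(probs).labels.tolist() == [0, 1, 0]

    def test_one_hot_rows_map_to_their_hot_index(self):
        probs = np.eye(4)[[2, 0, 3]]
        assert predict_classes(probs).labels.tolist() == [2, 0, 3]


def two_class_bundle(seed=0, n=200, n_features=300):
    spec = SyntheticSpec(
        class_counts=[n // 2, n // 2], n_features=n_features,
        n_informative=min(30, n_features // 2), effect_size=3.0, seed=seed,
    )
    return generate_dataset(spec)


class TestTraining:
    def test_separable_data_reaches_high_training_accuracy(self):
        bundle = two_class_bundle(seed=10)
        model = train_ensemble(bundle, TrainingConfig(seed=1, epochs=40))
        pred = model.predict(bundle.expression.values)
        acc = (pred.labels == bundle.labels.labels).mean()
        assert acc >= 0.95

    def test_training_is_deterministic_under_fixed_seed(self):
        bundle = two_class_bundle(seed=3, n=60, n_features=30)
        cfg = TrainingConfig(seed=5, epochs=8)
        held_out = np.random.default_rng(0).uniform(2, 8, size=(10, 30))
        probs_a = train_ensemble(bundle, cfg).predict_proba(held_out)
        probs_b = train_ensemble(bundle, cfg).predict_proba(held_out)
        assert np.array_equal(probs_a, probs_b)

    def test_members_differ_but_fuse_to_valid_distribution(self):
        bundle = two_class_bundle(seed=4, n=60, n_features=30)
        model = train_ensemble(bundle, TrainingConfig(seed=2, epochs=8))
        member_probs = model.member_probabilities(bundle.expression.values)
        assert not np.allclose(member_probs[0], member_probs[1])
        fused = model.predict_proba(bundle.expression.values)
        assert np.allclose(fused.sum(axis=1), 1.0, atol=1e-6)

    def test_constant_features_train_without_numeric_failure(self):
        values = np.full((20, 10), 4.2)
        bundle = DatasetBundle(
            ExpressionMatrix(values, [f"f{i}" for i in range(10)],
                             [f"S{i}" for i in range(20)]),
            LabelVector([0] * 10 + [1] * 10, ["A", "B"]),
        )
        model = train_ensemble(bundle, TrainingConfig(seed=0, epochs=3))
        probs = model.predict_proba(values)
        assert np.isfinite(probs).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_too_few_features_or_single_class_rejected(self):
        short = DatasetBundle(
            ExpressionMatrix(np.ones((4, 2)), ["a", "b"], list("WXYZ")),
            LabelVector([0, 0, 1, 1], ["A", "B"]),
        )
        with pytest.raises(ValidationError, match="kernel"):
            train_ensemble(short, TrainingConfig(epochs=1))
        single = DatasetBundle(
            ExpressionMatrix(np.ones((4, 5)), [f"f{i}" for i in range(5)], list("WXYZ")),
            LabelVector([0, 0, 0, 0], ["A", "B"]),
        )
        with pytest.raises(ValidationError, match="single class"):
            train_ensemble(single, TrainingConfig(epochs=1))

    def test_model_round_trips_through_disk(self, tmp_path):
        bundle = two_class_bundle(seed=6, n=40, n_features=20)
        model = train_ensemble(bundle, TrainingConfig(seed=3, epochs=5))
        wvcnn.save_model(model, str(tmp_path / "model"))
        again = wvcnn.load_model(str(tmp_path / "model"))
        X = bundle.expression.values
        assert np.allclose(model.predict_proba(X), again.predict_proba(X))
        assert again.class_names == model.class_names

    def test_hard_voting_option_returns_labels(self):
        bundle = two_class_bundle(seed=7, n=40, n_features=20)
        model = train_ensemble(bundle, TrainingConfig(seed=4, epochs=5))
        hard = model.predict(bundle.expression.values, voting="hard")
        soft = model.predict(bundle.expression.values, voting="soft")
        assert hard.labels.shape == soft.labels.shape
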