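"""The five estimators: backbone shape arithmetic, CNN construction,
classical baselines, and the hybrid predictor."""

import numpy as np
import pytest

from enoseml import (
    BPNNSpec,
    BackboneSpec,
    RFRParams,
    SVRParams,
    backbone_output_shape,
    build_1dcnn,
    build_backbone,
    fit_bpnn,
    fit_rfr,
    fit_svr,
    hybrid_predict,
)
from enoseml.models import ConvBlock, PoolBlock, feature_width

#: The backbone layer table for a (10, 100) input.
EXPECTED_STACK = [
    ("Conv1", 16, 50),
    ("Conv2", 32, 48),
    ("Pool1", 32, 24),
    ("Conv3", 64, 12),
    ("Pool2", 64, 6),
    ("Conv4", 128, 3),
    ("Pool3", 128, 1),
    ("Flatten", 128, 1),
]


class TestShapeArithmetic:
    def test_default_backbone_reproduces_the_layer_table(self):
        assert backbone_output_shape() == EXPECTED_STACK

    def test_agrees_with_bruteforce_oracle_on_random_configs(self):
        # independent oracle: simulate the sliding window index-by-index
        def brute_len(length, kernel, stride, padding):
            positions = 0
            start = -padding
            while start + kernel <= length + padding:
                positions += 1
                start += stride
            return positions

        rng = np.random.default_rng(42)
        for _ in range(200):
            k = int(rng.integers(1, 6))
            s = int(rng.integers(1, 4))
            p = int(rng.integers(0, 3))
            length = int(rng.integers(k + 1, 120))
            ch = int(rng.integers(1, 8))
            spec = BackboneSpec(
                layers=(("L", ConvBlock(4, k, stride=s, padding=p)),),
                in_channels=ch, in_length=length)
            got = backbone_output_shape(spec)[0]
            assert got == ("L", 4, brute_len(length, k, s, p))

    def test_too_short_input_names_the_offending_layer(self):
        # length 4 survives Conv1 (-> 2) but is shorter than Conv2's
        # unpadded kernel
        with pytest.raises(ValueError, match="Conv2"):
            backbone_output_shape(input_shape=(10, 4))

    def test_flatten_width_is_128(self):
        assert feature_width() == 128


class TestBackbone:
    def test_batch_forward_yields_128_features(self):
        bb = build_backbone(seed=0)
        x = np.random.default_rng(0).normal(1.5, 0.4, (5, 10, 100))
        assert bb.forward(x).shape == (5, 128)

    def test_same_seed_same_initial_outputs(self):
        x = np.random.default_rng(1).normal(1.5, 0.4, (3, 10, 100))
        a = build_backbone(seed=7).forward(x)
        b = build_backbone(seed=7).forward(x)
        assert np.array_equal(a, b)

    def test_wrong_input_length_is_a_shape_error(self):
        bb = build_backbone(seed=0)
        with pytest.raises(ValueError, match="100"):
            bb.forward(np.ones((2, 10, 99)))


class TestCNNRegressor:
    def test_scalar_output_per_sample_and_finite(self):
        m = build_1dcnn(seed=0)
        x = np.random.default_rng(2).normal(1.5, 0.4, (5, 10, 100))
        pred = m.predict(x)
        assert pred.shape == (5,)
        assert np.all(np.isfinite(pred))

    def test_backbone_is_shared_by_reference(self):
        m = build_1dcnn(seed=0)
        x = np.random.default_rng(3).normal(1.5, 0.4, (2, 10, 100))
        before = m.predict(x)
        # mutate through the extracted backbone view
        m.backbone.net.params()[0].v += 0.05
        after = m.predict(x)
        assert not np.allclose(before, after)

    def test_state_dict_round_trip(self):
        m = build_1dcnn(seed=0)
        x = np.random.default_rng(4).normal(1.5, 0.4, (2, 10, 100))
        state = m.state_dict()
        ref = m.predict(x)
        m.backbone.net.params()[0].v += 1.0
        m.load_state_dict(state)
        assert np.array_equal(m.predict(x), ref)


class TestRandomForest:
    def test_constant_labels_give_constant_predictions(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (30, 10))
        f = fit_rfr(X, np.full(30, 0.4), RFRParams(seed=0))
        assert np.allclose(f.predict(rng.normal(0, 1, (10, 10))), 0.4)

    def test_predictions_bounded_by_training_labels(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (100, 10))
        y = rng.uniform(0, 0.6, 100)
        f = fit_rfr(X, y, RFRParams(seed=0))
        far = rng.normal(0, 10, (50, 10))
        pred = f.predict(far)
        assert pred.min() >= y.min() - 1e-12
        assert pred.max() <= y.max() + 1e-12

    def test_single_stump_recovers_group_means(self):
        # one binary feature perfectly splitting two label groups: a
        # depth-1 tree without bootstrap must return the group means
        X = np.array([[0.0]] * 10 + [[1.0]] * 10)
        y = np.array([0.0] * 10 + [1.0] * 10)
        f = fit_rfr(X, y, RFRParams(n_trees=1, max_depth=1,
                                    bootstrap=False, seed=0,
                                    max_features_frac=1.0))
        assert np.allclose(f.predict([[0.0]]), 0.0)
        assert np.allclose(f.predict([[1.0]]), 1.0)

    def test_prediction_invariant_to_tree_order(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (60, 10))
        y = rng.uniform(0, 1, 60)
        f = fit_rfr(X, y, RFRParams(n_trees=20, seed=0))
        q = rng.normal(0, 1, (5, 10))
        ref = f.predict(q)
        f.estimators_ = list(reversed(f.estimators_))
        assert np.allclose(f.predict(q), ref)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_rfr(np.empty((0, 10)), np.empty(0))

    def test_more_trees_reduce_prediction_variance_across_seeds(self):
        # bagging: the across-seed variance of the ensemble prediction
        # shrinks as trees are added
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (80, 5))
        y = X[:, 0] + rng.normal(0, 0.3, 80)
        q = rng.normal(0, 1, (1, 5))

        def spread(n_trees):
            preds = [fit_rfr(X, y, RFRParams(n_trees=n_trees,
                                             seed=s)).predict(q)[0]
                     for s in range(20)]
            return np.var(preds)

        assert spread(50) < spread(2)


class TestSVRAndBPNN:
    def test_svr_on_constant_labels_predicts_within_epsilon(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (50, 10))
        m = fit_svr(X, np.full(50, 0.3), SVRParams(epsilon=0.1))
        assert np.all(np.abs(m.predict(X) - 0.3) <= 0.1 + 1e-6)

    def test_svr_requires_ten_columns(self):
        with pytest.raises(ValueError, match="10"):
            fit_svr(np.ones((5, 4)), np.ones(5))

    def test_bpnn_topology_and_convergence_on_linear_target(self):
        # y = x1 (other features silent): the 10-21-1 net must reach
        # train MSE < 1e-2 within its epoch budget
        rng = np.random.default_rng(9)
        X = np.zeros((200, 10))
        X[:, 0] = rng.uniform(0, 1, 200)
        y = X[:, 0]
        m = fit_bpnn(X, y, BPNNSpec(seed=0, n_epochs=5000))
        assert [c.shape for c in m.coefs_] == [(10, 21), (21, 1)]
        assert np.mean((m.predict(X) - y) ** 2) < 1e-2


class TestHybrid:
    def test_constant_forest_and_inference_determinism(self):
        rng = np.random.default_rng(10)
        bb = build_backbone(seed=0)
        X = rng.normal(1.5, 0.4, (20, 10, 100))
        feats = bb.extract_features(X)
        forest = fit_rfr(feats, np.full(20, 0.25), RFRParams(seed=0))
        p1 = hybrid_predict(bb, forest, X)
        p2 = hybrid_predict(bb, forest, X)
        assert np.allclose(p1, 0.25)
        assert np.array_equal(p1, p2)

    def test_feature_width_mismatch_is_an_error(self):
        rng = np.random.default_rng(11)
        bb = build_backbone(seed=0)
        forest = fit_rfr(rng.normal(0, 1, (20, 16)), rng.uniform(0, 1, 20),
                         RFRParams(seed=0))
        with pytest.raises(ValueError, match="128"):
            hybrid_predict(bb, forest, rng.normal(1.5, 0.4, (3, 10, 100)))
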