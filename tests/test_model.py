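"""Architecture fidelity, attention semantics and trainability of the network."""

import numpy as np
import pytest

import ictalnet as ic
from ictalnet.errors import ConfigurationError
from ictalnet.model import (
    ArchitectureSpec,
    AttentionConfig,
    Network,
    ResidualBlock,
    build_network,
)
from ictalnet.nn.layers import ChannelAttention
from ictalnet.nn.losses import weighted_cross_entropy

EXPECTED_TABLE = [
    ("Input", 0), ("Conv1D", 6272), ("BatchNorm + ReLU", 256),
    ("Channel Attention", 1088), ("MaxPool1D", 0),
    ("Conv1D", 41088), ("BatchNorm + ReLU", 512), ("Channel Attention", 4224),
    ("Conv1D", 82048), ("BatchNorm", 512), ("Skip Conv1D", 8320),
    ("Add + ReLU", 0), ("MaxPool1D", 0),
    ("Conv1D", 98560), ("BatchNorm + ReLU", 1024), ("Channel Attention", 16640),
    ("Conv1D", 196864), ("BatchNorm", 1024), ("Skip Conv1D", 33024),
    ("Add + ReLU", 0), ("GlobalPool + Concat", 0),
    ("Dense", 262656), ("BatchNorm + ReLU", 2048), ("Dropout(0.5)", 0),
    ("Dense (Softmax)", 2565),
]


class TestArchitecture:
    def test_layer_table_row_for_row(self):
        rows = build_network().layer_table()
        assert [(r.name, r.params) for r in rows] == EXPECTED_TABLE

    def test_total_parameter_count(self):
        assert build_network().num_params() == 758_725

    def test_spatial_shapes(self):
        rows = build_network().layer_table()
        sizes = [r.size for r in rows]
        assert "10 x 128" in sizes and "5 x 256" in sizes and "20 x 64" in sizes

    def test_strict_mode_rejects_deviation(self):
        bad = ArchitectureSpec(stage_widths=(32, 64, 128))
        with pytest.raises(ConfigurationError):
            build_network(bad, strict=True)
        assert build_network(ArchitectureSpec(), strict=True) is not None


class TestChannelAttention:
    def test_parameter_count_64_r8(self):
        layer = ChannelAttention(64, 8)
        assert layer.param_count() == 1088
        assert ChannelAttention(128, 8).param_count() == 4224
        assert ChannelAttention(256, 8).param_count() == 16640

    def test_output_bounded_by_input(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 64))
        y = ic.channel_attention(x, AttentionConfig(64), seed=1)
        assert y.shape == x.shape
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)

    def test_zero_input_gives_zero_output(self):
        y = ic.channel_attention(np.zeros((20, 64)), AttentionConfig(64))
        np.testing.assert_array_equal(y, 0.0)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            AttentionConfig(channels=20, reduction_ratio=8)


class TestResidualBlock:
    def test_block_parameter_sum(self):
        block = ResidualBlock(64, 128, 5, 8)
        total = sum(l.param_count() for l in block.layers())
        assert total == 41088 + 512 + 4224 + 82048 + 512 + 8320  # 136,704

    def test_zeroed_weights_identity_skip_reduces_to_relu(self):
        block = ResidualBlock(64, 64, 3, 8)
        assert block.projection is None
        for layer in (block.conv1, block.conv2, block.bn1, block.bn2):
            for k in layer.params:
                layer.params[k][:] = 0.0
        x = np.random.default_rng(1).standard_normal((2, 10, 64))
        np.testing.assert_allclose(block.forward(x), np.maximum(x, 0.0))

    def test_same_padding_preserves_length(self):
        x = np.random.default_rng(2).standard_normal((13, 64))
        y = ic.residual_block(x, out_channels=128, kernel=5)
        assert y.shape == (13, 128)


class TestForward:
    def test_softmax_probabilities(self):
        net = build_network(seed=3)
        x = np.random.default_rng(0).standard_normal((20, 14))
        p = ic.forward(net, x)
        assert p.shape == (5,)
        assert np.all(p > 0) and np.all(p < 1)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_equal_logits_give_uniform_probabilities(self):
        net = build_network(seed=3)
        net.fc2.params["W"][:] = 0.0
        net.fc2.params["b"][:] = 0.0
        p = ic.forward(net, np.random.default_rng(1).standard_normal((20, 14)))
        np.testing.assert_allclose(p, 0.2, atol=1e-12)

    def test_inference_deterministic(self):
        net = build_network(seed=4)
        x = np.random.default_rng(2).standard_normal((20, 14))
        np.testing.assert_array_equal(ic.forward(net, x), ic.forward(net, x))

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            build_network().forward(np.zeros((20, 13)))


class TestAttentionMaps:
    def test_tap_shapes_and_range(self):
        net = build_network(seed=5)
        x = np.random.default_rng(3).standard_normal((20, 14))
        maps = ic.extract_attention(net, x)
        assert [m.shape[0] for m in maps] == [64, 128, 256]
        for m in maps:
            assert np.all(m > 0) and np.all(m < 1)

    def test_maps_deterministic(self):
        net = build_network(seed=5)
        x = np.random.default_rng(3).standard_normal((20, 14))
        a = ic.extract_attention(net, x)
        b = ic.extract_attention(net, x)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma, mb)


class TestTrainability:
    def test_gradient_reaches_input(self):
        net = build_network(seed=6)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 20, 14))
        logits = net.forward(x, training=True)
        _, d = weighted_cross_entropy(logits, np.array([0, 1, 2, 3]))
        dx = net.backward(d)
        assert np.abs(dx).sum() > 0

    def test_save_load_round_trip(self, tmp_path):
        net = build_network(seed=7)
        x = np.random.default_rng(4).standard_normal((20, 14))
        p0 = ic.forward(net, x)
        net.save(tmp_path / "weights.npz")
        other = build_network(seed=99)
        other.load(tmp_path / "weights.npz")
        np.testing.assert_allclose(ic.forward(other, x), p0)


class TestEstimatorProtocol:
    def test_get_set_params_round_trip(self):
        clf = ic.AttentionResidualClassifier(learning_rate=3e-4)
        params = clf.get_params()
        assert params["learning_rate"] == 3e-4
        clf2 = ic.AttentionResidualClassifier().set_params(**params)
        assert clf2.get_params() == params

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            ic.AttentionResidualClassifier().predict(np.zeros((1, 280)))

    def test_fit_predict_shapes(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((20, 280)) + 5 * k for k in range(3)])
        y = np.repeat([0, 1, 2], 20)
        clf = ic.AttentionResidualClassifier(max_epochs=3, random_state=0)
        clf.fit(X, y)
        assert clf.predict(X).shape == (60,)
        proba = clf.predict_proba(X)
        assert proba.shape == (60, 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert set(clf.classes_) == {0, 1, 2}
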