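"""Attention algebra, residual block behaviour and network contracts."""

import numpy as np
import pytest

from rmamnet.autodiff import Tensor, softmax_cross_entropy
from rmamnet.network import NetworkSpec, RMAMNet, RMAMSpec, build_network
from rmamnet.nn import RMAM, ChannelAttention, TimeAttention

BIG = 500.0  # sigmoid(±500) saturates to exactly 1/0 in float32


def force_channel_weights(att: ChannelAttention, values: np.ndarray) -> None:
    """Pin the bottleneck output so weights sigmoid-saturate to `values` (0/1)."""
    att.fc1.weight.data[:] = 0.0
    att.fc1.bias.data[:] = 0.0
    att.fc2.weight.data[:] = 0.0
    att.fc2.bias.data[:] = np.where(np.asarray(values) > 0.5, BIG, -BIG)


def force_time_identity(att: TimeAttention) -> None:
    att.squeeze.weight.data[:] = 0.0
    att.squeeze.bias.data[:] = 0.0
    att.fc1.weight.data[:] = 0.0
    att.fc1.bias.data[:] = 0.0
    att.fc2.weight.data[:] = 0.0
    att.fc2.bias.data[:] = BIG


def reweight_oracle_channels(m: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Double-loop elementwise reweighting: out[b, i, :] = m[b, i, :] * w[b, i]."""
    out = np.empty_like(m)
    for b in range(m.shape[0]):
        for i in range(m.shape[1]):
            out[b, i, :] = m[b, i, :] * w[b, i]
    return out


def reweight_oracle_time(m: np.ndarray, w: np.ndarray) -> np.ndarray:
    out = np.empty_like(m)
    for b in range(m.shape[0]):
        for j in range(m.shape[2]):
            out[b, :, j] = m[b, :, j] * w[b, j]
    return out


class TestChannelAttention:
    def test_identity_weights_preserve_input(self, rng):
        att = ChannelAttention(3, reduction=1, rng=rng)
        force_channel_weights(att, np.ones(3))
        m = Tensor(rng.normal(size=(2, 3, 4)).astype(np.float32))
        np.testing.assert_array_equal(att(m).data, m.data)

    def test_zero_weight_masks_channel(self, rng):
        att = ChannelAttention(3, reduction=1, rng=rng)
        force_channel_weights(att, np.array([1, 0, 1]))
        m = Tensor(rng.normal(size=(2, 3, 4)).astype(np.float32))
        out = att(m).data
        assert np.all(out[:, 1, :] == 0.0)
        np.testing.assert_array_equal(out[:, [0, 2], :], m.data[:, [0, 2], :])

    def test_random_weights_match_loop_oracle(self, rng):
        att = ChannelAttention(4, reduction=2, rng=rng)
        m = Tensor(rng.normal(size=(3, 4, 3)).astype(np.float32))
        w = att.weights(m).data  # (B, C, 1)
        assert np.all((w > 0) & (w < 1))
        np.testing.assert_allclose(
            att(m).data, reweight_oracle_channels(m.data, w[:, :, 0]), atol=1e-6
        )

    def test_shape_preserved_and_odd_reduction_tolerated(self, rng):
        att = ChannelAttention(5, reduction=4, rng=rng)  # 5 % 4 != 0
        m = Tensor(rng.normal(size=(2, 5, 7)).astype(np.float32))
        assert att(m).shape == (2, 5, 7)


class TestTimeAttention:
    def test_identity_weights_preserve_input(self, rng):
        att = TimeAttention(4, rng=rng)
        force_time_identity(att)
        m = Tensor(rng.normal(size=(2, 4, 6)).astype(np.float32))
        np.testing.assert_array_equal(att(m).data, m.data)

    def test_one_hot_weights_mask_time_steps(self, rng):
        att = TimeAttention(2, rng=rng)
        m = Tensor(rng.normal(size=(1, 2, 5)).astype(np.float32))
        w = np.zeros((1, 1, 5), dtype=np.float32)
        w[0, 0, 3] = 1.0
        out = (m * Tensor(w)).data  # Nt = M ⊗ q̂ with forced one-hot q̂
        assert np.all(out[:, :, [0, 1, 2, 4]] == 0.0)
        np.testing.assert_array_equal(out[:, :, 3], m.data[:, :, 3])

    def test_random_weights_match_loop_oracle(self, rng):
        att = TimeAttention(2, rng=rng)
        m = Tensor(rng.normal(size=(2, 2, 5)).astype(np.float32))
        w = att.weights(m).data  # (B, 1, L)
        assert np.all((w > 0) & (w < 1))
        np.testing.assert_allclose(
            att(m).data, reweight_oracle_time(m.data, w[:, 0, :]), atol=1e-6
        )


class TestRMAM:
    def _identity_rmam(self, channels=2):
        """Conv modules pinned to the identity, attention to all-ones."""
        rmam = RMAM(channels, channels, 1, activation="relu",
                    rng=np.random.default_rng(0))
        for conv_module in (rmam.conv_module1, rmam.conv_module2):
            conv, bn, _ = conv_module.layers
            conv.weight.data[:] = 0.0
            for c in range(channels):
                conv.weight.data[c, c, 0] = 1.0
            conv.bias.data[:] = 0.0
            bn.eval()
            bn.running_mean[:] = 0.0
            bn.running_var[:] = 1.0
        force_channel_weights(rmam.channel_att, np.ones(channels))
        force_time_identity(rmam.time_att)
        rmam.eval()
        return rmam

    def test_forced_identity_gives_2m_plus_skip(self, rng):
        # With conv modules = identity and attention weights = 1:
        # M = x, Nz = Nt = x, combined = 2x, skip = x  ->  y = 3x.
        rmam = self._identity_rmam()
        # positive entries so the ReLU in the pinned conv modules is transparent
        x = np.array([[[1.0, 2.0, 0.5], [0.25, 3.0, 1.0]]], dtype=np.float32)
        out = rmam(Tensor(x)).data
        np.testing.assert_allclose(out, 3.0 * x, atol=1e-3)

    def test_output_channels_match_spec(self, rng):
        rmam = RMAM(3, 8, 3, rng=rng)
        x = Tensor(rng.normal(size=(2, 3, 12)).astype(np.float32))
        assert rmam(x).shape == (2, 8, 12)

    def test_attention_disabled_reduces_to_two_conv_block(self, rng):
        plain = RMAM(3, 5, 3, use_channel_att=False, use_time_att=False,
                     use_skip=False, rng=np.random.default_rng(1))
        full = RMAM(3, 5, 3, rng=np.random.default_rng(1))
        # parameter count shrinks to exactly the two conv modules
        n_plain = sum(p.data.size for p in plain.parameters())
        n_convs = sum(
            p.data.size for m in (full.conv_module1, full.conv_module2)
            for p in m.parameters()
        )
        assert n_plain == n_convs
        # and the output equals running the conv modules alone
        plain.eval()
        x = Tensor(np.random.default_rng(2).normal(size=(2, 3, 9)).astype(np.float32))
        expected = plain.conv_module2(plain.conv_module1(x)).data
        np.testing.assert_allclose(plain(x).data, expected, atol=1e-7)

    def test_gradient_reaches_every_parameter(self, rng):
        rmam = RMAM(3, 4, 3, rng=rng)
        x = Tensor(rng.normal(size=(4, 3, 10)).astype(np.float32))
        pooled = rmam(x).mean(axis=2)
        loss, _ = softmax_cross_entropy(pooled, np.array([0, 1, 2, 3]))
        loss.backward()
        for name, p in rmam.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name


TINY_SPEC = NetworkSpec(
    in_channels=6,
    blocks=(RMAMSpec(3, 8, 2), RMAMSpec(3, 8, 2)),
    final_conv_channels=8,
    n_classes=4,
)


class TestNetwork:
    def test_default_architecture_contract(self, rng):
        net = build_network(rng=rng)
        net.eval()
        x = Tensor(rng.normal(size=(2, 80, 301)).astype(np.float32))
        feats = net.features(x)
        assert feats.shape == (2, 256)
        probs = net.predict_proba(x)
        assert probs.shape == (2, 4)
        assert np.all((probs > 0) & (probs < 1))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_channel_progression(self, rng):
        net = build_network(rng=rng)
        widths = [net.backbone.layers[0].conv_module1.layers[0].in_channels]
        for layer in net.backbone.layers:
            if isinstance(layer, RMAM):
                widths.append(layer.conv_module2.layers[0].out_channels)
        assert widths == [80, 128, 256, 256, 256]

    def test_eval_forward_is_deterministic(self, rng):
        net = RMAMNet(TINY_SPEC, rng=rng)
        net.eval()
        x = Tensor(rng.normal(size=(3, 6, 40)).astype(np.float32))
        np.testing.assert_array_equal(net.predict_proba(x), net.predict_proba(x))

    def test_softmax_normalisation_many_random_inputs(self, rng):
        net = RMAMNet(TINY_SPEC, rng=rng)
        net.eval()
        x = Tensor(rng.normal(size=(1000, 6, 40)).astype(np.float32))
        probs = net.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), np.ones(1000), atol=1e-6)
        assert np.all((probs > 0) & (probs < 1))

    def test_wrong_channel_count_rejected(self, rng):
        net = RMAMNet(TINY_SPEC, rng=rng)
        with pytest.raises(ValueError, match="expected input"):
            net.features(Tensor(rng.normal(size=(1, 5, 40)).astype(np.float32)))

    def test_summary_lists_all_layers(self, rng):
        table = build_network(rng=rng).summary()
        assert "Global Average Pooling" in table and "256" in table
        assert table.count("RMAM") == 4

    def test_spec_roundtrip_through_dict(self):
        spec = NetworkSpec()
        assert NetworkSpec.from_dict(spec.to_dict()) == spec
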