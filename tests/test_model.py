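"""Architecture contracts: shapes, parameter counts, causality, attention,
and checkpoint round trips (probed on reduced/tiny configurations)."""

import numpy as np
import pytest

from insightsleep.model import (
    InsightSleepNet,
    ModelConfig,
    build_model,
    count_trainable_parameters,
    load_checkpoint,
    save_checkpoint,
)
from insightsleep.preprocess import EpochizedInput


@pytest.fixture(scope="module")
def small_net():
    cfg = ModelConfig.reduced(n_epochs=40, seed=2)
    return cfg, InsightSleepNet(cfg)


def _epochized(cfg, rng, n_valid=None):
    n_valid = cfg.n_epochs if n_valid is None else n_valid
    values = np.zeros((cfg.n_epochs, cfg.epoch_len))
    values[:n_valid] = rng.random((n_valid, cfg.epoch_len))
    mask = np.arange(cfg.n_epochs) < n_valid
    return EpochizedInput(values, mask)


class TestConfig:
    def test_attention_kernel_spans_seven_epochs(self):
        assert ModelConfig().attention_kernel == 7168
        assert ModelConfig(epoch_len=64).attention_kernel == 448

    def test_inception_channel_bookkeeping(self):
        cfg = ModelConfig()
        assert cfg.inception_in_channels == (32, 32, 64, 64, 128, 256)
        # each block emits 4 x branch filters, feeding the next block
        assert tuple(4 * f for f in cfg.inception_filters) == (32, 64, 64, 128, 256, 512)

    def test_dilations_double_from_one(self):
        assert ModelConfig().tcn_dilations == (1, 2, 4, 8, 16)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_epochs=7).validate()  # 7*1024 not divisible by 20

    def test_json_round_trip(self):
        cfg = ModelConfig.reduced(n_epochs=120, seed=9)
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestParameterCount:
    def test_single_dense_layer_arithmetic(self):
        from insightsleep.nn import Conv1d

        layer = Conv1d(4, 4, 1)
        assert layer.weight.size + layer.bias.size == 20

    def test_count_is_pure_function_of_config(self):
        a = count_trainable_parameters(build_model(ModelConfig(seed=0)))
        b = count_trainable_parameters(build_model(ModelConfig(seed=123)))
        assert a == b

    def test_module_additivity(self, small_net):
        _, net = small_net
        total = count_trainable_parameters(net)
        attn = sum(p.size for _, p in net.attention.named_parameters())
        rest = sum(
            p.size for name, p in net.named_parameters() if not name.startswith("attention")
        )
        assert attn + rest == total


class TestForward:
    def test_output_shape_and_probabilities(self, small_net):
        cfg, net = small_net
        rng = np.random.default_rng(0)
        grid = net.forward(_epochized(cfg, rng))
        assert grid.values.shape == (cfg.n_epochs, 4)
        assert np.isfinite(grid.values).all()
        np.testing.assert_allclose(grid.probabilities.sum(axis=1), 1.0, atol=1e-6)

    def test_two_class_override_changes_head(self):
        cfg = ModelConfig.reduced(n_epochs=40).with_overrides(n_classes=2)
        net = InsightSleepNet(cfg)
        grid = net.forward(_epochized(cfg, np.random.default_rng(1)))
        assert grid.values.shape == (40, 2)

    def test_all_zero_input_is_finite(self, small_net):
        cfg, net = small_net
        values = np.zeros((cfg.n_epochs, cfg.epoch_len))
        logits = net.forward_values(values)
        assert np.isfinite(logits).all()

    def test_eval_mode_is_deterministic(self, small_net):
        cfg, net = small_net
        x = np.random.default_rng(3).random((cfg.n_epochs, cfg.epoch_len))
        np.testing.assert_array_equal(net.forward_values(x), net.forward_values(x))

    def test_padded_epochs_still_produce_logits(self, small_net):
        cfg, net = small_net
        grid = net.forward(_epochized(cfg, np.random.default_rng(4), n_valid=25))
        assert np.isfinite(grid.values).all()


class TestAttentionCausality:
    def test_scores_in_sigmoid_range(self, small_net):
        cfg, net = small_net
        x = np.random.default_rng(5).random((cfg.n_epochs, cfg.epoch_len))
        net.forward_values(x)
        a = net.attention.last_attention
        assert a.size == cfg.n_epochs * cfg.epoch_len
        assert (a > 0).all() and (a < 1).all()

    def test_future_epoch_perturbation_leaves_past_attention(self, small_net):
        cfg, net = small_net
        rng = np.random.default_rng(6)
        x = rng.random((cfg.n_epochs, cfg.epoch_len))
        net.forward_values(x)
        a1 = net.attention.last_attention.copy()
        e = 20
        x2 = x.copy()
        x2[e + 2 :] = rng.random(x2[e + 2 :].shape)
        net.forward_values(x2)
        a2 = net.attention.last_attention
        upto = (e + 1) * cfg.epoch_len
        np.testing.assert_allclose(a1[:upto], a2[:upto], atol=1e-6)

    def test_receptive_field_is_seven_epochs(self, small_net):
        cfg, net = small_net
        rng = np.random.default_rng(7)
        x = rng.random((cfg.n_epochs, cfg.epoch_len))
        net.forward_values(x)
        a1 = net.attention.last_attention.copy()
        e = 20
        x2 = x.copy()
        x2[e - 8] = rng.random(cfg.epoch_len)  # 8 epochs in the past
        net.forward_values(x2)
        a2 = net.attention.last_attention
        sl = slice(e * cfg.epoch_len, (e + 1) * cfg.epoch_len)
        np.testing.assert_allclose(a1[sl], a2[sl], atol=1e-6)
        # 6 epochs back is inside the kernel: must change
        x3 = x.copy()
        x3[e - 6] = rng.random(cfg.epoch_len)
        net.forward_values(x3)
        a3 = net.attention.last_attention
        assert np.abs(a1[sl] - a3[sl]).max() > 1e-9


class TestTemporalCausality:
    def test_epoch_level_strict_causality(self, small_net):
        cfg, net = small_net
        rng = np.random.default_rng(8)
        feats = rng.standard_normal((cfg.tdd_width, cfg.n_epochs)).astype(np.float32)

        def run(f):
            x = f
            for t in net.tcn:
                x = t.forward(x)
            return x

        y1 = run(feats)
        e = 15
        feats2 = feats.copy()
        feats2[:, e + 1] += 5.0
        y2 = run(feats2)
        np.testing.assert_allclose(y1[:, : e + 1], y2[:, : e + 1], atol=1e-6)

    def test_stack_receptive_field_arithmetic(self):
        cfg = ModelConfig()
        rf = 1 + (cfg.tcn_kernel - 1) * 2 * sum(cfg.tcn_dilations)
        assert rf == 435


class TestAttentionExtraction:
    def test_normalized_view_and_per_epoch_length(self, small_net):
        cfg, net = small_net
        ep = _epochized(cfg, np.random.default_rng(9), n_valid=30)
        att = net.extract_attention(ep)
        assert att.per_epoch.shape == (cfg.n_epochs,)
        valid = att.normalized.reshape(cfg.n_epochs, -1)[ep.epoch_mask]
        assert valid.min() == pytest.approx(0.0, abs=1e-12)
        assert valid.max() == pytest.approx(1.0, abs=1e-12)

    def test_peak_vs_trough_attention_is_reported(self, synth_study):
        """The attention at pulse peaks differs from troughs on synthetic
        input (direction not asserted; the association is qualitative)."""
        cfg = ModelConfig.reduced(n_epochs=240, seed=0)
        net = InsightSleepNet(cfg)
        (epochized, _), meta = synth_study["dataset"][0], synth_study["metas"][0]
        att = net.extract_attention(epochized)
        fs_ratio = 1024 / (30 * 128)
        peaks = (meta["peak_indices"] * fs_ratio).astype(int)
        peaks = peaks[peaks < att.per_sample.size]
        trough = (peaks[:-1] + peaks[1:]) // 2
        diff = att.per_sample[peaks[:-1]].mean() - att.per_sample[trough].mean()
        assert np.isfinite(diff)


class TestSerialization:
    def test_checkpoint_round_trip_reproduces_logits(self, tmp_path, small_net):
        cfg, net = small_net
        x = np.random.default_rng(10).random((cfg.n_epochs, cfg.epoch_len))
        ref = net.forward_values(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net)
        net2 = load_checkpoint(path)
        np.testing.assert_array_equal(net2.forward_values(x), ref)

    def test_mismatched_state_rejected(self, small_net):
        _, net = small_net
        other = InsightSleepNet(ModelConfig.reduced(n_epochs=40).with_overrides(tdd_width=8))
        with pytest.raises(ValueError):
            net.load_state_dict(other.state_dict())
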