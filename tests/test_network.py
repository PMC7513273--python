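"""Architecture contracts: temporal fusion, bottleneck blocks, degeneracy."""

import numpy as np
import pytest

from angioseg.network import (DACBlock, NetworkConfig, RMPBlock, STNet,
                              TemporalKernel, build_network,
                              degenerate_to_2d, embed_2d_network,
                              load_checkpoint, predict_proba,
                              save_checkpoint, temporal_fuse)
from angioseg.nn import tensor as T
from angioseg.nn.tensor import Tensor

RNG = np.random.default_rng(99)


def brute_force_fuse(window, kernel):
    """Triple-nested-loop evaluation of the temporal fusion sum."""
    depth, h, w = window.shape
    n = depth // 2
    out_ch = kernel.weights.shape[0]
    padded = np.pad(window.astype(np.float64), ((0, 0), (1, 1), (1, 1)))
    out = np.zeros((out_ch, h, w))
    for o in range(out_ch):
        for x in range(h):
            for y in range(w):
                acc = 0.0
                for t in range(-n, n + 1):
                    for dx in range(-1, 2):
                        for dy in range(-1, 2):
                            acc += (kernel.weights[o, 0, t + n, dx + 1, dy + 1]
                                    * padded[t + n, x + dx + 1, y + dy + 1])
                out[o, x, y] = acc + kernel.bias[o]
    return out


class TestTemporalFuse:
    def test_matches_brute_force_oracle(self):
        win = RNG.standard_normal((5, 12, 12)).astype(np.float32)
        kernel = TemporalKernel(
            RNG.standard_normal((4, 1, 5, 3, 3)).astype(np.float32),
            RNG.standard_normal(4).astype(np.float32))
        got = temporal_fuse(win, kernel)
        want = brute_force_fuse(win, kernel)
        assert np.abs(got - want).max() < 1e-5

    def test_zero_window_zero_bias_gives_zero(self):
        kernel = TemporalKernel(
            RNG.standard_normal((16, 1, 3, 3, 3)).astype(np.float32),
            np.zeros(16, np.float32))
        out = temporal_fuse(np.zeros((3, 8, 8), np.float32), kernel)
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_kernel_reproduces_central_frame(self):
        w = np.zeros((2, 1, 5, 3, 3), np.float32)
        w[0, 0, 2, 1, 1] = 1.0          # centre of time, centre of space
        kernel = TemporalKernel(w, np.zeros(2, np.float32))
        win = RNG.standard_normal((5, 10, 10)).astype(np.float32)
        out = temporal_fuse(win, kernel)
        np.testing.assert_allclose(out[0], win[2], atol=1e-6)
        np.testing.assert_array_equal(out[1], 0.0)

    def test_depth_mismatch_reports_both_depths(self):
        kernel = TemporalKernel(np.zeros((1, 1, 5, 3, 3), np.float32),
                                np.zeros(1, np.float32))
        with pytest.raises(ValueError, match="3.*5|5.*3"):
            temporal_fuse(np.zeros((3, 8, 8), np.float32), kernel)

    def test_translation_covariance_in_interior(self):
        kernel = TemporalKernel(
            RNG.standard_normal((3, 1, 3, 3, 3)).astype(np.float32),
            RNG.standard_normal(3).astype(np.float32))
        win = RNG.standard_normal((3, 16, 16)).astype(np.float32)
        shifted = np.roll(win, shift=(2, 3), axis=(1, 2))
        a = temporal_fuse(win, kernel)
        b = temporal_fuse(shifted, kernel)
        rolled = np.roll(a, shift=(2, 3), axis=(1, 2))
        np.testing.assert_allclose(b[:, 4:-4, 4:-4], rolled[:, 4:-4, 4:-4],
                                   atol=1e-5)

    def test_kernel_validation(self):
        with pytest.raises(ValueError, match="odd"):
            TemporalKernel(np.zeros((1, 1, 4, 3, 3)), np.zeros(1))
        with pytest.raises(ValueError, match="3x3"):
            TemporalKernel(np.zeros((1, 1, 3, 5, 5)), np.zeros(1))


class TestConfig:
    def test_input_size_must_be_divisible_by_32(self):
        with pytest.raises(ValueError, match="32"):
            NetworkConfig(n=1, input_size=100)

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            NetworkConfig(n=-1)

    def test_paper_scale_depths(self):
        assert NetworkConfig(n=2).depth == 5
        assert NetworkConfig(n=1).depth == 3
        assert NetworkConfig(n=1).encoder_channels == (64, 128, 256, 512)


class TestForwardContracts:
    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_probability_map_shape_and_range(self, n):
        cfg = NetworkConfig(n=n, input_size=64, width_multiplier=0.25)
        net = build_network(cfg, seed=0)
        x = RNG.standard_normal((1, 2 * n + 1, 64, 64)).astype(np.float32)
        with T.no_grad():
            y = net(x)
        assert y.data.shape == (1, 1, 64, 64)
        assert y.data.min() >= 0.0 and y.data.max() <= 1.0

    def test_larger_input_size(self):
        cfg = NetworkConfig(n=1, input_size=96, width_multiplier=0.25)
        net = build_network(cfg, seed=1)
        with T.no_grad():
            y = net(np.zeros((1, 3, 96, 96), np.float32))
        assert y.data.shape == (1, 1, 96, 96)

    def test_depth_mismatch_raises(self, tiny_net):
        with pytest.raises(ValueError, match="depth"):
            tiny_net(np.zeros((1, 5, 64, 64), np.float32))


class TestBottleneck:
    def test_dac_preserves_shape(self):
        blk = DACBlock(8, rng=np.random.default_rng(0))
        x = Tensor(RNG.standard_normal((2, 8, 12, 12)))
        assert blk(x).data.shape == (2, 8, 12, 12)

    def test_dac_zero_input_zero_biases_gives_zero(self):
        blk = DACBlock(4, rng=np.random.default_rng(0))
        out = blk(Tensor(np.zeros((1, 4, 10, 10), np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_dac_receptive_field_exceeds_radius_three(self):
        """Dilated cascade must propagate an impulse beyond radius 3."""
        blk = DACBlock(1, rng=np.random.default_rng(3))
        for conv in (blk.dilate1, blk.dilate3, blk.dilate5, blk.conv1x1):
            conv.weight.data = np.abs(conv.weight.data) + 0.1
            conv.bias.data[:] = 0.0
        x = np.zeros((1, 1, 21, 21), np.float32)
        x[0, 0, 10, 10] = 1.0
        out = blk(Tensor(x)).data[0, 0] - x[0, 0]
        assert out[10, 14] != 0.0 or out[14, 10] != 0.0

    def test_rmp_adds_four_channels_and_preserves_dims(self):
        blk = RMPBlock(6, rng=np.random.default_rng(0))
        x = Tensor(RNG.standard_normal((2, 6, 12, 12)))
        assert blk(x).data.shape == (2, 10, 12, 12)

    def test_rmp_constant_input_constant_pooled_branches(self):
        blk = RMPBlock(3, rng=np.random.default_rng(1))
        out = blk(Tensor(np.full((1, 3, 12, 12), 0.7, np.float32)))
        for ch in range(3, 7):
            vals = out.data[0, ch]
            np.testing.assert_allclose(vals, vals.flat[0], atol=1e-6)

    def test_rmp_small_bottleneck_clamps_pool_kernels(self):
        blk = RMPBlock(3, rng=np.random.default_rng(2))
        out = blk(Tensor(RNG.standard_normal((1, 3, 4, 4))))
        assert out.data.shape == (1, 7, 4, 4)


class TestDegeneracy:
    def test_embedded_2d_network_agrees_with_2d(self):
        cfg2 = NetworkConfig(n=0, input_size=64, width_multiplier=0.25)
        net2 = build_network(cfg2, seed=7)
        net3 = embed_2d_network(net2, n=1)
        wins = [RNG.standard_normal((3, 64, 64)).astype(np.float32)
                for _ in range(3)]
        assert degenerate_to_2d(net3, net2, wins) < 1e-5

    def test_nonzero_off_centre_slices_break_equality(self):
        cfg2 = NetworkConfig(n=0, input_size=64, width_multiplier=0.25)
        net2 = build_network(cfg2, seed=8)
        net3 = embed_2d_network(net2, n=1)
        net3.temporal.weight.data[:, 0] += 0.05    # perturb the past slice
        wins = [RNG.standard_normal((3, 64, 64)).astype(np.float32)]
        assert degenerate_to_2d(net3, net2, wins) > 1e-5

    def test_weight_shape_mismatch_detected(self):
        net2 = build_network(NetworkConfig(n=0, input_size=64,
                                           width_multiplier=0.25), seed=0)
        other = build_network(NetworkConfig(n=1, input_size=64,
                                            width_multiplier=0.5), seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            degenerate_to_2d(other, net2, [np.zeros((3, 64, 64), np.float32)])


class TestCheckpoints:
    def test_roundtrip_preserves_function(self, tmp_path, tiny_net):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_net, path)
        loaded = load_checkpoint(path)
        assert loaded.config == tiny_net.config
        x = RNG.standard_normal((2, 3, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(predict_proba(loaded, x),
                                      predict_proba(tiny_net, x))

    def test_missing_sidecar_raises(self, tmp_path, tiny_net):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_net, path)
        (tmp_path / "model.json").unlink()
        with pytest.raises(FileNotFoundError, match="sidecar"):
            load_checkpoint(path)
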