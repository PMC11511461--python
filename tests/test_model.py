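import math

import numpy as np
import pytest

from pupilgaze.config import NetConfig
from pupilgaze.segnet import autodiff as ad
from pupilgaze.segnet.autodiff import Tensor
from pupilgaze.segnet.model import (
    PupilSegNet,
    forward,
    gate,
    load_checkpoint,
    save_checkpoint,
)
from pupilgaze.synthdata import generate_eye_frame


def _set_closure_output(net: PupilSegNet, p_close: float) -> None:
    """Pin the eye-closure head to a constant probability."""
    net.closure.weight.data[...] = 0.0
    net.closure.bias.data[...] = math.log(p_close / (1.0 - p_close))


@pytest.fixture(scope="module")
def net():
    return PupilSegNet(NetConfig(), seed=0)


@pytest.fixture(scope="module")
def frame(clean_cfg=None):
    from pupilgaze.config import SynthEyeConfig

    cfg = SynthEyeConfig(noise_sigma=0.0, glint_count_range=(0, 0),
                         illumination_gradient_range=(0.0, 0.0))
    return generate_eye_frame(cfg, seed=1)


class TestArchitecture:
    def test_bottleneck_is_one_sixteenth_resolution(self, net, frame):
        x = Tensor(frame.pixels[None, None].astype(np.float32))
        with ad.no_grad():
            bottleneck, skips = net.encode(x, training=False)
        assert bottleneck.shape[2:] == (4, 4)  # 64 / 16
        assert [s.shape[2] for s in skips] == [64, 32, 16, 8]

    def test_prob_map_matches_input_shape(self, net, frame):
        out = forward(frame, net)
        assert out.prob_map.shape == frame.pixels.shape
        assert out.prob_map.min() >= 0.0 and out.prob_map.max() <= 1.0

    @pytest.mark.parametrize("size", [(32, 32), (64, 32), (96, 64)])
    def test_shape_conservation_across_sizes(self, net, size):
        pixels = np.random.default_rng(0).uniform(0, 1, size=size)
        out = forward(pixels, net)
        assert out.prob_map.shape == size

    def test_indivisible_input_rejected_naming_factor(self, net):
        with pytest.raises(ValueError, match="16"):
            forward(np.zeros((60, 64)), net)

    def test_footprint_within_1_2_mb(self, net):
        assert net.footprint_bytes(4) <= 1.2 * 1e6


class TestGating:
    def test_high_p_close_skips_decoder(self, frame):
        net = PupilSegNet(NetConfig(), seed=0)
        _set_closure_output(net, 0.999)
        out = forward(frame, net)
        assert out.gate == 0
        assert out.decoder_ran is False
        assert not out.prob_map.any()

    def test_low_p_close_runs_decoder(self, frame):
        net = PupilSegNet(NetConfig(), seed=0)
        _set_closure_output(net, 0.01)
        out = forward(frame, net)
        assert out.gate == 1 and out.decoder_ran is True

    @pytest.mark.parametrize("p", [0.05, 0.5, 0.95, 0.99, 0.999])
    def test_forward_gate_consistent_with_heaviside(self, frame, p):
        net = PupilSegNet(NetConfig(), seed=0)
        _set_closure_output(net, p)
        out = forward(frame, net)
        assert out.gate == gate(out.p_close, net.config.epsilon)
        assert out.decoder_ran == bool(out.gate)


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, frame):
        net = PupilSegNet(NetConfig(), seed=3)
        ckpt = tmp_path / "model.npz"
        save_checkpoint(net, ckpt)
        restored = load_checkpoint(ckpt)
        a = forward(frame, net)
        b = forward(frame, restored)
        np.testing.assert_array_equal(a.prob_map, b.prob_map)
        assert a.p_close == b.p_close

    def test_sidecar_restores_config(self, tmp_path):
        cfg = NetConfig(base_channels=4, epsilon=0.05)
        net = PupilSegNet(cfg, seed=0)
        save_checkpoint(net, tmp_path / "m.npz")
        restored = load_checkpoint(tmp_path / "m.npz")
        assert restored.config.base_channels == 4
        assert restored.config.epsilon == 0.05


class TestAutodiffGradients:
    """Finite-difference checks of the custom backward passes."""

    def _fd_check(self, op, x0, rel=2e-2, n_probe=4):
        rng = np.random.default_rng(0)
        w = rng.normal(size=op(Tensor(x0)).shape)

        xt = Tensor(x0, requires_grad=True)
        out = op(xt)
        loss = ad.tsum(ad.mul(out, Tensor(w)))
        loss.backward()
        eps = 1e-3
        flat_idx = rng.choice(x0.size, size=n_probe, replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, x0.shape)
            xp, xm = x0.copy(), x0.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (
                float((op(Tensor(xp)).data * w).sum())
                - float((op(Tensor(xm)).data * w).sum())
            ) / (2 * eps)
            assert xt.grad[idx] == pytest.approx(num, rel=rel, abs=1e-2)

    def test_conv2d_gradient(self, rng):
        w = Tensor(rng.normal(size=(3, 2, 3, 3)).astype(np.float32), requires_grad=True)
        b = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)
        x0 = rng.normal(size=(2, 2, 5, 5)).astype(np.float32)
        self._fd_check(lambda t: ad.conv2d(t, w, b), x0)

    def test_avg_pool_gradient(self, rng):
        x0 = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        self._fd_check(ad.avg_pool2, x0)

    def test_softmax_channels_gradient(self, rng):
        x0 = rng.normal(size=(1, 5, 3, 3)).astype(np.float32)
        self._fd_check(ad.softmax_channels, x0)

    def test_pixel_shuffle_gradient(self, rng):
        x0 = rng.normal(size=(1, 8, 3, 3)).astype(np.float32)
        self._fd_check(lambda t: ad.pixel_shuffle(t, 2), x0)

    def test_batch_norm_gradient(self, rng):
        gamma = Tensor(np.ones(3, dtype=np.float32), requires_grad=True)
        beta = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)
        x0 = rng.normal(size=(4, 3, 4, 4)).astype(np.float32)

        def op(t):
            rm = np.zeros(3, dtype=np.float32)
            rv = np.ones(3, dtype=np.float32)
            return ad.batch_norm2d(t, gamma, beta, rm, rv, training=True)

        self._fd_check(op, x0, rel=5e-2)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        NetConfig(carafe_kernel=4).validate()
    with pytest.raises(ValueError):
        NetConfig(carafe_ratio=3).validate()
    with pytest.raises(ValueError):
        NetConfig(epsilon=0.0).validate()
    with pytest.raises(ValueError):
        NetConfig(loss_weights=(0.0, 0.0)).validate()
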