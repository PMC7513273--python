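"""The 3D-2D segmentation network.

Architecture
------------
A window of ``2N+1`` consecutive grayscale frames enters a *temporal-fusion*
3D convolution: kernel ``(2N+1) x 3 x 3``, spatial padding 1, no padding along
the temporal axis, stride 1 everywhere, so the temporal depth collapses to 1
and the layer emits 16 channels of 2D feature maps at full resolution,

    g(x, y) = sum_{t=-N..N} sum_{w=-1..1} sum_{h=-1..1}
              w(t, w, h) * f(i + t, x + w, y + h)

per output channel (``f`` the frame stack, ``i`` the central/target frame).
Because the single-channel frame stack enters with its temporal axis as depth
and no z-padding, the layer is computed as a 2D convolution whose input
channels are the 2N+1 temporal slices — mathematically identical, and it is
what makes the N=0 configuration *exactly* a 2D network.

The fused maps pass through a 2D 3x3 convolution (to the first encoder width)
and a 2x2 max-pool, then a CE-Net-style body: four residual encoder stages
(ResNet-34 block counts 3,4,6,3), a dense-atrous-convolution (DAC) cascade and
residual multi-kernel pooling (RMP) bottleneck, four decoder stages with
additive skip connections, and a sigmoid head that restores full resolution.
Instance normalization is used throughout.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

FUSION_CHANNELS = 16
_ENCODER_WIDTHS = (64, 128, 256, 512)
_ENCODER_BLOCKS = (3, 4, 6, 3)
_RMP_KERNELS = (2, 3, 5, 6)


@dataclasses.dataclass
class NetworkConfig:
    """Hyperparameters fixing the network graph.

    ``n`` is the temporal context radius (window depth ``2n+1``; 0 gives the
    purely 2D baseline).  ``width_multiplier`` scales every encoder/decoder
    width (1.0 = full scale; fractions give desk-scale models).
    ``pretrained_weights`` may point to an ``.npz`` of convolutional encoder
    weights to load after construction (optional; normalization statistics are
    not transferable across norm flavours, so only conv kernels are taken).
    """

    n: int = 2
    input_size: int = 448
    fusion_channels: int = FUSION_CHANNELS
    width_multiplier: float = 1.0
    pretrained_weights: Optional[str] = None
    normalization: str = "instance"

    def __post_init__(self):
        if self.n < 0:
            raise ValueError(f"temporal radius n must be >= 0, got {self.n}")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be > 0")
        if self.input_size % 32 != 0:
            raise ValueError(
                f"input_size must be divisible by 32, got {self.input_size}")
        if self.normalization != "instance":
            raise ValueError("only instance normalization is supported")

    @property
    def depth(self) -> int:
        return 2 * self.n + 1

    @property
    def encoder_channels(self) -> Tuple[int, ...]:
        return tuple(max(4, int(round(c * self.width_multiplier)))
                     for c in _ENCODER_WIDTHS)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclasses.dataclass
class TemporalKernel:
    """Weights of the temporal-fusion 3D input layer.

    ``weights`` has shape ``(out_channels, 1, 2N+1, 3, 3)``; ``bias`` one
    scalar per output channel.
    """

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float32)
        self.bias = np.asarray(self.bias, dtype=np.float32)
        if self.weights.ndim != 5 or self.weights.shape[1] != 1:
            raise ValueError(
                f"expected (out, 1, depth, 3, 3) weights, got {self.weights.shape}")
        if self.weights.shape[3:] != (3, 3):
            raise ValueError(
                f"spatial extent must be 3x3, got {self.weights.shape[3:]}")
        if self.weights.shape[2] % 2 == 0:
            raise ValueError(
                f"temporal depth must be odd, got {self.weights.shape[2]}")
        if self.bias.shape != (self.weights.shape[0],):
            raise ValueError("bias must have one entry per output channel")

    @property
    def depth(self) -> int:
        return self.weights.shape[2]


def temporal_fuse(window: np.ndarray, kernel: TemporalKernel) -> np.ndarray:
    """Apply the temporal-fusion 3D convolution to one frame window.

    ``window`` is a ``(2N+1, H, W)`` stack; returns ``(out_channels, H, W)``.
    Spatial padding 1 with zeros, no temporal padding: the depth axis
    collapses to 1 while H and W are preserved.
    """
    window = np.asarray(window, dtype=np.float32)
    if window.ndim != 3:
        raise ValueError(f"window must be (depth, H, W), got {window.shape}")
    if window.shape[0] != kernel.depth:
        raise ValueError(
            f"depth mismatch: window has {window.shape[0]} frames, "
            f"kernel depth is {kernel.depth}")
    w2d = Tensor(kernel.weights[:, 0])          # (out, depth, 3, 3)
    x = Tensor(window[None])                    # (1, depth, H, W)
    with T.no_grad():
        y = T.conv2d(x, w2d, Tensor(kernel.bias), stride=1, padding=1)
    return y.data[0]


class DACBlock(nn.Module):
    """Dense atrous convolution cascade (dilations 1, 3, 5, then 1x1).

    Each stage of the cascade is ReLU-activated and added residually to the
    input, growing the receptive field without changing resolution.
    """

    def __init__(self, channels: int, rng=None):
        self.dilate1 = nn.Conv2d(channels, channels, 3, padding=1, dilation=1,
                                 rng=rng)
        self.dilate3 = nn.Conv2d(channels, channels, 3, padding=3, dilation=3,
                                 rng=rng)
        self.dilate5 = nn.Conv2d(channels, channels, 3, padding=5, dilation=5,
                                 rng=rng)
        self.conv1x1 = nn.Conv2d(channels, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        c1 = T.relu(self.dilate1(x))
        c2 = T.relu(self.dilate3(c1))
        c3 = T.relu(self.dilate5(c2))
        c4 = T.relu(self.conv1x1(c3))
        out = T.add(x, c1)
        out = T.add(out, c2)
        out = T.add(out, c3)
        return T.add(out, c4)


class RMPBlock(nn.Module):
    """Residual multi-kernel pooling: multi-scale max-pooled context.

    Pools at kernel sizes 2, 3, 5 and 6 (each clamped to the feature map's
    spatial size so small bottlenecks remain valid), projects each pooled map
    to a single channel, upsamples back, and concatenates the four context
    maps onto the input (channels + 4).
    """

    def __init__(self, channels: int, rng=None):
        self.projections = [nn.Conv2d(channels, 1, 1, rng=rng)
                            for _ in _RMP_KERNELS]

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        branches = [x]
        for k, proj in zip(_RMP_KERNELS, self.projections):
            ke = min(k, h, w)
            pooled = T.maxpool2d(x, ke)
            branches.append(T.upsample_nearest(proj(pooled), (h, w)))
        return T.concat(branches, axis=1)


class DecoderBlock(nn.Module):
    """1x1 reduce -> 3x3 stride-2 transposed conv (x2 upsample) -> 1x1 expand."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        mid = max(1, in_ch // 4)
        self.reduce = nn.ConvINReLU(in_ch, mid, 1, rng=rng)
        self.up = nn.ConvTranspose2d(mid, mid, 3, stride=2, padding=1,
                                     output_padding=1, rng=rng)
        self.up_norm = nn.InstanceNorm2d(mid)
        self.expand = nn.ConvINReLU(mid, out_ch, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.reduce(x)
        y = T.relu(self.up_norm(self.up(y)))
        return self.expand(y)


class STNet(nn.Module):
    """The 3D-2D network (temporal fusion + CE-Net-style 2D body)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = config.encoder_channels
        fc = config.fusion_channels
        self.temporal = nn.Conv2d(config.depth, fc, 3, padding=1, rng=rng)
        self.fuse = nn.ConvINReLU(fc, c1, 3, padding=1, rng=rng)
        self.enc1 = self._stage(c1, c1, _ENCODER_BLOCKS[0], 1, rng)
        self.enc2 = self._stage(c1, c2, _ENCODER_BLOCKS[1], 2, rng)
        self.enc3 = self._stage(c2, c3, _ENCODER_BLOCKS[2], 2, rng)
        self.enc4 = self._stage(c3, c4, _ENCODER_BLOCKS[3], 2, rng)
        self.dac = DACBlock(c4, rng=rng)
        self.rmp = RMPBlock(c4, rng=rng)
        self.dec4 = DecoderBlock(c4 + len(_RMP_KERNELS), c3, rng=rng)
        self.dec3 = DecoderBlock(c3, c2, rng=rng)
        self.dec2 = DecoderBlock(c2, c1, rng=rng)
        self.dec1 = DecoderBlock(c1, c1, rng=rng)
        self.head = nn.ConvINReLU(c1, c1, 3, padding=1, rng=rng)
        self.classify = nn.Conv2d(c1, 1, 1, rng=rng)
        if config.pretrained_weights:
            self._load_pretrained(config.pretrained_weights)

    @staticmethod
    def _stage(in_ch, out_ch, blocks, stride, rng):
        layers = [nn.ResidualBlock(in_ch, out_ch, stride, rng=rng)]
        layers.extend(nn.ResidualBlock(out_ch, out_ch, rng=rng)
                      for _ in range(blocks - 1))
        return layers

    def _load_pretrained(self, path: str) -> None:
        """Load matching convolution kernels from an .npz (encoder only)."""
        arrs = np.load(path)
        own = dict(self.named_parameters())
        for key in arrs.files:
            if key in own and own[key].data.shape == arrs[key].shape:
                own[key].data = arrs[key].astype(np.float32)

    @staticmethod
    def _run_stage(stage, x):
        for block in stage:
            x = block(x)
        return x

    def forward(self, x: Union[np.ndarray, Tensor]) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4:
            raise ValueError(f"expected (batch, depth, H, W), got {x.shape}")
        if x.shape[1] != self.config.depth:
            raise ValueError(
                f"depth mismatch: input has {x.shape[1]} frames, "
                f"network expects {self.config.depth}")
        t = self.temporal(x)                      # (B, 16, S, S)
        f = self.fuse(t)                          # (B, c1, S, S)
        p = T.maxpool2d(f, 2)                     # S/2
        e1 = self._run_stage(self.enc1, p)        # S/2
        e2 = self._run_stage(self.enc2, e1)       # S/4
        e3 = self._run_stage(self.enc3, e2)       # S/8
        e4 = self._run_stage(self.enc4, e3)       # S/16
        b = self.rmp(self.dac(e4))
        d4 = T.add(self.dec4(b), e3)              # S/8
        d3 = T.add(self.dec3(d4), e2)             # S/4
        d2 = T.add(self.dec2(d3), e1)             # S/2
        d1 = self.dec1(d2)                        # S
        return T.sigmoid(self.classify(self.head(d1)))

    # -- temporal kernel view ---------------------------------------------
    @property
    def temporal_kernel(self) -> TemporalKernel:
        w = self.temporal.weight.data              # (16, depth, 3, 3)
        return TemporalKernel(w[:, None].copy(), self.temporal.bias.data.copy())

    def set_temporal_kernel(self, kernel: TemporalKernel) -> None:
        if kernel.depth != self.config.depth:
            raise ValueError(
                f"depth mismatch: kernel {kernel.depth} vs network "
                f"{self.config.depth}")
        self.temporal.weight.data = kernel.weights[:, 0].copy()
        self.temporal.bias.data = kernel.bias.copy()


def build_network(config: NetworkConfig, seed: int = 0) -> STNet:
    """Assemble the 3D-2D network for a given configuration."""
    return STNet(config, seed=seed)


def predict_proba(model: STNet, windows: np.ndarray,
                  batch_size: int = 8) -> np.ndarray:
    """Forward a stack of windows (M, depth, H, W) -> (M, H, W) in [0, 1]."""
    windows = np.asarray(windows, dtype=np.float32)
    out = np.empty((windows.shape[0],) + windows.shape[2:], np.float32)
    with T.no_grad():
        for lo in range(0, windows.shape[0], batch_size):
            batch = windows[lo:lo + batch_size]
            out[lo:lo + batch.shape[0]] = model(batch).data[:, 0]
    return out


# ---------------------------------------------------------------------------
# degeneracy: the 2D network is a point in the 3D-2D parameter space
# ---------------------------------------------------------------------------

def embed_2d_network(net2d: STNet, n: int, seed: int = 0) -> STNet:
    """Embed a 2D (N=0) network into the 3D-2D parameter space.

    The returned network has temporal radius ``n``; its temporal kernel is
    zero on all non-central slices and equals the 2D net's input kernel on the
    central slice, and every other weight is copied.  By construction it
    computes the same function of the central frame.
    """
    if net2d.config.n != 0:
        raise ValueError("net2d must have temporal radius 0")
    cfg = dataclasses.replace(net2d.config, n=n)
    net3d = STNet(cfg, seed=seed)
    state = net2d.state_dict()
    w2d = state.pop("temporal.weight")            # (16, 1, 3, 3)
    net3d.load_state_dict(state, strict=False)
    depth = cfg.depth
    w3d = np.zeros((w2d.shape[0], depth, 3, 3), np.float32)
    w3d[:, depth // 2] = w2d[:, 0]
    net3d.temporal.weight.data = w3d
    net3d.temporal.bias.data = state["temporal.bias"].copy()
    return net3d


def degenerate_to_2d(net3d: STNet, net2d: STNet,
                     windows: Sequence[np.ndarray]) -> float:
    """Maximum absolute output difference between the 3D-2D network and the
    2D network run on the central frames of ``windows``.

    The caller arranges the weight sharing (see :func:`embed_2d_network`);
    shapes are validated here.
    """
    n = net3d.config.n
    for name, p2 in net2d.named_parameters():
        p3 = dict(net3d.named_parameters()).get(name)
        if p3 is None or (name != "temporal.weight"
                          and p3.data.shape != p2.data.shape):
            raise ValueError(f"weight shape mismatch at {name}")
    worst = 0.0
    with T.no_grad():
        for win in windows:
            win = np.asarray(win, dtype=np.float32)
            out3 = net3d(win[None]).data
            out2 = net2d(win[None, n:n + 1]).data
            worst = max(worst, float(np.abs(out3 - out2).max()))
    return worst


# ---------------------------------------------------------------------------
# checkpoints: npz weight map + JSON config sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(model: STNet, path: Union[str, Path]) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    real = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = real.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=2))


def load_checkpoint(path: Union[str, Path]) -> STNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing config sidecar {sidecar}")
    config = NetworkConfig.from_dict(json.loads(sidecar.read_text()))
    model = STNet(config, seed=0)
    with np.load(path) as arrs:
        model.load_state_dict({k: arrs[k] for k in arrs.files})
    return model
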