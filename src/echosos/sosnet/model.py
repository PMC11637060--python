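"""The SoS regression network: a fully convolutional encoder-decoder mapping
one 128 x 1024 plane-wave RF frame to a 384 x 384 pixel-wise SoS map.

Architecture (one consistent realization of the stated kernel progressions):

* Encoder, six stages with anisotropic kernels whose time-axis width narrows
  from 15 to 3.  The first stages contract the 1024-sample axis faster than
  the 128-channel axis via strided convolution; the last three stages add 2x2
  max pooling.  Each stage is conv + LeakyReLU(0.1) + BatchNorm.
* Decoder, six stages with kernels widening from 3 to 11: nearest x2
  upsampling + conv (+BN) for the first four, conv + bilinear resize to
  384 x 384 in stage five, a 3x3 conv + BN in stage six, and a final 1x1
  conv.  Encoder stages 4/3/2 are concatenated onto decoder stages 3/4/5
  (the shape-matched skip pairing).

The network regresses SoS on a normalized scale s = (SoS - 1500)/100; the
final conv is zero-bias so an untrained model predicts 1500 m/s everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .layers import (F32, Conv2d, BatchNorm2d, LeakyReLU, MaxPool2x2,
                     Upsample2x, Resize, Layer)

SOS_OFFSET = 1500.0
SOS_SCALE = 100.0
INPUT_SHAPE = (128, 1024)
OUTPUT_SHAPE = (384, 384)


@dataclass
class NetworkConfig:
    # time-axis kernel widths: 15 narrowing to 3 (encoder), 3 widening to 11 (decoder)
    encoder_kernels: Tuple[Tuple[int, int], ...] = (
        (3, 15), (3, 13), (3, 11), (3, 9), (3, 7), (3, 3))
    decoder_kernels: Tuple[Tuple[int, int], ...] = (
        (3, 3), (3, 5), (3, 7), (3, 9), (3, 11), (3, 3))
    encoder_channels: Tuple[int, ...] = (32, 64, 128, 256, 256, 256)
    decoder_channels: Tuple[int, ...] = (256, 128, 64, 32, 32, 32)
    # stride per encoder stage; stages with pool=True append 2x2 max pooling.
    # The time axis contracts faster than the channel axis (1024 -> 256 after
    # one stage vs 128 -> 64).
    encoder_strides: Tuple[Tuple[int, int], ...] = (
        (2, 4), (1, 2), (2, 2), (1, 1), (1, 1), (1, 1))
    encoder_pool: Tuple[bool, ...] = (False, False, False, True, True, True)
    # (encoder_stage, decoder_stage), 1-based: encoder output concatenated
    # onto the decoder stage input
    skip_pairs: Tuple[Tuple[int, int], ...] = ((4, 3), (3, 4), (2, 5))
    leaky_slope: float = 0.1

    def small(self) -> "NetworkConfig":
        """Desk-scale profile: same topology, thin channels."""
        return NetworkConfig(encoder_channels=(4, 8, 8, 8, 8, 8),
                             decoder_channels=(8, 8, 8, 4, 4, 4),
                             encoder_kernels=self.encoder_kernels,
                             decoder_kernels=self.decoder_kernels,
                             encoder_strides=self.encoder_strides,
                             encoder_pool=self.encoder_pool,
                             skip_pairs=self.skip_pairs,
                             leaky_slope=self.leaky_slope)


@dataclass
class SoSMap:
    """Pixel-wise SoS estimate (384 x 384 at 0.1 mm), values in m/s."""

    values: np.ndarray
    pixel_size_mm: float = 0.1
    clipped: bool = False

    def clip_for_report(self, lo: float = 1300.0, hi: float = 1800.0) -> "SoSMap":
        return SoSMap(np.clip(self.values, lo, hi), self.pixel_size_mm, clipped=True)


class SoSNet:
    """Encoder-decoder regression model (see module docstring)."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.enc: List[List[Layer]] = []
        cin = 1
        for k, c, s, pool in zip(cfg.encoder_kernels, cfg.encoder_channels,
                                 cfg.encoder_strides, cfg.encoder_pool):
            stage: List[Layer] = [Conv2d(cin, c, k, stride=s, rng=rng),
                                  LeakyReLU(cfg.leaky_slope)]
            if pool:
                stage.append(MaxPool2x2())
            stage.append(BatchNorm2d(c))
            self.enc.append(stage)
            cin = c

        skip_from = {d: e for e, d in cfg.skip_pairs}
        self.skip_from = skip_from
        self.dec: List[List[Layer]] = []
        for i, (k, c) in enumerate(zip(cfg.decoder_kernels, cfg.decoder_channels), start=1):
            cin_stage = cin
            if i in skip_from:
                cin_stage += cfg.encoder_channels[skip_from[i] - 1]
            stage = []
            if i <= 4:
                stage.append(Upsample2x())
                stage.append(Conv2d(cin_stage, c, k, rng=rng))
                stage.append(LeakyReLU(cfg.leaky_slope))
                stage.append(BatchNorm2d(c))
            elif i == 5:
                stage.append(Conv2d(cin_stage, c, k, rng=rng))
                stage.append(LeakyReLU(cfg.leaky_slope))
                stage.append(Resize(*OUTPUT_SHAPE))
            else:  # stage 6: 3x3 conv + BN
                stage.append(Conv2d(cin_stage, c, k, rng=rng))
                stage.append(LeakyReLU(cfg.leaky_slope))
                stage.append(BatchNorm2d(c))
            self.dec.append(stage)
            cin = c
        self.head = Conv2d(cin, 1, (1, 1), rng=rng)
        self.head.params["b"][...] = 0.0

    # -- graph execution ----------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (B, 128, 1024) -> normalized SoS maps (B, 384, 384)."""
        h = x[:, None, :, :].astype(F32)
        enc_out: Dict[int, np.ndarray] = {}
        for idx, stage in enumerate(self.enc, start=1):
            for layer in stage:
                h = layer.forward(h, train)
            enc_out[idx] = h
        self._concat_channels: Dict[int, int] = {}
        for idx, stage in enumerate(self.dec, start=1):
            if idx in self.skip_from:
                skip = enc_out[self.skip_from[idx]]
                self._concat_channels[idx] = skip.shape[1]
                h = np.concatenate([h, skip], axis=1)
            for layer in stage:
                h = layer.forward(h, train)
        h = self.head.forward(h, train)
        return h[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        g = self.head.backward(dy[:, None].astype(F32))
        skip_grads: Dict[int, np.ndarray] = {}
        for idx in range(len(self.dec), 0, -1):
            for layer in reversed(self.dec[idx - 1]):
                g = layer.backward(g)
            if idx in self.skip_from:
                nskip = self._concat_channels[idx]
                skip_grads[self.skip_from[idx]] = g[:, -nskip:]
                g = g[:, :-nskip]
        for idx in range(len(self.enc), 0, -1):
            if idx in skip_grads:
                g = g + skip_grads[idx]
            for layer in reversed(self.enc[idx - 1]):
                g = layer.backward(g)

    # -- parameter plumbing -------------------------------------------------

    def layers(self) -> List[Layer]:
        out: List[Layer] = []
        for stage in self.enc + self.dec:
            out.extend(stage)
        out.append(self.head)
        return out

    def param_groups(self) -> List[Tuple[Layer, str]]:
        return [(l, name) for l in self.layers() for name in l.params]

    def n_parameters(self) -> int:
        return sum(l.params[n].size for l, n in self.param_groups())

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {}
        for i, l in enumerate(self.layers()):
            for name, arr in l.params.items():
                state[f"{i}.{name}"] = arr.copy()
            if isinstance(l, BatchNorm2d):
                state[f"{i}.running_mean"] = l.running_mean.copy()
                state[f"{i}.running_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers()):
            for name in l.params:
                l.params[name][...] = state[f"{i}.{name}"]
            if isinstance(l, BatchNorm2d):
                l.running_mean[...] = state[f"{i}.running_mean"]
                l.running_var[...] = state[f"{i}.running_var"]

    def checksum(self) -> float:
        """Over the full state (parameters + BN running statistics)."""
        return float(sum(np.abs(a).sum() for a in self.state_dict().values()))

    def param_checksum(self) -> float:
        """Over trainable parameters only."""
        return float(sum(np.abs(l.params[n]).sum() for l, n in self.param_groups()))


def build_model(cfg: Optional[NetworkConfig] = None, seed: int = 0) -> SoSNet:
    """Construct a seed-deterministic, Xavier-initialized model and verify the
    (128, 1024) -> (384, 384) shape contract with a dry run."""
    cfg = cfg or NetworkConfig()
    model = SoSNet(cfg, seed=seed)
    probe = np.zeros((1,) + INPUT_SHAPE, F32)
    out = model.forward(probe, train=False)
    if out.shape[1:] != OUTPUT_SHAPE:
        raise ValueError(f"network output {out.shape[1:]} != {OUTPUT_SHAPE}")
    return model


def predict_sos(model: "SoSNet | AugmentedSoSNet", rf: np.ndarray) -> SoSMap:
    """Map one conditioned RF frame to an SoS map in m/s."""
    rf = np.asarray(rf, dtype=F32)
    if rf.shape != INPUT_SHAPE:
        raise ValueError(f"expected RF shape {INPUT_SHAPE}, got {rf.shape}")
    means = np.abs(rf.mean(axis=1))
    nonzero = rf.std(axis=1) > 0
    if np.any(means[nonzero] > 0.1):
        import warnings
        warnings.warn("RF frame does not look conditioned (channel mean > 0.1)")
    out = model.forward(rf[None], train=False)[0]
    return SoSMap(SOS_OFFSET + SOS_SCALE * out.astype(np.float64))


class AugmentedSoSNet:
    """Frozen base + trainable residual head on the output map.

    output = base(x) + head(base(x)); the head's last conv is zero-initialized
    so the augmented model initially reproduces the base exactly.
    """

    def __init__(self, base: SoSNet, hidden: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.base = base
        self.head_layers: List[Layer] = [
            Conv2d(1, hidden, (3, 3), rng=rng),
            LeakyReLU(0.1),
            Conv2d(hidden, 1, (3, 3), zero_init=True),
        ]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        base_out = self.base.forward(x, train=False)  # frozen: eval statistics
        return self.forward_from_base(base_out, train=train)

    def forward_from_base(self, base_out: np.ndarray, train: bool = True) -> np.ndarray:
        """Head application on precomputed base outputs (the base is frozen,
        so its outputs can be cached during fine-tuning)."""
        h = base_out[:, None]
        for layer in self.head_layers:
            h = layer.forward(h, train)
        return base_out + h[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        # gradients flow through the head only; the base stays untouched
        g = dy[:, None].astype(F32)
        for layer in reversed(self.head_layers):
            g = layer.backward(g)

    def param_groups(self) -> List[Tuple[Layer, str]]:
        return [(l, n) for l in self.head_layers for n in l.params]

    def n_parameters(self) -> int:
        return sum(l.params[n].size for l, n in self.param_groups())


def attach_residual_head(model: SoSNet, hidden: int = 8, seed: int = 0) -> AugmentedSoSNet:
    return AugmentedSoSNet(model, hidden=hidden, seed=seed)


def expected_parameter_count(cfg: NetworkConfig) -> int:
    """Closed-form parameter count from the config layer arithmetic (conv
    weights+bias, BN gamma+beta), independent of the layer implementations."""
    total = 0
    cin = 1
    for k, c, pool in zip(cfg.encoder_kernels, cfg.encoder_channels, cfg.encoder_pool):
        total += c * cin * k[0] * k[1] + c  # conv
        total += 2 * c  # BN
        cin = c
    skip_from = {d: e for e, d in cfg.skip_pairs}
    for i, (k, c) in enumerate(zip(cfg.decoder_kernels, cfg.decoder_channels), start=1):
        cin_stage = cin + (cfg.encoder_channels[skip_from[i] - 1] if i in skip_from else 0)
        total += c * cin_stage * k[0] * k[1] + c
        if i != 5:  # stage 5 has no BN (conv + resize)
            total += 2 * c
        cin = c
    total += 1 * cin * 1 * 1 + 1  # final 1x1 conv
    return total
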