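"""Shared 2-D encoder–decoder network family.

The segmentation and registration stages all build on the same U-Net
backbone: encoding depth 5 (4 downsamplings), 3×3 convolutions starting at
16 kernels and doubling after each 2×2 max-pool up to 256 at the
bottleneck, a mirrored decoder with 2×2 nearest-neighbor upsampling,
leaky-ReLU (slope 0.01) + batch normalization after every convolution, and
residual (additive) skips between encoder and decoder blocks at equal
resolution.

Two heads are defined here:

* a segmentation/projection head — a 1×1 convolution on the decoder output;
* an affine head — 1×1 conv → 2×2 max-pool → flatten → dense(16) →
  dense(6) on the bottleneck features, emitting the 6 parameters of a 2-D
  affine map.  The 6 outputs are *deltas* about the identity, so a
  zero-initialized final layer starts exactly at the identity transform.

The non-rigid displacement head (two convolutions of 16 and 2 filters with
a ReLU between, final layer zero-initialized so training starts from zero
displacement) lives in :class:`NonRigidNet`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .nn import Tensor, Module, Conv2d, BatchNorm2d, Linear
from .nn import functional as F


@dataclass
class UNetConfig:
    """Architecture of one U-Net instance.

    Defaults reproduce the full-size backbone; tests use shallower/narrower
    variants (the architecture is a pure function of this config).
    """
    depth: int = 5
    base_channels: int = 16
    max_channels: int = 256
    in_channels: int = 1
    out_channels: int = 3
    leaky_slope: float = 0.01

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** l, self.max_channels)
                for l in range(self.depth)]

    def check_input(self, h: int, w: int):
        d = 2 ** (self.depth - 1)
        if h % d or w % d:
            raise ValueError(
                f"spatial dims ({h},{w}) must be divisible by {d}; "
                f"zero-pad the input (see preproc.pad_to_canvas)")


class _ConvBlock(Module):
    """conv → BN → leaky-ReLU, twice; optional residual add after conv1."""

    def __init__(self, cin: int, cout: int, slope: float,
                 rng: np.random.Generator):
        super().__init__()
        self.slope = slope
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)

    def __call__(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        h = self.bn1(self.conv1(x)).leaky_relu(self.slope)
        if skip is not None:
            h = h + skip
        return self.bn2(self.conv2(h)).leaky_relu(self.slope)


class UNet(Module):
    def __init__(self, cfg: UNetConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.channels()
        cin = cfg.in_channels
        for l in range(cfg.depth):
            setattr(self, f"enc{l}", _ConvBlock(cin, ch[l], cfg.leaky_slope, rng))
            cin = ch[l]
        for l in range(cfg.depth - 2, -1, -1):
            setattr(self, f"dec{l}", _ConvBlock(ch[l + 1], ch[l],
                                                cfg.leaky_slope, rng))
        self.head = Conv2d(ch[0], cfg.out_channels, 1, rng)

    def encode(self, x: Tensor) -> list[Tensor]:
        """Return per-level encoder features; last entry is the bottleneck."""
        self.cfg.check_input(*x.shape[2:])
        feats = []
        h = x
        for l in range(self.cfg.depth):
            h = getattr(self, f"enc{l}")(h)
            feats.append(h)
            if l < self.cfg.depth - 1:
                h = F.maxpool2x2(h)
        return feats

    def decode(self, feats: list[Tensor]) -> Tensor:
        h = feats[-1]
        for l in range(self.cfg.depth - 2, -1, -1):
            h = getattr(self, f"dec{l}")(F.upsample2x2(h), skip=feats[l])
        return h

    def features(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))


class AffineNet(Module):
    """Encoder + affine head predicting 6 affine deltas per batch item."""

    def __init__(self, cfg: UNetConfig, input_size: int, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.input_size = input_size
        rng = np.random.default_rng(seed)
        ch = cfg.channels()
        cin = cfg.in_channels
        for l in range(cfg.depth):
            setattr(self, f"enc{l}", _ConvBlock(cin, ch[l], cfg.leaky_slope, rng))
            cin = ch[l]
        self.reduce = Conv2d(ch[-1], 16, 1, rng)
        bottleneck = input_size // 2 ** (cfg.depth - 1)
        flat = 16 * (bottleneck // 2) ** 2
        self.fc1 = Linear(flat, 16, rng)
        self.fc2 = Linear(16, 6, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        self.cfg.check_input(*x.shape[2:])
        h = x
        for l in range(self.cfg.depth):
            h = getattr(self, f"enc{l}")(h)
            if l < self.cfg.depth - 1:
                h = F.maxpool2x2(h)
        h = F.maxpool2x2(self.reduce(h))
        h = h.reshape(h.shape[0], -1)
        return self.fc2(self.fc1(h).leaky_relu(self.cfg.leaky_slope))


class NonRigidNet(Module):
    """U-Net + displacement head (conv 16 → ReLU → conv 2, zero-init)."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed + 101)
        self.unet = UNet(cfg, seed=seed)
        self.hconv1 = Conv2d(cfg.channels()[0], 16, 3, rng)
        self.hconv2 = Conv2d(16, 2, 3, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.unet.features(x)
        return self.hconv2(self.hconv1(h).relu())


@dataclass
class ParameterSet:
    """Serializable weights + the config/seed that produced them."""
    state: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_module(cls, module: Module, config: dict | UNetConfig,
                    seed: int = 0) -> "ParameterSet":
        cfgd = asdict(config) if isinstance(config, UNetConfig) else dict(config)
        return cls(state=module.state_dict(), config=cfgd, seed=seed)

    def load_into(self, module: Module):
        module.load_state_dict(self.state)

    def save(self, path: str | Path):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state)
        manifest = {"config": self.config, "seed": self.seed,
                    "keys": sorted(self.state)}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            state = {k: z[k] for k in z.files}
        manifest = json.loads(path.with_suffix(".json").read_text())
        return cls(state=state, config=manifest["config"],
                   seed=manifest["seed"])


def unet_forward(params: ParameterSet, cfg: UNetConfig,
                 x: np.ndarray) -> np.ndarray:
    """Functional inference pass: (B, Cin, H, W) → (B, Cout, H, W)."""
    net = UNet(cfg, seed=params.seed)
    params.load_into(net)
    net.eval()
    return net(Tensor(x)).data


def affine_head_forward(params: ParameterSet, cfg: UNetConfig,
                        x: np.ndarray) -> np.ndarray:
    """Functional affine inference: (B, Cin, H, W) → (B, 6) deltas."""
    net = AffineNet(cfg, input_size=x.shape[-1], seed=params.seed)
    params.load_into(net)
    net.eval()
    return net(Tensor(x)).data
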