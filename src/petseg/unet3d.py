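"""3D u-net for volumetric kidney segmentation.

Encoder-decoder with skip connections in the fastMRI style, with every 2D
operation replaced by its 3D counterpart: convolution blocks of two 3x3x3
convolutions, each followed by instance normalization, leaky ReLU (negative
slope 0.2) and channel dropout; 2x2x2 average pooling down, 2x2x2 stride-2
transpose convolutions up, channel count doubling per level, and a final
1x1x1 convolution plus sigmoid so outputs lie in (0, 1).

The reference profile (depth 4, 24 base channels, 256x256x128 inputs) is the
full-scale configuration; a desk profile (depth 3, 8 channels, 64x64x32) keeps
training feasible on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .image_io import BinaryMask3D, MaskKind

__all__ = ["UNetConfig", "UNet3D", "build_model", "predict_mask",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class UNetConfig:
    in_channels: int = 1
    depth: int = 4              # number of downsampling levels
    base_channels: int = 24     # output channels of the first convolution
    leaky_slope: float = 0.2
    dropout_p: float = 0.1
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")

    @classmethod
    def desk(cls, in_channels: int = 1, **kw) -> "UNetConfig":
        """Small profile for CPU-scale experiments."""
        kw.setdefault("depth", 3)
        kw.setdefault("base_channels", 8)
        return cls(in_channels=in_channels, **kw)

    @classmethod
    def paper_scale(cls, in_channels: int = 1, **kw) -> "UNetConfig":
        return cls(in_channels=in_channels, **kw)


class _Sequential:
    def __init__(self, layers: list[nn.Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def _conv_block(cin: int, cout: int, cfg: UNetConfig, rng: np.random.Generator,
                dropout_rng: np.random.Generator) -> _Sequential:
    layers: list[nn.Layer] = []
    for a, b in ((cin, cout), (cout, cout)):
        layers += [
            nn.Conv3d(a, b, 3, rng, bias=False),
            nn.InstanceNorm3d(b),
            nn.LeakyReLU(cfg.leaky_slope),
            nn.ChannelDropout(cfg.dropout_p, dropout_rng),
        ]
    return _Sequential(layers)


def _transpose_block(cin: int, cout: int, cfg: UNetConfig,
                     rng: np.random.Generator) -> _Sequential:
    return _Sequential([
        nn.ConvTranspose3d(cin, cout, rng, bias=False),
        nn.InstanceNorm3d(cout),
        nn.LeakyReLU(cfg.leaky_slope),
    ])


class UNet3D:
    """Single-volume (no batch axis) 3D u-net; see module docstring."""

    def __init__(self, cfg: UNetConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)
        self.dropout_rng = np.random.default_rng(cfg.init_seed + 1)
        c = cfg.base_channels
        self.downs: list[_Sequential] = [_conv_block(cfg.in_channels, c, cfg, rng,
                                                     self.dropout_rng)]
        ch = c
        for _ in range(cfg.depth - 1):
            self.downs.append(_conv_block(ch, ch * 2, cfg, rng, self.dropout_rng))
            ch *= 2
        self.pools = [nn.AvgPool3d() for _ in range(cfg.depth)]
        self.bottleneck = _conv_block(ch, ch * 2, cfg, rng, self.dropout_rng)
        self.up_transpose: list[_Sequential] = []
        self.up_convs: list[_Sequential] = []
        for _ in range(cfg.depth):
            self.up_transpose.append(_transpose_block(ch * 2, ch, cfg, rng))
            self.up_convs.append(_conv_block(ch * 2, ch, cfg, rng, self.dropout_rng))
            ch //= 2
        self.final = nn.Conv3d(c, 1, 1, rng, bias=True)
        self.sigmoid = nn.Sigmoid()
        self._skip_channels: list[int] = []

    # -- plumbing ---------------------------------------------------------

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for blk in (*self.downs, self.bottleneck, *self.up_transpose, *self.up_convs):
            out.extend(blk.layers)
        out.extend(self.pools)
        out.append(self.final)
        out.append(self.sigmoid)
        return out

    def num_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected input shaped ({self.cfg.in_channels}, X, Y, Z), got {x.shape}")
        stride = 2 ** self.cfg.depth
        if any(s % stride for s in x.shape[1:]):
            raise ValueError(
                f"spatial dimensions {x.shape[1:]} must be divisible by 2^depth={stride}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Returns a (1, X, Y, Z) probability map with values in (0, 1)."""
        x = np.asarray(x, dtype=np.float32)
        self._check_input(x)
        skips: list[np.ndarray] = []
        for down, pool in zip(self.downs, self.pools):
            x = down.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up_t, up_c in zip(self.up_transpose, self.up_convs):
            skip = skips.pop()
            x = up_t.forward(x, train)
            self._skip_channels.append(x.shape[0])
            x = np.concatenate([x, skip], axis=0)
            x = up_c.forward(x, train)
        x = self.final.forward(x, train)
        return self.sigmoid.forward(x, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = self.sigmoid.backward(gy)
        gy = self.final.backward(gy)
        skip_grads: list[np.ndarray] = []
        for up_t, up_c, c_up in zip(reversed(self.up_transpose), reversed(self.up_convs),
                                    reversed(self._skip_channels)):
            gy = up_c.backward(gy)
            g_up, g_skip = gy[:c_up], gy[c_up:]
            skip_grads.append(g_skip)
            gy = up_t.backward(np.ascontiguousarray(g_up))
        gy = self.bottleneck.backward(gy)
        for down, pool in zip(reversed(self.downs), reversed(self.pools)):
            gy = pool.backward(gy) + skip_grads.pop()
            gy = down.backward(np.ascontiguousarray(gy))
        return gy


def build_model(cfg: UNetConfig) -> UNet3D:
    return UNet3D(cfg)


def predict_mask(model: UNet3D, channels: np.ndarray, spacing,
                 threshold: float = 0.5, kind: MaskKind = MaskKind.FINE) -> BinaryMask3D:
    """Binarize the model's sigmoid output at ``threshold`` (default 0.5)."""
    channels = np.asarray(channels, dtype=np.float32)
    if channels.ndim == 3:
        channels = channels[None]
    if channels.shape[0] != model.cfg.in_channels:
        raise ValueError(
            f"model expects {model.cfg.in_channels} channels, got {channels.shape[0]}")
    prob = model.forward(channels, train=False)[0]
    return BinaryMask3D(data=(prob >= threshold).astype(np.uint8),
                        spacing=spacing, kind=kind)


def save_checkpoint(model: UNet3D, path, extra: dict | None = None) -> None:
    """Parameters plus the embedded UNetConfig, as a .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers()):
        for name, p in layer.params.items():
            arrays[f"param.{i}.{name}"] = p
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    arrays["__meta__"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[UNet3D, dict]:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        model = UNet3D(UNetConfig(**meta["config"]))
        for i, layer in enumerate(model.layers()):
            for name in layer.params:
                layer.params[name][...] = npz[f"param.{i}.{name}"]
    return model, meta.get("extra", {})
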