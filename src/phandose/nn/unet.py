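"""The 2D U-net dose-prediction architecture.

Encoder-decoder with skip concatenations between matching resolutions.
Each resolution level holds a residual block (conv-BN-ReLU-conv-BN +
identity, ReLU), followed by one dropout layer — so dropout appears after
every two batch-normalisation layers.  Downsampling is a stride-2 2x2
convolution doubling the feature count; upsampling is nearest-neighbour
interpolation followed by a 3x3 convolution halving it, after which the
skip tensor is concatenated and fused by a 3x3 convolution.  The output is
a single-channel map at the input spatial size (linear activation: the
target is a normalised dose in [0, 1], and predictions are clamped to be
non-negative only after denormalisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Adam, BatchNorm, Conv2d, Dropout, Layer, Param, ReLU, Upsample2x


@dataclass(frozen=True)
class NetConfig:
    """U-net architecture parameters.

    ``base_features`` is the channel count at full resolution, doubled at
    every downsampling; ``depth`` is the number of downsamplings.  The
    desk-scale default (8 features, depth 2) trains on one CPU; the
    clinical-scale variant is expressible by raising both.
    """

    in_channels: int = 7
    base_features: int = 8
    depth: int = 2
    dropout: float = 0.1
    residual: bool = True
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.in_channels != 7:
            raise ValueError("the dose model takes exactly 7 input channels")


class _ResBlock:
    def __init__(self, c: int, cfg: NetConfig, rng, drop_rng):
        self.cfg = cfg
        self.conv1 = Conv2d(c, c, 3, rng=rng)
        self.bn1 = BatchNorm(c) if cfg.batchnorm else None
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c, c, 3, rng=rng)
        self.bn2 = BatchNorm(c) if cfg.batchnorm else None
        self.relu2 = ReLU()
        self.drop = Dropout(cfg.dropout, drop_rng)

    def layers(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2, self.drop]
        return [l for l in out if l is not None]

    def forward(self, x, train):
        h = self.conv1.forward(x, train)
        if self.bn1 is not None:
            h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        if self.bn2 is not None:
            h = self.bn2.forward(h, train)
        if self.cfg.residual:
            h = h + x
        h = self.relu2.forward(h, train)
        return self.drop.forward(h, train)

    def backward(self, dy):
        d = self.drop.backward(dy)
        d = self.relu2.backward(d)
        d_res = d if self.cfg.residual else None
        if self.bn2 is not None:
            d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        if self.bn1 is not None:
            d = self.bn1.backward(d)
        d = self.conv1.backward(d)
        return d + d_res if d_res is not None else d


class UNet:
    """2D U-net built from :class:`NetConfig`; see the module docstring.

    Takes input stacks of shape ``(B, 7, H, W)`` and returns ``(B, 1, H,
    W)``; H and W must be divisible by ``2**depth``.
    """

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        init_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        self._drop_rng = drop_rng
        ch = [cfg.base_features * 2**l for l in range(cfg.depth + 1)]

        self.stem = Conv2d(cfg.in_channels, ch[0], 3, rng=init_rng)
        self.stem_relu = ReLU()
        self.enc = [_ResBlock(ch[l], cfg, init_rng, drop_rng) for l in range(cfg.depth)]
        self.down = [Conv2d(ch[l], ch[l + 1], 2, stride=2, rng=init_rng) for l in range(cfg.depth)]
        self.bottleneck = _ResBlock(ch[cfg.depth], cfg, init_rng, drop_rng)
        self.up = [Upsample2x() for _ in range(cfg.depth)]
        self.upconv = [Conv2d(ch[l + 1], ch[l], 3, rng=init_rng) for l in range(cfg.depth)]
        self.fuse = [Conv2d(2 * ch[l], ch[l], 3, rng=init_rng) for l in range(cfg.depth)]
        self.fuse_relu = [ReLU() for _ in range(cfg.depth)]
        self.dec = [_ResBlock(ch[l], cfg, init_rng, drop_rng) for l in range(cfg.depth)]
        self.head = Conv2d(ch[0], 1, 1, rng=init_rng)
        self._ch = ch

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        mods: list[Layer] = [self.stem, self.stem_relu]
        for blk in self.enc:
            mods.extend(blk.layers())
        mods.extend(self.down)
        mods.extend(self.bottleneck.layers())
        mods.extend(self.upconv)
        mods.extend(self.fuse)
        for blk in self.dec:
            mods.extend(blk.layers())
        mods.append(self.head)
        return mods

    def params(self) -> list[Param]:
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def num_params(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected (B, {self.cfg.in_channels}, H, W), got {x.shape}")
        H, W = x.shape[2], x.shape[3]
        if H % 2**self.cfg.depth or W % 2**self.cfg.depth:
            raise ValueError(f"spatial size ({H},{W}) not divisible by 2^depth")
        # internal layout is channels-first (C, B, H, W)
        h = np.ascontiguousarray(np.transpose(x, (1, 0, 2, 3)), dtype=np.float32)
        h = self.stem_relu.forward(self.stem.forward(h, train), train)
        skips = []
        for l in range(self.cfg.depth):
            h = self.enc[l].forward(h, train)
            skips.append(h)
            h = self.down[l].forward(h, train)
        h = self.bottleneck.forward(h, train)
        for l in reversed(range(self.cfg.depth)):
            h = self.upconv[l].forward(self.up[l].forward(h, train), train)
            h = np.concatenate([h, skips[l]], axis=0)
            h = self.fuse_relu[l].forward(self.fuse[l].forward(h, train), train)
            h = self.dec[l].forward(h, train)
        y = self.head.forward(h, train)
        return np.transpose(y, (1, 0, 2, 3))

    def backward(self, dy: np.ndarray) -> None:
        d = np.ascontiguousarray(np.transpose(dy, (1, 0, 2, 3)), dtype=np.float32)
        d = self.head.backward(d)
        skip_grads: dict[int, np.ndarray] = {}
        for l in range(self.cfg.depth):
            d = self.dec[l].backward(d)
            d = self.fuse[l].backward(self.fuse_relu[l].backward(d))
            c = self._ch[l]
            skip_grads[l] = d[c:]
            d = self.up[l].backward(self.upconv[l].backward(np.ascontiguousarray(d[:c])))
        d = self.bottleneck.backward(d)
        for l in reversed(range(self.cfg.depth)):
            d = self.down[l].backward(d)
            d = d + skip_grads[l]
            d = self.enc[l].backward(d)
        self.stem.backward(self.stem_relu.backward(d))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (dropout off, running BN stats)."""
        return self.forward(x, train=False)

    # -- (de)serialisation --------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        i = 0
        for m in self._modules():
            if isinstance(m, BatchNorm):
                state[f"bn_{i}_mean"] = m.running_mean
                state[f"bn_{i}_var"] = m.running_var
                i += 1
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = state[f"param_{i}"].astype(np.float32)
        i = 0
        for m in self._modules():
            if isinstance(m, BatchNorm):
                m.running_mean = state[f"bn_{i}_mean"].astype(np.float32)
                m.running_var = state[f"bn_{i}_var"].astype(np.float32)
                i += 1


def build_unet(cfg: NetConfig, seed: int = 0) -> UNet:
    """Construct a seeded U-net; weights are reproducible from the seed."""
    return UNet(cfg, seed=seed)


def make_optimizer(model: UNet, lr: float = 1e-3, beta1: float = 0.9,
                   beta2: float = 0.999, weight_decay: float = 0.0) -> Adam:
    return Adam(model.params(), lr=lr, beta1=beta1, beta2=beta2, weight_decay=weight_decay)
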