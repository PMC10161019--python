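"""The ResDense U-net.

A five-level (configurable) encoder/decoder U-net for binary segmentation of
2-D patches. Each level is built from a ResDense block: two conv units
(3x3 convolution -> batch norm -> ReLU), whose output feature map is
*concatenated* with the block input along channels — a residual unit whose
skip connection preserves both the refined features and the untouched input
instead of summing them, so the identity path carries features (and
gradients) through the network unchanged. A 1x1 convolution after each
concatenation compresses channels back to the level width, keeping growth
bounded across levels. The decoder mirrors the encoder with nearest 2x
upsampling + 3x3 conv and concatenation of the corresponding encoder
feature; the head is a 1x1 convolution with a sigmoid, so the output is a
per-pixel vessel probability map.

``block`` selects the unit used at every level: ``resdense`` (default),
``residual`` (summation skip), ``dense`` (concatenate every conv unit's
output with the input) or ``plain`` (no skip).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    MaxPool2d,
    Param,
    ReLU,
    Sigmoid,
    UpsampleNearest2d,
)

__all__ = ["NetworkConfig", "ConvUnit", "ResDenseBlock", "UNet", "build_unet",
           "save_model", "load_model"]

_BLOCKS = ("resdense", "residual", "dense", "plain")


@dataclasses.dataclass
class NetworkConfig:
    """Declarative network description.

    ``input_size`` must be divisible by ``2**(levels-1)``; channel widths
    double per level starting at ``base_channels`` (32, 64, 128, 256, 512 at
    the defaults). ``blocks_per_level`` stacks that many blocks per level.
    """

    levels: int = 5
    base_channels: int = 32
    conv_kernel: int = 3
    pool_kernel: int = 2
    block: str = "resdense"
    blocks_per_level: int = 1
    in_channels: int = 1
    out_channels: int = 1
    input_size: int = 256

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.block not in _BLOCKS:
            raise ValueError(f"block must be one of {_BLOCKS}")
        if self.input_size % 2 ** (self.levels - 1):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.levels - 1}"
            )
        if self.blocks_per_level < 1:
            raise ValueError("blocks_per_level must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ConvUnit:
    """conv(3x3) -> batch norm -> ReLU; spatial size preserved."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3):
        self.conv = Conv2d(c_in, c_out, kernel, rng)
        self.bn = BatchNorm2d(c_out)
        self.relu = ReLU()
        self.out_channels = c_out

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x), train))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class ResDenseBlock:
    """out = concat(conv_unit(conv_unit(x, width), width), x).

    Output channels = width + c_in; the last c_in channels are the input,
    bit-for-bit, whatever the conv weights are.
    """

    def __init__(self, c_in: int, width: int, rng: np.random.Generator, kernel: int = 3):
        if width < 1:
            raise ValueError("width must be >= 1")
        self.u1 = ConvUnit(c_in, width, rng, kernel)
        self.u2 = ConvUnit(width, width, rng, kernel)
        self.c_in = c_in
        self.width = width
        self.out_channels = width + c_in

    def params(self) -> list[Param]:
        return self.u1.params() + self.u2.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        f = self.u2.forward(self.u1.forward(x, train), train)
        return np.concatenate([f, x], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        df, dx_direct = dy[..., : self.width], dy[..., self.width :]
        dx = self.u1.backward(self.u2.backward(df))
        return dx + dx_direct


class ResidualBlock:
    """Summation skip: out = conv_unit(conv_unit(x)) + proj(x); width channels."""

    def __init__(self, c_in: int, width: int, rng: np.random.Generator, kernel: int = 3):
        self.u1 = ConvUnit(c_in, width, rng, kernel)
        self.u2 = ConvUnit(width, width, rng, kernel)
        self.proj = Conv2d(c_in, width, 1, rng) if c_in != width else None
        self.out_channels = width

    def params(self) -> list[Param]:
        p = self.u1.params() + self.u2.params()
        return p + (self.proj.params() if self.proj else [])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        f = self.u2.forward(self.u1.forward(x, train), train)
        s = self.proj.forward(x) if self.proj else x
        return f + s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.u1.backward(self.u2.backward(dy))
        ds = self.proj.backward(dy) if self.proj else dy
        return dx + ds


class DenseBlock:
    """out = concat(f2, f1, x) with f1 = u1(x), f2 = u2(f1)."""

    def __init__(self, c_in: int, width: int, rng: np.random.Generator, kernel: int = 3):
        self.u1 = ConvUnit(c_in, width, rng, kernel)
        self.u2 = ConvUnit(width, width, rng, kernel)
        self.width = width
        self.out_channels = 2 * width + c_in

    def params(self) -> list[Param]:
        return self.u1.params() + self.u2.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        f1 = self.u1.forward(x, train)
        f2 = self.u2.forward(f1, train)
        return np.concatenate([f2, f1, x], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w = self.width
        df2, df1, dx_direct = dy[..., :w], dy[..., w : 2 * w], dy[..., 2 * w :]
        df1 = df1 + self.u2.backward(df2)
        return self.u1.backward(df1) + dx_direct


class PlainBlock:
    def __init__(self, c_in: int, width: int, rng: np.random.Generator, kernel: int = 3):
        self.u1 = ConvUnit(c_in, width, rng, kernel)
        self.u2 = ConvUnit(width, width, rng, kernel)
        self.out_channels = width

    def params(self) -> list[Param]:
        return self.u1.params() + self.u2.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.u2.forward(self.u1.forward(x, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.u1.backward(self.u2.backward(dy))


_BLOCK_CLS = {
    "resdense": ResDenseBlock,
    "residual": ResidualBlock,
    "dense": DenseBlock,
    "plain": PlainBlock,
}


class _Level:
    """blocks_per_level blocks, each followed by a 1x1 channel compression."""

    def __init__(self, c_in: int, width: int, cfg: NetworkConfig, rng: np.random.Generator):
        cls = _BLOCK_CLS[cfg.block]
        self.stages = []
        c = c_in
        for _ in range(cfg.blocks_per_level):
            block = cls(c, width, rng, cfg.conv_kernel)
            comp = (Conv2d(block.out_channels, width, 1, rng)
                    if block.out_channels != width else None)
            self.stages.append((block, comp))
            c = width
        self.out_channels = width

    def params(self) -> list[Param]:
        out = []
        for block, comp in self.stages:
            out += block.params()
            if comp:
                out += comp.params()
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for block, comp in self.stages:
            x = block.forward(x, train)
            if comp:
                x = comp.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for block, comp in reversed(self.stages):
            if comp:
                dy = comp.backward(dy)
            dy = block.backward(dy)
        return dy


class UNet:
    """The model handle: configuration, parameter state and training history."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.history: dict | None = None
        rng = np.random.default_rng(seed)
        L = config.levels
        widths = [config.base_channels * 2**i for i in range(L)]

        self.enc: list[_Level] = []
        self.pools: list[MaxPool2d] = []
        c = config.in_channels
        for lvl in range(L - 1):
            level = _Level(c, widths[lvl], config, rng)
            self.enc.append(level)
            self.pools.append(MaxPool2d())
            c = widths[lvl]
        self.bottleneck = _Level(c, widths[L - 1], config, rng)

        self.ups: list[UpsampleNearest2d] = []
        self.upconv: list[ConvUnit] = []
        self.dec: list[_Level] = []
        c = widths[L - 1]
        for lvl in range(L - 2, -1, -1):
            self.ups.append(UpsampleNearest2d())
            self.upconv.append(ConvUnit(c, widths[lvl], rng, config.conv_kernel))
            self.dec.append(_Level(2 * widths[lvl], widths[lvl], config, rng))
            c = widths[lvl]
        self.head = Conv2d(widths[0], config.out_channels, 1, rng)
        self.sigmoid = Sigmoid()

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for level in self.enc:
            out += level.params()
        out += self.bottleneck.params()
        for uc, level in zip(self.upconv, self.dec):
            out += uc.params()
            out += level.params()
        out += self.head.params()
        return out

    def _bn_layers(self) -> list[BatchNorm2d]:
        bns = []

        def collect(obj):
            if isinstance(obj, BatchNorm2d):
                bns.append(obj)
            elif isinstance(obj, ConvUnit):
                bns.append(obj.bn)
            elif isinstance(obj, (_Level,)):
                for block, _ in obj.stages:
                    collect(block)
            elif isinstance(obj, (ResDenseBlock, ResidualBlock, DenseBlock, PlainBlock)):
                collect(obj.u1)
                collect(obj.u2)

        for level in self.enc:
            collect(level)
        collect(self.bottleneck)
        for uc in self.upconv:
            collect(uc)
        for level in self.dec:
            collect(level)
        return bns

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn{i}.mean"] = bn.running_mean.copy()
            state[f"bn{i}.var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"bn{i}.mean"]
            bn.running_var[...] = state[f"bn{i}.var"]

    # -- forward / backward -------------------------------------------------
    # Feature maps run channels-last internally; the public contract is
    # channels-first (N, 1, H, W), matching the patch arrays.
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probability map, same shape as the input, values in (0, 1).

        Accepts ``(H, W)``, ``(N, H, W)`` or ``(N, C, H, W)``; returns
        ``(N, C_out, H, W)``.
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        h, w = x.shape[2:]
        div = 2 ** (self.config.levels - 1)
        if h % div or w % div:
            raise ValueError(f"input {h}x{w} not divisible by {div}")
        skips = []
        out = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # -> NHWC
        for level, pool in zip(self.enc, self.pools):
            out = level.forward(out, train)
            skips.append(out)
            out = pool.forward(out)
        out = self.bottleneck.forward(out, train)
        for up, uc, level, skip in zip(self.ups, self.upconv, self.dec, reversed(skips)):
            out = up.forward(out)
            out = uc.forward(out, train)
            out = np.concatenate([out, skip], axis=-1)
            out = level.forward(out, train)
        prob = self.sigmoid.forward(self.head.forward(out))
        return np.ascontiguousarray(prob.transpose(0, 3, 1, 2))  # -> NCHW

    __call__ = forward

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. the output probabilities (NCHW);
        returns the gradient w.r.t. the network input (NCHW)."""
        dprob = np.ascontiguousarray(
            np.asarray(dprob, dtype=np.float32).transpose(0, 2, 3, 1)
        )
        dy = self.head.backward(self.sigmoid.backward(dprob))
        skip_grads: list[np.ndarray] = []
        # decoder backward (reverse order of forward)
        for i in range(len(self.dec) - 1, -1, -1):
            lvl_width = self.dec[i].out_channels
            dy = self.dec[i].backward(dy)
            d_up, d_skip = dy[..., :lvl_width], dy[..., lvl_width:]
            skip_grads.append(d_skip)
            dy = self.ups[i].backward(self.upconv[i].backward(d_up))
        dy = self.bottleneck.backward(dy)
        # backward visits decoder levels shallow-first, so skip_grads[lvl]
        # already lines up with encoder level lvl
        for lvl in range(len(self.enc) - 1, -1, -1):
            dy = self.pools[lvl].backward(dy)
            dy = dy + skip_grads[lvl]
            dy = self.enc[lvl].backward(dy)
        return np.ascontiguousarray(dy.transpose(0, 3, 1, 2))  # -> NCHW

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def summary(self) -> str:
        cfg = self.config
        widths = [cfg.base_channels * 2**i for i in range(cfg.levels)]
        lines = [
            f"UNet(levels={cfg.levels}, block={cfg.block}, widths={widths}, "
            f"params={self.n_parameters():,})"
        ]
        size = cfg.input_size
        for lvl, w in enumerate(widths[:-1]):
            lines.append(f"  enc L{lvl}: {size}x{size} x{w}")
            size //= 2
        lines.append(f"  bottleneck: {size}x{size} x{widths[-1]}")
        for lvl in range(cfg.levels - 2, -1, -1):
            size *= 2
            lines.append(f"  dec L{lvl}: {size}x{size} x{widths[lvl]}")
        return "\n".join(lines)


def build_unet(cfg: NetworkConfig | None = None, seed: int = 0) -> UNet:
    """Construct a randomly initialized network from the configuration."""
    return UNet(cfg or NetworkConfig(), seed=seed)


def save_model(model: UNet, path: str | Path) -> None:
    """Single-file checkpoint: parameter state plus the embedded config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **state)


def load_model(path: str | Path) -> UNet:
    arch = np.load(path)
    cfg = NetworkConfig(**json.loads(bytes(arch["__config__"]).decode()))
    model = UNet(cfg)
    model.load_state_dict({k: arch[k] for k in arch.files if k != "__config__"})
    return model
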