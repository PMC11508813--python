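"""The wheal-segmentation network: VGG-16 encoder, skip-connected decoder.

Five convolutional blocks (64/128/256/512/512 filters at full width), each
followed by 2x2 max pooling; a 7x7 + 1x1 head of 4096 filters; a 1x1 class
scorer; then 2x upsampling summed with a 1x1-adjusted pool4 skip, another
2x upsampling summed with a 1x1-adjusted pool3 skip, and a final 8x
upsampling into a per-pixel softmax.  All hidden activations are ReLU.

``width_multiplier`` scales every filter count so the same topology can be
trained at desk scale on CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from whealmeter.nn import layers as L

VGG16_WIDTHS = (64, 128, 256, 512, 512)
VGG16_CONVS_PER_BLOCK = (2, 2, 3, 3, 3)
HEAD_KERNEL = 7


class ConfigurationError(ValueError):
    """The network configuration violates an architectural constraint."""


@dataclass(frozen=True)
class NetworkConfig:
    input_size: tuple[int, int] = (640, 480)  # (width, height)
    n_classes: int = 3
    encoder_widths: tuple[int, ...] = VGG16_WIDTHS
    convs_per_block: tuple[int, ...] = VGG16_CONVS_PER_BLOCK
    head_width: int = 4096
    width_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.input_size
        if w % 32 or h % 32:
            raise ConfigurationError(
                f"input dimensions must be divisible by 32 (five 2x poolings), got {w}x{h}"
            )
        if self.width_multiplier <= 0:
            raise ConfigurationError("width_multiplier must be positive")
        if len(self.encoder_widths) != len(self.convs_per_block):
            raise ConfigurationError("encoder_widths and convs_per_block lengths differ")

    def scaled_widths(self) -> tuple[int, ...]:
        return tuple(max(1, round(w * self.width_multiplier)) for w in self.encoder_widths)

    def scaled_head_width(self) -> int:
        return max(1, round(self.head_width * self.width_multiplier))

    def parameter_count(self) -> int:
        """Analytic parameter count (weights + biases), without allocation."""
        total = 0
        c_in = 3
        for width, n_convs in zip(self.scaled_widths(), self.convs_per_block):
            for _ in range(n_convs):
                total += width * c_in * 9 + width
                c_in = width
        head = self.scaled_head_width()
        total += head * c_in * HEAD_KERNEL**2 + head  # 7x7 head conv
        total += head * head + head  # 1x1 head conv
        nc = self.n_classes
        total += nc * head + nc  # class scorer
        # skip adjustments: 1x1 convs from pool4 and pool3 widths to n_classes
        total += nc * self.scaled_widths()[3] + nc
        total += nc * self.scaled_widths()[2] + nc
        # three transposed convolutions (2x, 2x, 8x), kernels 4, 4, 16
        total += nc * nc * 16 + nc
        total += nc * nc * 16 + nc
        total += nc * nc * 256 + nc
        return total


class FCN:
    """Fully convolutional segmentation model (see module docstring)."""

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.scaled_widths()
        nc = config.n_classes

        self.blocks: list[list[L.Layer]] = []
        self.pools: list[L.MaxPool2] = []
        c_in = 3
        for width, n_convs in zip(widths, config.convs_per_block):
            block: list[L.Layer] = []
            for _ in range(n_convs):
                block.append(L.Conv2D(c_in, width, 3, rng))
                block.append(L.ReLU())
                c_in = width
            self.blocks.append(block)
            self.pools.append(L.MaxPool2())

        head = config.scaled_head_width()
        self.head7 = L.Conv2D(c_in, head, HEAD_KERNEL, rng)
        self.head7_relu = L.ReLU()
        self.head1 = L.Conv2D(head, head, 1, rng)
        self.head1_relu = L.ReLU()
        self.score = L.Conv2D(head, nc, 1, rng)
        # zero-init skips: early training matches the skip-free path
        self.skip4 = L.Conv2D(widths[3], nc, 1, rng, init="zero")
        self.skip3 = L.Conv2D(widths[2], nc, 1, rng, init="zero")
        self.up2a = L.ConvTranspose2D(nc, nc, 2, rng)
        self.up2b = L.ConvTranspose2D(nc, nc, 2, rng)
        self.up8 = L.ConvTranspose2D(nc, nc, 8, rng)

    # -- plumbing ----------------------------------------------------------

    def layers(self) -> list[L.Layer]:
        out: list[L.Layer] = [l for block in self.blocks for l in block]
        out += self.pools
        out += [
            self.head7,
            self.head7_relu,
            self.head1,
            self.head1_relu,
            self.score,
            self.skip4,
            self.skip3,
            self.up2a,
            self.up2b,
            self.up8,
        ]
        return out

    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers() for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers() for g in l.grads()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward ------------------------------------------------

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Input ``(N, 3, H, W)`` float -> per-pixel class logits ``(N, C, H, W)``."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ConfigurationError(
                f"input dimensions must be divisible by 32, got {x.shape[2]}x{x.shape[3]}"
            )
        feats = []
        for block, pool in zip(self.blocks, self.pools):
            for layer in block:
                x = layer.forward(x)
            x = pool.forward(x)
            feats.append(x)
        pool3, pool4 = feats[2], feats[3]

        x = self.head7_relu.forward(self.head7.forward(x))
        x = self.head1_relu.forward(self.head1.forward(x))
        x = self.score.forward(x)
        x = self.up2a.forward(x) + self.skip4.forward(pool4)
        x = self.up2b.forward(x) + self.skip3.forward(pool3)
        return self.up8.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities ``(N, C, H, W)`` (softmax over C)."""
        return L.softmax(self.forward_logits(x), axis=1)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        d = self.up8.backward(dlogits)
        dpool3 = self.skip3.backward(d)
        d = self.up2b.backward(d)
        dpool4 = self.skip4.backward(d)
        d = self.up2a.backward(d)
        d = self.score.backward(d)
        d = self.head1.backward(self.head1_relu.backward(d))
        d = self.head7.backward(self.head7_relu.backward(d))

        for i in reversed(range(len(self.blocks))):
            if i == 3:
                d = d + dpool4
            elif i == 2:
                d = d + dpool3
            d = self.pools[i].backward(d)
            for layer in reversed(self.blocks[i]):
                d = layer.backward(d)

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model expects {len(params)}"
            )
        for i, p in enumerate(params):
            arr = state[f"param_{i}"]
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for param_{i}: {arr.shape} vs {p.shape}")
            p[...] = arr

    def config_json(self) -> str:
        return json.dumps(asdict(self.config))


def build_network(config: NetworkConfig) -> FCN:
    """Construct the segmentation network for the given configuration."""
    return FCN(config)
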