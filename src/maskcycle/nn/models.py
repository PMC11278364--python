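"""Model architectures: residual generator, patch discriminator, U-Net.

The generator and discriminator follow the canonical unpaired-translation
recipe: a c7s1 stem, two stride-2 downsampling convolutions, a stack of
residual blocks at the bottleneck resolution, nearest-upsample+conv
decoding, reflection padding and instance normalization; the discriminator
is a patch-level least-squares classifier.  Channel counts and block depth
are constructor arguments so desk-scale tests can run tiny instances.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (Conv2d, InstanceNorm2d, LeakyReLU, Module, ReLU,
                     Sequential, Sigmoid, Tanh, Upsample2x)


class ResidualBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.body = Sequential(
            Conv2d(channels, channels, 3, rng, padding=1, pad_mode="reflect"),
            InstanceNorm2d(), ReLU(),
            Conv2d(channels, channels, 3, rng, padding=1, pad_mode="reflect"),
            InstanceNorm2d(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return ag.add(x, self.body(x))


class ResnetGenerator(Module):
    """Encoder / residual bottleneck / decoder generator with tanh output."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 base_channels: int = 64, n_blocks: int = 6):
        b = base_channels
        layers: list[Module] = [
            Conv2d(in_ch, b, 7, rng, padding=3, pad_mode="reflect"),
            InstanceNorm2d(), ReLU(),
            Conv2d(b, 2 * b, 3, rng, stride=2, padding=1),
            InstanceNorm2d(), ReLU(),
            Conv2d(2 * b, 4 * b, 3, rng, stride=2, padding=1),
            InstanceNorm2d(), ReLU(),
        ]
        layers += [ResidualBlock(4 * b, rng) for _ in range(n_blocks)]
        layers += [
            Upsample2x(), Conv2d(4 * b, 2 * b, 3, rng, padding=1),
            InstanceNorm2d(), ReLU(),
            Upsample2x(), Conv2d(2 * b, b, 3, rng, padding=1),
            InstanceNorm2d(), ReLU(),
            Conv2d(b, out_ch, 7, rng, padding=3, pad_mode="reflect"),
            Tanh(),
        ]
        self.net = Sequential(*layers)
        self.in_channels = in_ch
        self.out_channels = out_ch

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"generator expects NCHW input with {self.in_channels} channels, "
                f"got shape {x.data.shape}")
        return self.net(x)


class PatchDiscriminator(Module):
    """Convolutional classifier producing a grid of realism scores."""

    def __init__(self, in_ch: int, rng: np.random.Generator,
                 base_channels: int = 64, n_layers: int = 3):
        b = base_channels
        layers: list[Module] = [
            Conv2d(in_ch, b, 4, rng, stride=2, padding=1), LeakyReLU(0.2)]
        ch = b
        for i in range(1, n_layers):
            nxt = min(b * 2 ** i, 8 * b)
            layers += [Conv2d(ch, nxt, 4, rng, stride=2, padding=1),
                       InstanceNorm2d(), LeakyReLU(0.2)]
            ch = nxt
        nxt = min(b * 2 ** n_layers, 8 * b)
        layers += [Conv2d(ch, nxt, 4, rng, stride=1, padding=1),
                   InstanceNorm2d(), LeakyReLU(0.2),
                   Conv2d(nxt, 1, 4, rng, stride=1, padding=1)]
        self.net = Sequential(*layers)
        self.in_channels = in_ch

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"discriminator expects NCHW input with {self.in_channels} channels, "
                f"got shape {x.data.shape}")
        return self.net(x)


class _DoubleConv(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.body = Sequential(
            Conv2d(in_ch, out_ch, 3, rng, padding=1, init_gain=0.05),
            InstanceNorm2d(), ReLU(),
            Conv2d(out_ch, out_ch, 3, rng, padding=1, init_gain=0.05),
            InstanceNorm2d(), ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class UNet(Module):
    """Encoder-decoder segmenter with skip connections and sigmoid output.

    Downsampling is a stride-2 convolution, upsampling nearest-neighbour
    followed by a convolution; spatial dimensions are preserved end to end
    and must be divisible by 2**depth.
    """

    def __init__(self, rng: np.random.Generator, depth: int = 4,
                 base_channels: int = 64, in_ch: int = 3, out_ch: int = 1):
        if depth < 2:
            raise ValueError("U-Net depth must be >= 2")
        self.depth = depth
        self.in_channels = in_ch
        self.enc = []
        self.down = []
        ch = in_ch
        width = base_channels
        for _ in range(depth):
            self.enc.append(_DoubleConv(ch, width, rng))
            self.down.append(Conv2d(width, width, 3, rng, stride=2, padding=1,
                                    init_gain=0.05))
            ch = width
            width *= 2
        self.bottleneck = _DoubleConv(ch, width, rng)
        self.up = []
        self.dec = []
        for _ in range(depth):
            self.up.append(Conv2d(width, ch, 3, rng, padding=1, init_gain=0.05))
            self.dec.append(_DoubleConv(2 * ch, ch, rng))
            width = ch
            ch = max(ch // 2, base_channels)
        self.head = Conv2d(width, out_ch, 1, rng, init_gain=0.05)
        self.out_act = Sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != self.in_channels:
            raise ValueError(f"U-Net expects NCHW input with {self.in_channels} "
                             f"channels, got shape {x.data.shape}")
        H, W = x.data.shape[2], x.data.shape[3]
        factor = 2 ** self.depth
        if H % factor or W % factor:
            raise ValueError(
                f"input dims ({H}x{W}) must be divisible by 2**depth = {factor}; "
                "pad or resize the input")
        skips = []
        for enc, down in zip(self.enc, self.down):
            x = enc(x)
            skips.append(x)
            x = down(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up(ag.upsample_nearest2x(x))
            x = dec(ag.concat([skip, x], axis=1))
        return self.out_act(self.head(x))
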