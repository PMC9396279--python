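"""Per-modality feature-extraction backbone: a symmetric U-Net auto-encoder.

Each input modality gets its own auto-encoder (identical architecture,
independent weights) trained to reconstruct its input under a pixel-wise
l1 loss.  The encoder taps export the modality's "unique" feature maps at
three depths — the two skip-connection levels and the bottleneck — which
downstream fusion blocks consume.  Encoder activations are LeakyReLU,
decoder activations ReLU, and every convolution is followed by batch
normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Tensor, concat, conv_bn_act, max_pool2d, upsample_nearest2d,
                 Module, Conv2d, Tanh, Identity)


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of one auto-encoder.

    base_channels doubles at each pooling stage; depth is the number of
    pooling stages (the two skip connections require depth >= 2).  Inputs
    must be divisible by 2**depth in both spatial dimensions.
    """

    base_channels: int = 32
    depth: int = 2
    kernel_size: int = 3
    leaky_slope: float = 0.2
    output_activation: str = "tanh"     # "tanh" for [-1,1]-scaled data
    feature_tap_levels: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2 (two skip connections)")
        for lvl in self.feature_tap_levels:
            if not 0 <= lvl <= self.depth:
                raise ValueError(f"tap level {lvl} outside 0..{self.depth}")

    def channels_at(self, level: int) -> int:
        return self.base_channels * 2 ** level

    @staticmethod
    def tiny() -> "BackboneConfig":
        return BackboneConfig(base_channels=8)


@dataclass
class FeatureSet:
    """Per-modality unique features S^(i) keyed by tap level.

    Level 0 is full resolution; the spatial size halves per level; the
    deepest level is the bottleneck f_i.
    """

    levels: dict[int, Tensor] = field(default_factory=dict)
    modality: str = ""

    def __getitem__(self, level: int) -> Tensor:
        return self.levels[level]

    @property
    def tap_levels(self) -> list[int]:
        return sorted(self.levels)

    @property
    def bottleneck(self) -> Tensor:
        return self.levels[max(self.levels)]

    def shapes(self) -> dict[int, tuple]:
        return {k: v.data.shape for k, v in self.levels.items()}


class UNetBackbone(Module):
    """Symmetric U-Net auto-encoder with skip connections at every level."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        super().__init__()
        self.config = config
        c = config
        self.enc_blocks = []
        ch_in = in_channels
        for lvl in range(c.depth):
            block = conv_bn_act(ch_in, c.channels_at(lvl), rng,
                                activation="leaky_relu",
                                kernel_size=c.kernel_size,
                                leaky_slope=c.leaky_slope)
            setattr(self, f"enc{lvl}", block)
            self.enc_blocks.append(block)
            ch_in = c.channels_at(lvl)
        self.bottleneck_block = conv_bn_act(
            ch_in, c.channels_at(c.depth), rng, activation="leaky_relu",
            kernel_size=c.kernel_size, leaky_slope=c.leaky_slope)
        self.dec_blocks = []
        ch_in = c.channels_at(c.depth)
        for lvl in reversed(range(c.depth)):
            block = conv_bn_act(ch_in + c.channels_at(lvl), c.channels_at(lvl),
                                rng, activation="relu",
                                kernel_size=c.kernel_size)
            setattr(self, f"dec{lvl}", block)
            self.dec_blocks.append(block)
            ch_in = c.channels_at(lvl)
        self.out_conv = Conv2d(ch_in, in_channels, c.kernel_size, rng)
        self.out_act = Tanh() if c.output_activation == "tanh" else Identity()

    # -- forward passes -----------------------------------------------------

    def encode(self, x: Tensor, modality: str = "") -> FeatureSet:
        """Run the encoder; export tap-level maps (level 0 = full res)."""
        c = self.config
        self._check_spatial(x)
        levels: dict[int, Tensor] = {}
        h = x
        for lvl, block in enumerate(self.enc_blocks):
            h = block(h)
            levels[lvl] = h
            h = max_pool2d(h, 2)
        h = self.bottleneck_block(h)
        levels[c.depth] = h
        return FeatureSet(
            levels={k: levels[k] for k in c.feature_tap_levels},
            modality=modality)

    def decode(self, fs: FeatureSet) -> Tensor:
        """Reconstruct from a full FeatureSet (skips consume the tap maps)."""
        c = self.config
        for lvl in range(c.depth + 1):
            if lvl not in fs.levels:
                raise ValueError(f"FeatureSet missing tap level {lvl} "
                                 "needed by the decoder skip connections")
        h = fs.levels[c.depth]
        for block, lvl in zip(self.dec_blocks, reversed(range(c.depth))):
            h = upsample_nearest2d(h, 2)
            skip = fs.levels[lvl]
            if skip.data.shape[-2:] != h.data.shape[-2:]:
                raise ValueError(
                    f"skip at level {lvl} has spatial {skip.data.shape[-2:]}, "
                    f"decoder path has {h.data.shape[-2:]}")
            h = block(concat([h, skip], axis=1))
        return self.out_act(self.out_conv(h))

    def decoder_features(self, fs: FeatureSet) -> Tensor:
        """Output of the first decoder stage (attachment point for the
        slice-index branch)."""
        c = self.config
        h = upsample_nearest2d(fs.levels[c.depth], 2)
        return self.dec_blocks[0](concat([h, fs.levels[c.depth - 1]], axis=1))

    def forward(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))

    def _check_spatial(self, x: Tensor) -> None:
        H, W = x.data.shape[-2:]
        f = 2 ** self.config.depth
        if H % f or W % f:
            raise ValueError(
                f"spatial size ({H},{W}) not divisible by 2^depth = {f}")


def reconstruction_loss(x: Tensor, x_hat: Tensor) -> Tensor:
    """Pixel-wise l1 reconstruction loss (mean reduction)."""
    if x.data.shape != x_hat.data.shape:
        raise ValueError(f"shape mismatch: {x.data.shape} vs {x_hat.data.shape}")
    return (x - x_hat).abs().mean()
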