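"""Multimodal attention feature fusion (MAFFB) and the layer-wise fusion network.

A MAFFB fuses two same-shape feature maps S1, S2 by three element-wise
operations,

    F+   = S1 + S2
    F×   = S1 · S2
    Fmax = max(S1, S2)
    F_concat = [F+, F×, Fmax]  (3C channels),

weighs F_concat per channel with an attention map

    M_c = σ( MLP(avgpool(F_concat)) + MLP(maxpool(F_concat)) ),

(the MLP is a shared two-layer 1×1-conv bottleneck), then applies
conv–BN–ReLU, concatenates the previous block's common features when
present, and a second conv–BN–ReLU produces the block's common features F_n.
All three fusion operations are symmetric, so every block — and the whole
fusion network — is invariant to swapping the two modality streams.

The fusion network chains three MAFFBs across the backbone tap levels
(full resolution, half, bottleneck); the previous block's output is
average-pooled (stride 2) to the next level's spatial size.
"""

from __future__ import annotations

import numpy as np

from .backbone import BackboneConfig, FeatureSet
from .nn import (Module, Conv2d, Tensor, avg_pool2d, concat, conv_bn_act,
                 maximum)


def fuse_ops(s1: Tensor, s2: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Element-wise sum, product and maximum of two same-shape maps."""
    if s1.data.shape != s2.data.shape:
        raise ValueError(f"shape mismatch: {s1.data.shape} vs {s2.data.shape}")
    return s1 + s2, s1 * s2, maximum(s1, s2)


class ChannelAttention(Module):
    """Per-channel gate in (0,1) from pooled descriptors through a shared MLP.

    The MLP is 1×1 conv (C → C/r) → ReLU → 1×1 conv (C → C), applied to both
    the global-average and global-max pooled descriptors; the two responses
    are summed and squashed by a sigmoid.
    """

    def __init__(self, channels: int, rng: np.random.Generator, ratio: int = 8):
        super().__init__()
        hidden = max(1, channels // ratio)
        self.fc1 = Conv2d(channels, hidden, 1, rng, padding=0, bias=False)
        self.fc2 = Conv2d(hidden, channels, 1, rng, padding=0, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max_spatial()
        shared = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return shared.sigmoid()


class MAFFB(Module):
    """One multimodal attention feature fusion block.

    ``prev_channels`` is the channel count of the previous block's (spatially
    aligned) common features, or None for a first block with two inputs only.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, prev_channels: int | None = None,
                 attention_ratio: int = 8):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.prev_channels = prev_channels
        self.attention = ChannelAttention(3 * in_channels, rng,
                                          ratio=attention_ratio)
        self.conv1 = conv_bn_act(3 * in_channels, out_channels, rng, "relu")
        c2_in = out_channels + (prev_channels or 0)
        self.conv2 = conv_bn_act(c2_in, out_channels, rng, "relu")

    def forward(self, s1: Tensor, s2: Tensor,
                f_prev: Tensor | None = None) -> Tensor:
        if (f_prev is None) != (self.prev_channels is None):
            raise ValueError("f_prev presence does not match block configuration")
        f_plus, f_times, f_max = fuse_ops(s1, s2)
        f_concat = concat([f_plus, f_times, f_max], axis=1)
        gated = f_concat * self.attention(f_concat)
        h = self.conv1(gated)
        if f_prev is not None:
            if f_prev.data.shape[-2:] != h.data.shape[-2:]:
                raise ValueError(
                    f"f_prev spatial {f_prev.data.shape[-2:]} incompatible "
                    f"with block spatial {h.data.shape[-2:]}")
            if f_prev.data.shape[1] != self.prev_channels:
                raise ValueError(
                    f"f_prev has {f_prev.data.shape[1]} channels, block "
                    f"expects {self.prev_channels}")
            h = concat([h, f_prev], axis=1)
        return self.conv2(h)


class FusionNetwork(Module):
    """Three chained MAFFBs over the backbone tap levels.

    Block k consumes both modalities' unique features at tap level k plus the
    previous block's common features, average-pooled down one level.  Common
    feature widths default to the corresponding unique widths.
    """

    N_BLOCKS = 3

    def __init__(self, backbone_config: BackboneConfig,
                 rng: np.random.Generator, attention_ratio: int = 8):
        super().__init__()
        taps = sorted(backbone_config.feature_tap_levels)
        if len(taps) != self.N_BLOCKS:
            raise ValueError(
                f"fusion network needs {self.N_BLOCKS} tap levels, got {taps}")
        self.tap_levels = taps
        self.common_channels = {
            lvl: backbone_config.channels_at(lvl) for lvl in taps}
        self.blocks: list[MAFFB] = []
        prev = None
        for lvl in taps:
            block = MAFFB(backbone_config.channels_at(lvl),
                          self.common_channels[lvl], rng,
                          prev_channels=prev, attention_ratio=attention_ratio)
            # named MAFFB_1..MAFFB_3 so checkpoints address individual blocks
            setattr(self, f"MAFFB_{len(self.blocks) + 1}", block)
            self.blocks.append(block)
            prev = self.common_channels[lvl]

    def forward(self, fs1: FeatureSet, fs2: FeatureSet) -> dict[int, Tensor]:
        """Common features {tap level: F_k} from two modality FeatureSets."""
        for lvl in self.tap_levels:
            if lvl not in fs1.levels or lvl not in fs2.levels:
                raise ValueError(f"missing tap level {lvl} in a FeatureSet")
        common: dict[int, Tensor] = {}
        f_prev = None
        for block, lvl in zip(self.blocks, self.tap_levels):
            if f_prev is not None:
                f_prev = avg_pool2d(f_prev, 2)
            common[lvl] = block(fs1[lvl], fs2[lvl], f_prev)
            f_prev = common[lvl]
        return common
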