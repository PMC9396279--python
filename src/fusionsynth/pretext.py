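"""Self-supervised pre-training of the per-modality backbones.

Two pretext tasks supply supervision without labels:

* **Masked inpainting** (2-D context): rectangular regions of the input
  patch are zeroed (zero is the midpoint of the [-1,1] intensity range) and
  the auto-encoder must restore the original, under the same l1 loss as
  plain reconstruction.
* **Slice-index regression** (3-D context): the network sees three adjacent
  axial slices, compressed to one channel by an extra front convolution, and
  a small branch on the decoder must regress the (normalised) index of the
  centre slice,

      L = ||x − x̂||₁ + w ||y − ŷ||₂²,

  with y = k / (depth − 1) ∈ [0,1].  Being able to localise a slice from
  content implies the encoder has captured axial anatomy.

By default both tasks are trained jointly (one optimizer, summed losses);
the front compression layer is dropped when the encoder is transferred to
the synthesis stage, which consumes single slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import UNetBackbone, reconstruction_loss
from .mri_io import PatchRecord
from .nn import Adam, Conv2d, Linear, Module, Sequential, Tensor, conv_bn_act
from .phantoms import MaskSpec, sample_masks


def mask_patch(x: np.ndarray, m: MaskSpec, fill: float = 0.0) -> np.ndarray:
    """Replace the masked pixels of a patch by ``fill``; others untouched."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-2:] != m.patch_shape:
        raise ValueError(
            f"patch spatial shape {x.shape[-2:]} != mask shape {m.patch_shape}")
    out = x.copy()
    out[..., m.combined] = fill
    return out


class TripletCompressor(Module):
    """Front convolution squeezing a 3-slice stack into one channel."""

    def __init__(self, rng: np.random.Generator, kernel_size: int = 3):
        super().__init__()
        self.conv = Conv2d(3, 1, kernel_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != 3:
            raise ValueError(f"expected 3 input slices, got {x.data.shape[1]}")
        return self.conv(x)


@dataclass(frozen=True)
class IndexBranchConfig:
    n_convs: int = 4
    hidden_channels: int = 16
    attach_level: str = "decoder_first"   # first decoder stage output


class IndexBranch(Module):
    """Slice-index regressor: 4 conv–BN–ReLU stages, global average pooling,
    one fully connected layer to a scalar."""

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 config: IndexBranchConfig = IndexBranchConfig()):
        super().__init__()
        self.config = config
        stages = []
        ch = in_channels
        for _ in range(config.n_convs):
            stages.append(conv_bn_act(ch, config.hidden_channels, rng, "relu"))
            ch = config.hidden_channels
        self.convs = Sequential(*stages)
        self.fc = Linear(ch, 1, rng)

    def forward(self, features: Tensor) -> Tensor:
        h = self.convs(features)
        pooled = h.mean(axis=(2, 3))           # global average pooling
        return self.fc(pooled)                 # (N, 1)


def _as_batch(patches: list[np.ndarray]) -> np.ndarray:
    return np.stack(patches)[:, None]          # (N,1,H,W)


def pretrain_inpainting(backbone: UNetBackbone, patches: list[np.ndarray],
                        steps: int, seed: int, batch_size: int = 8,
                        lr: float = 2e-4, n_masks: int = 4,
                        mask_size: tuple[int, int] = (32, 32)
                        ) -> list[float]:
    """Train the auto-encoder to restore masked patches; returns the loss trace."""
    if not patches:
        raise ValueError("empty inpainting dataset")
    rng = np.random.default_rng(seed)
    opt = Adam(backbone.parameters(), lr=lr)
    trace: list[float] = []
    patch_shape = patches[0].shape[-2:]
    for step in range(steps):
        idx = rng.integers(0, len(patches), size=min(batch_size, len(patches)))
        spec = sample_masks(patch_shape, n_masks=n_masks, mask_size=mask_size,
                            seed=int(rng.integers(0, 2 ** 31)))
        clean = _as_batch([patches[i] for i in idx])
        masked = mask_patch(clean, spec)
        x_hat = backbone(Tensor(masked))
        loss = reconstruction_loss(Tensor(clean), x_hat)
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return trace


def pretrain_index(backbone: UNetBackbone, compressor: TripletCompressor,
                   branch: IndexBranch,
                   triplets: list[tuple[np.ndarray, float]],
                   steps: int, seed: int, batch_size: int = 8,
                   lr: float = 2e-4, index_weight: float = 1.0
                   ) -> list[float]:
    """Joint reconstruction + index-regression training on 3-slice stacks.

    ``triplets`` pairs each (3,H,W) stack with its normalised centre index in
    [0,1].  Returns the loss trace.  With ``index_weight=0`` the objective
    reduces exactly to the plain reconstruction loss.
    """
    if not triplets:
        raise ValueError("empty triplet dataset")
    rng = np.random.default_rng(seed)
    params = (list(backbone.parameters()) + list(compressor.parameters())
              + list(branch.parameters()))
    opt = Adam(params, lr=lr)
    trace: list[float] = []
    for step in range(steps):
        idx = rng.integers(0, len(triplets), size=min(batch_size, len(triplets)))
        stacks = np.stack([triplets[i][0] for i in idx])          # (N,3,H,W)
        targets = np.array([[triplets[i][1]] for i in idx])       # (N,1)
        centre = stacks[:, 1:2]                                   # (N,1,H,W)
        x = compressor(Tensor(stacks))
        fs = backbone.encode(x)
        x_hat = backbone.decode(fs)
        y_hat = branch(backbone.decoder_features(fs))
        rec = reconstruction_loss(Tensor(centre), x_hat)
        reg = ((Tensor(targets) - y_hat) ** 2).mean()
        loss = rec + index_weight * reg
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return trace


def pretrain_joint(backbone: UNetBackbone, compressor: TripletCompressor,
                   branch: IndexBranch, patches: list[np.ndarray],
                   triplets: list[tuple[np.ndarray, float]],
                   steps: int, seed: int, batch_size: int = 8,
                   lr: float = 2e-4, n_masks: int = 4,
                   mask_size: tuple[int, int] = (32, 32),
                   index_weight: float = 1.0) -> list[float]:
    """Train both pretext tasks with one optimizer and summed losses."""
    if not patches or not triplets:
        raise ValueError("empty pretext dataset")
    rng = np.random.default_rng(seed)
    params = (list(backbone.parameters()) + list(compressor.parameters())
              + list(branch.parameters()))
    opt = Adam(params, lr=lr)
    trace: list[float] = []
    patch_shape = patches[0].shape[-2:]
    for step in range(steps):
        # inpainting half
        idx = rng.integers(0, len(patches), size=min(batch_size, len(patches)))
        spec = sample_masks(patch_shape, n_masks=n_masks, mask_size=mask_size,
                            seed=int(rng.integers(0, 2 ** 31)))
        clean = _as_batch([patches[i] for i in idx])
        x_hat = backbone(Tensor(mask_patch(clean, spec)))
        loss = reconstruction_loss(Tensor(clean), x_hat)
        # index half
        jdx = rng.integers(0, len(triplets), size=min(batch_size, len(triplets)))
        stacks = np.stack([triplets[j][0] for j in jdx])
        targets = np.array([[triplets[j][1]] for j in jdx])
        x = compressor(Tensor(stacks))
        fs = backbone.encode(x)
        loss = loss + reconstruction_loss(Tensor(stacks[:, 1:2]),
                                          backbone.decode(fs))
        y_hat = branch(backbone.decoder_features(fs))
        loss = loss + index_weight * ((Tensor(targets) - y_hat) ** 2).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return trace


def triplet_dataset(volume_patches: list[PatchRecord],
                    depth: int) -> list[tuple[np.ndarray, float]]:
    """Pair 3-slice PatchRecords with normalised centre-slice indices."""
    if depth < 3:
        raise ValueError(f"need depth >= 3, got {depth}")
    out = []
    for rec in volume_patches:
        if rec.pixels.ndim != 3 or rec.pixels.shape[0] != 3:
            raise ValueError("expected 3-slice stacks")
        out.append((rec.pixels, rec.slice_index / (depth - 1)))
    return out
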