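"""GAN-based generation: generator, dual discriminators, edge features, losses.

The generator decodes the fused common features back to the target-modality
patch.  It compresses the deepest common features with two convolutions,
then runs three further MAFFBs (decoder direction: bottleneck → full
resolution), each consuming the two modalities' unique features at that
depth plus the upsampled output of the previous stage concatenated with the
corresponding fusion-network common features, and ends with a convolution
and tanh.

Two independent discriminators critique the synthesis: a pixel-level one on
raw patches (appearance realism) and a feature-level one on Canny edge maps
(anatomical-contour consistency).  Both are five conv–BN stages with
channels 32, 64, 128, 256, 1 and strides 2, 2, 2, 2, 1 — a 128×128 input
yields an 8×8 single-channel response map — with LeakyReLU(0.2) activations
for the pixel-level network and ReLU for the feature-level one.

The training objective is

    L = L_pixel-adv + L_feature-adv + λ1 L_GRec + λ2 L_Rec

with L_GRec the l1 distance between real and synthesized patch, L_Rec the
backbones' own reconstruction loss, and the adversarial terms in the
standard minimax/non-saturating convention (real → log D, fake →
log(1 − D); the generator maximises log D on fakes).  Canny itself is not
differentiable (non-maximum suppression and hysteresis are hard decisions),
so the generator's feature-level gradient flows through a smooth Sobel
edge-magnitude surrogate; the feature-level discriminator is trained on the
hard Canny maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny as _skimage_canny

from .backbone import FeatureSet, UNetBackbone, reconstruction_loss
from .fusion import MAFFB, FusionNetwork
from .nn import (Adam, Module, Conv2d, Sequential, Tensor, concat,
                 conv_bn_act, upsample_nearest2d)


# -- discriminators ----------------------------------------------------------


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Five conv stages; the defaults are the tabulated architecture."""

    channels: tuple[int, ...] = (32, 64, 128, 256, 1)
    strides: tuple[int, ...] = (2, 2, 2, 2, 1)
    kernel_size: int = 3
    activation: str = "leaky_relu"      # pixel-level; feature-level uses relu
    leaky_slope: float = 0.2

    def __post_init__(self):
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")

    @staticmethod
    def pixel() -> "DiscriminatorConfig":
        return DiscriminatorConfig(activation="leaky_relu")

    @staticmethod
    def feature() -> "DiscriminatorConfig":
        return DiscriminatorConfig(activation="relu")

    @staticmethod
    def tiny(activation: str = "leaky_relu") -> "DiscriminatorConfig":
        return DiscriminatorConfig(channels=(8, 16, 32, 64, 1),
                                   activation=activation)


class Discriminator(Module):
    """Conv–BN–activation stack emitting an unnormalised response map.

    The map is squashed by a sigmoid inside the adversarial loss, not here.
    """

    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        super().__init__()
        self.config = config
        stages = []
        ch_in = in_channels
        for ch_out, stride in zip(config.channels, config.strides):
            stages.append(conv_bn_act(ch_in, ch_out, rng,
                                      activation=config.activation,
                                      kernel_size=config.kernel_size,
                                      stride=stride,
                                      leaky_slope=config.leaky_slope))
            ch_in = ch_out
        self.stages = Sequential(*stages)

    def forward(self, x: Tensor) -> Tensor:
        return self.stages(x)


# -- edge features -----------------------------------------------------------


def canny_features(img: np.ndarray, low: float = 0.1, high: float = 0.2,
                   sigma: float = 1.0) -> np.ndarray:
    """{0,1}-valued Canny edge map of a 2-D patch.

    The patch is min-max normalised to [0,1] first, so ``low``/``high`` act
    as relative hysteresis thresholds and the edge map is invariant to
    positive affine intensity changes.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D patch, got shape {img.shape}")
    if low >= high:
        raise ValueError(f"low threshold {low} must be < high threshold {high}")
    rng_ = img.max() - img.min()
    norm = (img - img.min()) / rng_ if rng_ > 0 else np.zeros_like(img)
    edges = _skimage_canny(norm, sigma=sigma, low_threshold=low,
                           high_threshold=high)
    return edges.astype(np.float64)


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64) / 8.0
_SOBEL_Y = _SOBEL_X.T.copy()


def soft_edge_map(x: Tensor) -> Tensor:
    """Differentiable edge-magnitude surrogate: tanh of Sobel magnitude.

    Used only on the generator's synthesis so that feature-level adversarial
    gradient can reach it; shape-preserving, values in [0, 1).
    """
    from .nn.autodiff import conv2d
    n_ch = x.data.shape[1]
    wx = Tensor(np.tile(_SOBEL_X[None, None], (n_ch, n_ch, 1, 1)) / n_ch)
    wy = Tensor(np.tile(_SOBEL_Y[None, None], (n_ch, n_ch, 1, 1)) / n_ch)
    gx = conv2d(x, wx, stride=1, padding=1)
    gy = conv2d(x, wy, stride=1, padding=1)
    return ((gx * gx + gy * gy + 1e-12).sqrt() * 4.0).tanh()


def canny_batch(batch: np.ndarray, low: float = 0.1, high: float = 0.2,
                sigma: float = 1.0) -> np.ndarray:
    """Canny maps for an (N,1,H,W) batch."""
    return np.stack([
        canny_features(batch[i, 0], low=low, high=high, sigma=sigma)
        for i in range(batch.shape[0])])[:, None]


# -- generator ---------------------------------------------------------------


class Generator(Module):
    """Feature-to-image decoder with three MAFFBs (MAFFB_4..MAFFB_6).

    Stage k runs at tap level ``taps[-k]``; the chain starts from the deepest
    common features (compressed to the smallest common width by two
    convolutions) and each later stage receives the upsampled previous output
    concatenated with the fusion network's common features at its level.
    Every component is symmetric in the two modality streams.
    """

    def __init__(self, fusion: FusionNetwork, rng: np.random.Generator,
                 attention_ratio: int = 8):
        super().__init__()
        taps = fusion.tap_levels
        cc = fusion.common_channels
        g = min(cc.values())                 # compression target width
        self.taps = taps
        self.width = g
        deep = taps[-1]
        self.compress = Sequential(
            conv_bn_act(cc[deep], g, rng, "relu"),
            conv_bn_act(g, g, rng, "relu"),
        )
        down = list(reversed(taps))          # deepest level first
        self.blocks: list[MAFFB] = []
        prev = g                             # first stage sees the compressed features
        for i, lvl in enumerate(down):
            block = MAFFB(in_channels=cc[lvl], out_channels=cc[lvl], rng=rng,
                          prev_channels=prev, attention_ratio=attention_ratio)
            setattr(self, f"MAFFB_{i + 4}", block)
            self.blocks.append(block)
            if i + 1 < len(down):
                # next stage: upsampled output ++ common features at its level
                prev = cc[lvl] + cc[down[i + 1]]
        self.out_conv = Conv2d(cc[taps[0]], 1, 3, rng)

    def forward(self, common: dict[int, Tensor], fs1: FeatureSet,
                fs2: FeatureSet) -> Tensor:
        out, _ = self.forward_collect(common, fs1, fs2)
        return out

    def forward_collect(self, common: dict[int, Tensor], fs1: FeatureSet,
                        fs2: FeatureSet) -> tuple[Tensor, dict[str, Tensor]]:
        """Forward pass that also exports each block's common features
        (keys MAFFB_4..MAFFB_6), for the interpretability analysis."""
        taps = self.taps
        down = list(reversed(taps))
        h = self.compress(common[down[0]])
        collected: dict[str, Tensor] = {}
        for i, (block, lvl) in enumerate(zip(self.blocks, down)):
            h = block(fs1[lvl], fs2[lvl], h)
            collected[f"MAFFB_{i + 4}"] = h
            if i + 1 < len(down):
                h = concat([upsample_nearest2d(h, 2), common[down[i + 1]]], axis=1)
        return self.out_conv(h).tanh(), collected


class SynthesisModel(Module):
    """Both backbones, the fusion network and the generator, end to end."""

    def __init__(self, backbone1: UNetBackbone, backbone2: UNetBackbone,
                 fusion: FusionNetwork, generator: Generator):
        super().__init__()
        self.backbone1 = backbone1
        self.backbone2 = backbone2
        self.fusion = fusion
        self.generator = generator

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        fs1 = self.backbone1.encode(x1, "source1")
        fs2 = self.backbone2.encode(x2, "source2")
        common = self.fusion(fs1, fs2)
        return self.generator(common, fs1, fs2)

    def synthesize(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        """Eval-mode synthesis on an (N,1,H,W) numpy batch."""
        was_training = self.training
        self.eval()
        out = self.forward(Tensor(x1), Tensor(x2)).data
        self.train(was_training)
        return out


# -- losses ------------------------------------------------------------------


def _softplus(x: Tensor) -> Tensor:
    # numerically stable log(1 + e^x)
    return x.relu() + ((-(x.abs())).exp() + 1.0).log()


def adversarial_d_loss(real_logits: Tensor, fake_logits: Tensor) -> Tensor:
    """Discriminator view: −E[log D(real)] − E[log(1 − D(fake))]."""
    return _softplus(-real_logits).mean() + _softplus(fake_logits).mean()


def adversarial_g_loss(fake_logits: Tensor) -> Tensor:
    """Generator view (non-saturating): −E[log D(fake)]."""
    return _softplus(-fake_logits).mean()


@dataclass
class LossReport:
    """Named loss components of one training step.

    The adversarial entries are the generator-view terms; the total follows
    total = l_pixel_adv + l_feature_adv + λ1·l_grec + λ2·l_rec.
    The discriminator-view losses are carried alongside for logging.
    """

    l_grec: float
    l_pixel_adv: float
    l_feature_adv: float
    l_rec: float
    lambda1: float
    lambda2: float
    d_pixel_loss: float = float("nan")
    d_feature_loss: float = float("nan")

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("trade-off weights must be non-negative")

    @property
    def total(self) -> float:
        return (self.l_pixel_adv + self.l_feature_adv
                + self.lambda1 * self.l_grec + self.lambda2 * self.l_rec)


def gan_losses(y: Tensor, y_hat: Tensor, d_pixel: Discriminator,
               d_feature: Discriminator, lambda1: float = 100.0,
               lambda2: float = 10.0, l_rec: Tensor | None = None
               ) -> tuple[LossReport, dict[str, Tensor]]:
    """All loss components for one (real, synthesized) batch.

    Returns the numeric report plus the differentiable generator-side and
    discriminator-side loss tensors (keys ``g_total``, ``d_pixel``,
    ``d_feature``).  The feature-level path sees only edge maps, never raw
    pixels: hard Canny maps of both images on the discriminator side, the
    smooth surrogate of the synthesis on the generator side.
    """
    if y.data.shape != y_hat.data.shape:
        raise ValueError(f"shape mismatch: {y.data.shape} vs {y_hat.data.shape}")
    l_grec = reconstruction_loss(y, y_hat)
    y_det = y_hat.detach()

    d_pix_loss = adversarial_d_loss(d_pixel(y), d_pixel(y_det))
    edges_real = Tensor(canny_batch(y.data))
    edges_fake = Tensor(canny_batch(y_det.data))
    d_feat_loss = adversarial_d_loss(d_feature(edges_real),
                                     d_feature(edges_fake))

    g_pix_adv = adversarial_g_loss(d_pixel(y_hat))
    g_feat_adv = adversarial_g_loss(d_feature(soft_edge_map(y_hat)))
    l_rec_t = l_rec if l_rec is not None else Tensor(0.0)
    g_total = (g_pix_adv + g_feat_adv + lambda1 * l_grec + lambda2 * l_rec_t)

    report = LossReport(
        l_grec=float(l_grec.data), l_pixel_adv=float(g_pix_adv.data),
        l_feature_adv=float(g_feat_adv.data), l_rec=float(l_rec_t.data),
        lambda1=lambda1, lambda2=lambda2,
        d_pixel_loss=float(d_pix_loss.data),
        d_feature_loss=float(d_feat_loss.data))
    tensors = {"g_total": g_total, "d_pixel": d_pix_loss,
               "d_feature": d_feat_loss}
    return report, tensors


@dataclass
class GANModels:
    model: SynthesisModel
    d_pixel: Discriminator
    d_feature: Discriminator


@dataclass
class GANOptimizers:
    g: Adam
    d_pixel: Adam
    d_feature: Adam

    @staticmethod
    def build(models: GANModels, lr: float = 2e-4,
              betas: tuple[float, float] = (0.5, 0.999)) -> "GANOptimizers":
        return GANOptimizers(
            g=Adam(models.model.parameters(), lr=lr, betas=betas),
            d_pixel=Adam(models.d_pixel.parameters(), lr=lr, betas=betas),
            d_feature=Adam(models.d_feature.parameters(), lr=lr, betas=betas))


def train_step(batch: tuple[np.ndarray, np.ndarray, np.ndarray],
               models: GANModels, optimizers: GANOptimizers,
               lambda1: float = 100.0, lambda2: float = 10.0) -> LossReport:
    """One alternating update: both discriminators, then the generator side.

    ``batch`` is (x1, x2, y) as (N,1,H,W) arrays in the scaled [-1,1] range.
    The generator side comprises the generator, both backbones and the
    fusion network (the backbones also reconstruct their own inputs, so the
    l_rec side-output keeps constraining them).
    """
    x1, x2, y = (Tensor(b) for b in batch)
    m = models.model

    fs1 = m.backbone1.encode(x1, "source1")
    fs2 = m.backbone2.encode(x2, "source2")
    common = m.fusion(fs1, fs2)
    y_hat = m.generator(common, fs1, fs2)
    l_rec = (reconstruction_loss(x1, m.backbone1.decode(fs1))
             + reconstruction_loss(x2, m.backbone2.decode(fs2)))

    report, tensors = gan_losses(y, y_hat, models.d_pixel, models.d_feature,
                                 lambda1=lambda1, lambda2=lambda2, l_rec=l_rec)
    if not np.isfinite(report.total):
        raise FloatingPointError(
            f"non-finite loss encountered: {report}")

    optimizers.d_pixel.zero_grad()
    tensors["d_pixel"].backward()
    optimizers.d_pixel.step()

    optimizers.d_feature.zero_grad()
    tensors["d_feature"].backward()
    optimizers.d_feature.step()

    optimizers.g.zero_grad()
    models.d_pixel.zero_grad()      # G backward also reaches D parameters;
    models.d_feature.zero_grad()    # their optimizers never see these grads
    tensors["g_total"].backward()
    optimizers.g.step()
    return report
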