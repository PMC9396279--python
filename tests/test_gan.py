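"""Generator wiring, discriminator contracts, Canny features, GAN losses."""

import numpy as np
import pytest
from skimage.feature import canny as skimage_canny

from fusionsynth.gan import (Discriminator, DiscriminatorConfig, GANModels,
                             GANOptimizers, LossReport, SynthesisModel,
                             adversarial_d_loss, canny_features, gan_losses,
                             train_step)
from fusionsynth.nn import Tensor
from fusionsynth.nn.layers import BatchNorm2d, Conv2d, LeakyReLU, ReLU


class TestDiscriminatorContract:
    @pytest.mark.parametrize("factory,act", [
        (DiscriminatorConfig.pixel, LeakyReLU),
        (DiscriminatorConfig.feature, ReLU),
    ])
    def test_five_stages_with_tabulated_channels_strides_activations(
            self, factory, act):
        cfg = factory()
        d = Discriminator(cfg, np.random.default_rng(0))
        stages = list(d.stages)
        assert len(stages) == 5
        for stage, ch, stride in zip(stages, (32, 64, 128, 256, 1),
                                     (2, 2, 2, 2, 1)):
            conv = stage[0]
            assert isinstance(conv, Conv2d)
            assert conv.out_channels == ch and conv.stride == stride
            assert conv.kernel_size == 3
            assert isinstance(stage[1], BatchNorm2d)
            assert isinstance(stage[2], act)
            if isinstance(stage[2], LeakyReLU):
                assert stage[2].slope == 0.2

    def test_128_input_yields_8x8_single_channel_map(self):
        for cfg in (DiscriminatorConfig.pixel(), DiscriminatorConfig.feature()):
            d = Discriminator(cfg, np.random.default_rng(1)).eval()
            out = d(Tensor(np.random.default_rng(2).normal(size=(1, 1, 128, 128))))
            assert out.data.shape == (1, 1, 8, 8)


class TestGenerator:
    def test_output_matches_input_patch_shape(self, micro_models):
        m = micro_models.model
        for size in (32, 64):
            x = np.random.default_rng(0).normal(size=(1, 1, size, size))
            assert m.synthesize(x, x).shape == (1, 1, size, size)

    def test_single_modal_mode_duplicates_one_input(self, micro_models):
        # both feature streams fed the same image: the wiring must accept it
        m = micro_models.model
        x = np.tanh(np.random.default_rng(1).normal(size=(2, 1, 32, 32)))
        out = m.synthesize(x, x)
        assert out.shape == x.shape and np.isfinite(out).all()

    def test_swapping_source_streams_is_bit_identical(self, micro_models):
        m = micro_models.model.eval()
        rng = np.random.default_rng(2)
        x1 = Tensor(rng.normal(size=(1, 1, 32, 32)))
        x2 = Tensor(rng.normal(size=(1, 1, 32, 32)))
        fs1 = m.backbone1.encode(x1)
        fs2 = m.backbone2.encode(x2)
        a = m.generator(m.fusion(fs1, fs2), fs1, fs2).data
        b = m.generator(m.fusion(fs2, fs1), fs2, fs1).data
        assert np.array_equal(a, b)

    def test_output_lies_in_scaled_range(self, micro_models):
        x = np.random.default_rng(3).normal(size=(1, 1, 32, 32)) * 5
        out = micro_models.model.synthesize(x, x)
        assert (out >= -1).all() and (out <= 1).all()


class TestCanny:
    def test_zero_image_has_no_edges(self):
        assert canny_features(np.zeros((32, 32))).max() == 0.0

    def test_filled_square_gives_closed_contour(self):
        img = np.zeros((64, 64))
        img[20:44, 20:44] = 1.0
        edges = canny_features(img, sigma=1.0)
        reference = skimage_canny(img, sigma=1.0, low_threshold=0.1,
                                  high_threshold=0.2).astype(float)
        np.testing.assert_array_equal(edges, reference)
        assert edges.sum() > 0
        # all edge pixels hug the square boundary (within NMS discretisation)
        rr, cc = np.nonzero(edges)
        on_boundary = ((np.isclose(rr, 20, atol=2) | np.isclose(rr, 43, atol=2))
                       | (np.isclose(cc, 20, atol=2) | np.isclose(cc, 43, atol=2)))
        assert on_boundary.all()

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(5)
        img = rng.random((48, 48))
        base = canny_features(img)
        np.testing.assert_array_equal(base, canny_features(3.0 * img + 10.0))

    def test_bad_thresholds_raise(self):
        with pytest.raises(ValueError):
            canny_features(np.zeros((8, 8)), low=0.5, high=0.2)


class _ConstantLogitD:
    """Stub discriminator answering a fixed logit everywhere."""

    def __init__(self, logit=0.0):
        self.logit = logit

    def __call__(self, x):
        return Tensor(np.full((x.data.shape[0], 1, 2, 2), self.logit))


class TestLosses:
    def test_identical_pair_zeroes_reconstruction_term(self, micro_models):
        y = Tensor(np.tanh(np.random.default_rng(0).normal(size=(1, 1, 32, 32))))
        rep, _ = gan_losses(y, Tensor(y.data.copy()), micro_models.d_pixel,
                            micro_models.d_feature)
        assert rep.l_grec == 0.0

    def test_half_probability_discriminator_loss_value(self):
        # with D = 0.5 everywhere, each adversarial discriminator loss is
        # -log(0.5) - log(1 - 0.5) = 2 log 2 per sample
        d = _ConstantLogitD(0.0)
        y = Tensor(np.zeros((3, 1, 8, 8)))
        loss = adversarial_d_loss(d(y), d(y))
        assert abs(float(loss.data) - 2 * np.log(2)) < 1e-12

    def test_total_additivity(self, micro_models):
        rng = np.random.default_rng(1)
        y = Tensor(np.tanh(rng.normal(size=(2, 1, 32, 32))))
        y_hat = Tensor(np.tanh(rng.normal(size=(2, 1, 32, 32))))
        for l1, l2 in ((0.0, 0.0), (100.0, 10.0), (7.0, 0.5)):
            rep, _ = gan_losses(y, y_hat, micro_models.d_pixel,
                                micro_models.d_feature, lambda1=l1, lambda2=l2,
                                l_rec=Tensor(0.37))
            expect = rep.l_pixel_adv + rep.l_feature_adv \
                + l1 * rep.l_grec + l2 * rep.l_rec
            assert abs(rep.total - expect) < 1e-12

    def test_zero_weights_reduce_to_adversarial_terms(self, micro_models):
        rng = np.random.default_rng(2)
        y = Tensor(np.tanh(rng.normal(size=(1, 1, 32, 32))))
        y_hat = Tensor(np.tanh(rng.normal(size=(1, 1, 32, 32))))
        rep, _ = gan_losses(y, y_hat, micro_models.d_pixel,
                            micro_models.d_feature, lambda1=0.0, lambda2=0.0)
        assert rep.total == rep.l_pixel_adv + rep.l_feature_adv

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossReport(l_grec=0, l_pixel_adv=0, l_feature_adv=0, l_rec=0,
                       lambda1=-1.0, lambda2=0.0)

    def test_feature_discriminator_sees_only_edge_maps(self, micro_models,
                                                       monkeypatch):
        # interface assertion: every array entering d_feature on the
        # discriminator side is a {0,1}-valued Canny map
        seen = []
        original = micro_models.d_feature.forward

        def spy(x):
            seen.append(x.data.copy())
            return original(x)

        monkeypatch.setattr(micro_models.d_feature, "forward", spy)
        rng = np.random.default_rng(3)
        y = Tensor(np.tanh(rng.normal(size=(1, 1, 32, 32))))
        y_hat = Tensor(np.tanh(rng.normal(size=(1, 1, 32, 32))))
        gan_losses(y, y_hat, micro_models.d_pixel, micro_models.d_feature)
        assert len(seen) == 3           # real edges, fake edges, soft surrogate
        for arr in seen[:2]:
            assert set(np.unique(arr)) <= {0.0, 1.0}


class TestTrainStep:
    @pytest.fixture
    def batch(self):
        rng = np.random.default_rng(7)
        mk = lambda: np.tanh(rng.normal(size=(2, 1, 32, 32)))
        return mk(), mk(), mk()

    def test_zero_learning_rate_leaves_parameters_bit_identical(
            self, micro_models, batch):
        opts = GANOptimizers.build(micro_models, lr=0.0)
        before = {
            "g": micro_models.model.state_dict(),
            "dp": micro_models.d_pixel.state_dict(),
            "df": micro_models.d_feature.state_dict()}
        micro_models.model.eval()       # freeze BN running stats too
        micro_models.d_pixel.eval()
        micro_models.d_feature.eval()
        train_step(batch, micro_models, opts)
        assert all(np.array_equal(v, micro_models.model.state_dict()[k])
                   for k, v in before["g"].items())
        assert all(np.array_equal(v, micro_models.d_pixel.state_dict()[k])
                   for k, v in before["dp"].items())

    def test_discriminator_and_generator_updates_are_isolated(
            self, micro_models, batch):
        opts = GANOptimizers.build(micro_models, lr=1e-3)
        opts.g.lr = 0.0                 # only discriminators step
        g_before = {k: v.copy() for k, v
                    in micro_models.model.state_dict().items()
                    if "running" not in k}
        d_before = {k: v.copy() for k, v
                    in micro_models.d_pixel.state_dict().items()
                    if "running" not in k}
        train_step(batch, micro_models, opts)
        g_after = micro_models.model.state_dict()
        assert all(np.array_equal(v, g_after[k]) for k, v in g_before.items())
        d_after = micro_models.d_pixel.state_dict()
        assert any(not np.array_equal(v, d_after[k])
                   for k, v in d_before.items())

    def test_loss_report_components_are_finite(self, micro_models, batch):
        opts = GANOptimizers.build(micro_models, lr=1e-4)
        rep = train_step(batch, micro_models, opts)
        for v in (rep.l_grec, rep.l_pixel_adv, rep.l_feature_adv, rep.l_rec,
                  rep.d_pixel_loss, rep.d_feature_loss, rep.total):
            assert np.isfinite(v)
        assert rep.l_grec >= 0 and rep.l_rec >= 0
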