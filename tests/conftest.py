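import numpy as np
import pytest

from fusionsynth.backbone import BackboneConfig, UNetBackbone
from fusionsynth.fusion import FusionNetwork
from fusionsynth.gan import (Discriminator, DiscriminatorConfig, GANModels,
                             Generator, SynthesisModel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def micro_config():
    """Smallest usable backbone: base width 4, two pooling stages."""
    return BackboneConfig(base_channels=4)


@pytest.fixture
def micro_backbone(micro_config):
    return UNetBackbone(micro_config, np.random.default_rng(7))


@pytest.fixture
def micro_models(micro_config):
    """A complete synthesis model + discriminators at micro scale."""
    r = np.random.default_rng(11)
    b1 = UNetBackbone(micro_config, r)
    b2 = UNetBackbone(micro_config, r)
    fusion = FusionNetwork(micro_config, r)
    gen = Generator(fusion, r)
    d_pix = Discriminator(DiscriminatorConfig.tiny("leaky_relu"), r)
    d_feat = Discriminator(DiscriminatorConfig.tiny("relu"), r)
    return GANModels(model=SynthesisModel(b1, b2, fusion, gen),
                     d_pixel=d_pix, d_feature=d_feat)
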