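"""GAN construction, initialization scheme, training contracts, checkpoints."""

import numpy as np
import pytest

from ganscreen import nn
from ganscreen.errors import ConfigurationError, ValidationError
from ganscreen.gan import (GanConfig, build_models, discriminate, generate,
                           init_weights, load_checkpoint, save_checkpoint,
                           train_gan)
from ganscreen.synthetic import PhantomSpec, ViewLabel, generate_dataset


def tiny_config(**kw):
    base = dict(latent_dim=16, resolution=16, base_feature_maps=8,
                batch_size=4, train_steps=3, seed=3)
    base.update(kw)
    return GanConfig(**base)


@pytest.fixture(scope="module")
def tiny_models():
    return build_models(tiny_config())


class TestBuild:
    def test_shape_contract(self):
        m = build_models(GanConfig(latent_dim=100, resolution=64,
                                   base_feature_maps=8, seed=0))
        z = np.random.default_rng(0).standard_normal(100)
        img = generate(m, z)
        assert img.pixels.shape == (64, 64)
        assert img.pixels.min() > -1.0 and img.pixels.max() < 1.0

    def test_discriminator_sigmoid_codomain(self, tiny_models):
        out = discriminate(tiny_models, np.zeros((1, 1, 16, 16)))
        assert out.shape == (1,)
        assert 0.0 < out[0] < 1.0

    def test_same_seed_identical_parameters(self):
        a, b = build_models(tiny_config()), build_models(tiny_config())
        for k, arr in a.generator_params.items():
            assert np.array_equal(arr, b.generator_params[k])
        for k, arr in a.discriminator_params.items():
            assert np.array_equal(arr, b.discriminator_params[k])

    def test_unsupported_resolution_rejected(self):
        with pytest.raises(ConfigurationError, match="resolution"):
            build_models(tiny_config(resolution=48))

    def test_bad_hyperparameters_rejected(self):
        with pytest.raises(ValidationError):
            build_models(tiny_config(learning_rate=0.0))
        with pytest.raises(ValidationError):
            build_models(tiny_config(beta1=1.5))


class TestInitWeights:
    def test_initialization_scheme_statistics(self):
        # large build for tight sampling distributions
        m = build_models(GanConfig(latent_dim=64, resolution=32,
                                   base_feature_maps=32, seed=5))
        conv_w = np.concatenate([
            layer.params["w"].ravel()
            for net in (m.generator, m.discriminator)
            for layer in net.layers
            if isinstance(layer, (nn.Conv2d, nn.ConvTranspose2d))])
        n = conv_w.size
        assert abs(conv_w.mean()) < 3 * 0.02 / np.sqrt(n)
        # sample std of a normal has SE ~ sigma/sqrt(2n); 10% is generous
        assert abs(conv_w.std() - 0.02) < 0.1 * 0.02
        for net in (m.generator, m.discriminator):
            for layer in net.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    assert np.all(layer.params["beta"] == 0.0)
                    gam = layer.params["gamma"]
                    assert abs(gam.mean() - 1.0) < 0.05

    def test_reinit_seed_determinism(self, tiny_models):
        a = build_models(tiny_config())
        init_weights(a, seed=99)
        b = build_models(tiny_config())
        init_weights(b, seed=99)
        for k, arr in a.generator_params.items():
            assert np.array_equal(arr, b.generator_params[k])


class TestGenerate:
    def test_deterministic(self, tiny_models):
        z = np.random.default_rng(1).standard_normal(16)
        assert np.array_equal(generate(tiny_models, z).pixels,
                              generate(tiny_models, z).pixels)

    def test_wrong_latent_length(self, tiny_models):
        with pytest.raises(ValidationError, match="latent"):
            generate(tiny_models, np.zeros(7))

    def test_continuity_under_small_perturbation(self, tiny_models):
        z = np.random.default_rng(2).standard_normal(16)
        z2 = z.copy()
        z2[0] += 1e-4
        delta = np.abs(generate(tiny_models, z).pixels
                       - generate(tiny_models, z2).pixels).max()
        assert delta < 1e-2


@pytest.fixture(scope="module")
def phantoms():
    return generate_dataset(24, 0, PhantomSpec(ViewLabel.FRONTAL, 16), 4)


class TestTrain:
    def test_zero_steps_identity(self, phantoms):
        cfg = tiny_config(train_steps=0)
        m = build_models(cfg)
        before = {k: v.copy() for k, v in m.generator_params.items()}
        m, trace = train_gan(m, phantoms, cfg)
        assert trace.generator_loss == [] and trace.discriminator_loss == []
        for k, arr in m.generator_params.items():
            assert np.array_equal(arr, before[k])

    def test_losses_finite_and_lengths(self, phantoms):
        cfg = tiny_config(train_steps=5)
        m, trace = train_gan(build_models(cfg), phantoms, cfg)
        assert len(trace.generator_loss) == len(trace.discriminator_loss) == 5
        assert np.all(np.isfinite(trace.generator_loss))
        assert np.all(np.isfinite(trace.discriminator_loss))

    def test_training_bitwise_reproducible(self, phantoms):
        cfg = tiny_config(train_steps=4)
        m1, t1 = train_gan(build_models(cfg), phantoms, cfg)
        m2, t2 = train_gan(build_models(cfg), phantoms, cfg)
        assert t1.generator_loss == t2.generator_loss
        for k, arr in m1.generator_params.items():
            assert np.array_equal(arr, m2.generator_params[k])

    def test_empty_images_rejected(self):
        cfg = tiny_config()
        with pytest.raises(ValidationError):
            train_gan(build_models(cfg), [], cfg)

    def test_resolution_mismatch_rejected(self):
        cfg = tiny_config()
        wrong = generate_dataset(2, 0, PhantomSpec(ViewLabel.FRONTAL, 32), 0)
        with pytest.raises(ValidationError):
            train_gan(build_models(cfg), wrong, cfg)


def test_checkpoint_roundtrip(tmp_path):
    cfg = tiny_config(train_steps=2)
    imgs = generate_dataset(8, 0, PhantomSpec(ViewLabel.FRONTAL, 16), 4)
    m, _ = train_gan(build_models(cfg), imgs, cfg)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(m, path, 2)
    m2 = load_checkpoint(path)
    assert m2.config == cfg
    for k, arr in m.generator_params.items():
        assert np.array_equal(arr, m2.generator_params[k])
    z = np.random.default_rng(0).standard_normal(16)
    assert np.array_equal(generate(m, z).pixels, generate(m2, z).pixels)
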