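"""Generator contracts: shapes, ranges, conditioning, the excitation module."""

import numpy as np
import pytest

import spectgan as sg
from spectgan.generator import NetworkError, sample_latent
from spectgan.nn import Tensor

SMALL = sg.GeneratorConfig(base_channels=16, seed=0)
SMALL_B = sg.GeneratorConfig(variant=sg.Variant.B, base_channels=16, seed=0)


@pytest.fixture(scope="module")
def gen():
    return sg.build_generator(SMALL)


class TestBuild:
    def test_embedding_input_dimension_variant_a(self, gen):
        assert gen.embed.weight.shape[0] == 256 + 6

    def test_embedding_input_dimension_variant_b(self):
        g = sg.build_generator(SMALL_B)
        assert g.embed.weight.shape[0] == 256 + 3

    def test_embedding_width(self, gen):
        assert gen.embed.weight.shape[1] == 64

    def test_single_excitation_module(self, gen):
        from spectgan.generator import SkipLayerExcitation

        sles = [v for v in vars(gen).values() if isinstance(v, SkipLayerExcitation)]
        assert len(sles) == 1

    def test_seeded_build_reproducible(self):
        a = sg.build_generator(SMALL)
        b = sg.build_generator(SMALL)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)


class TestGenerate:
    def test_output_shape_and_open_range(self, gen, rng):
        y = sg.encode_condition(sg.Level.COR, sg.Pattern.NORMAL, sg.Variant.A)
        img = sg.generate(gen, rng.normal(size=256), y)
        assert img.shape == (64, 64)
        assert np.all(img > -1.0) and np.all(img < 1.0)

    def test_deterministic_for_fixed_inputs(self, gen, rng):
        y = sg.encode_condition(sg.Level.BG, sg.Pattern.BILATERAL, sg.Variant.A)
        z = rng.normal(size=256)
        assert np.array_equal(sg.generate(gen, z, y), sg.generate(gen, z, y))

    def test_distinct_latents_give_distinct_images(self, gen, rng):
        y = sg.encode_condition(sg.Level.CER, sg.Pattern.NORMAL, sg.Variant.A)
        a = sg.generate(gen, rng.normal(size=256), y)
        b = sg.generate(gen, rng.normal(size=256), y)
        assert not np.array_equal(a, b)

    def test_condition_changes_output(self, gen, rng):
        z = rng.normal(size=256)
        a = sg.generate(
            gen, z, sg.encode_condition(sg.Level.COR, sg.Pattern.NORMAL, sg.Variant.A)
        )
        b = sg.generate(
            gen,
            z,
            sg.encode_condition(sg.Level.COR, sg.Pattern.BILATERAL, sg.Variant.A),
        )
        assert not np.array_equal(a, b)

    def test_variant_mismatch_rejected(self, gen, rng):
        y = sg.encode_condition(sg.Level.COR, sg.Pattern.NORMAL, sg.Variant.B)
        with pytest.raises(NetworkError, match="variant"):
            sg.generate(gen, rng.normal(size=256), y)

    def test_latent_dimension_mismatch_rejected(self, gen, rng):
        y = sg.encode_condition(sg.Level.COR, sg.Pattern.NORMAL, sg.Variant.A)
        with pytest.raises(NetworkError, match="latent"):
            sg.generate(gen, rng.normal(size=100), y)

    def test_unit_rescale_bounds(self, gen, rng):
        imgs = sg.sample_images(gen, sg.Level.COR, sg.Pattern.NORMAL, 3, rng)
        assert imgs.shape == (3, 64, 64)
        assert imgs.max() <= 1.0 and imgs.min() >= 0.0


class TestSkipLayerExcitation:
    def test_zero_high_res_stays_zero(self, rng):
        sle = sg.SkipLayerExcitation(4, 8, low_size=8, rng=rng)
        low = Tensor(rng.normal(size=(2, 4, 8, 8)))
        high = Tensor(np.zeros((2, 8, 32, 32)))
        assert np.allclose(sle(low, high).data, 0.0)

    def test_output_shape_matches_high_res(self, rng):
        sle = sg.SkipLayerExcitation(4, 8, low_size=8, rng=rng)
        low = Tensor(rng.normal(size=(2, 4, 8, 8)))
        high = Tensor(rng.normal(size=(2, 8, 32, 32)))
        assert sle(low, high).shape == high.shape

    def test_gate_bounded_by_sigmoid(self, rng):
        sle = sg.SkipLayerExcitation(4, 8, low_size=8, rng=rng)
        low = Tensor(rng.normal(size=(1, 4, 8, 8)))
        high = Tensor(np.ones((1, 8, 32, 32)))
        out = sle(low, high).data
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_channel_mismatch_rejected(self, rng):
        sle = sg.SkipLayerExcitation(4, 8, low_size=8, rng=rng)
        low = Tensor(rng.normal(size=(1, 4, 8, 8)))
        high = Tensor(rng.normal(size=(1, 5, 32, 32)))
        with pytest.raises(NetworkError, match="channels"):
            sle(low, high)


def test_adversarial_gradient_reaches_generator(rng):
    """The generator loss produces nonzero gradients on generator weights."""
    g = sg.build_generator(SMALL)
    d = sg.build_discriminator(sg.DiscriminatorConfig(base_channels=4, seed=1))
    y = sg.encode_condition(sg.Level.COR, sg.Pattern.NORMAL, sg.Variant.A)
    yb = np.tile(y.as_array(), (2, 1))
    cond = np.stack([sg.condition_image(y, 64, 64)] * 2)
    fake = g(sample_latent(2, rng), yb)
    logits, _, _ = d(fake, cond)
    loss = sg.loss_generator(logits)
    loss.backward()
    norms = [0.0 if p.grad is None else float(np.abs(p.grad).max()) for p in g.parameters()]
    assert max(norms) > 0.0
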