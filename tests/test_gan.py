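"""Generator/discriminator contracts: shapes, ranges, wiring, gradients."""

import numpy as np
import pytest

from egan3d.autodiff import Tensor
from egan3d.config import make_config
from egan3d.gan import discriminate, edge_channel, generator_forward
from egan3d.trainer import build_models
from egan3d.volume import Volume

EXTENT = 8


@pytest.fixture(scope="module")
def models():
    cfg = make_config(
        "desk", extent=EXTENT, branch_channels=2, channels_2d=4,
        decoder_channels=(4, 4, 2), disc_channels=(4, 8),
    )
    return build_models(cfg, np.random.default_rng(42))


def _pet_volume(rng, extent=EXTENT):
    data = rng.uniform(-1, 1, size=(extent,) * 3)
    data.flat[0], data.flat[1] = -1.0, 1.0
    return Volume(data)


class TestGenerator:
    def test_output_shape_and_range(self, models, rng):
        gen, _ = models
        out = generator_forward(_pet_volume(rng), gen)
        assert out.shape == (EXTENT,) * 3
        assert out.data.min() > -1.0 and out.data.max() < 1.0

    def test_eval_mode_deterministic(self, models, rng):
        gen, _ = models
        pet = _pet_volume(rng)
        a = generator_forward(pet, gen)
        b = generator_forward(pet, gen)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_weights_give_tanh_zero(self, rng):
        cfg = make_config("desk", extent=EXTENT, branch_channels=2, channels_2d=4,
                          decoder_channels=(4, 4, 2), disc_channels=(4, 8))
        gen, _ = build_models(cfg, np.random.default_rng(0))
        for p in gen.parameters():
            p.data[...] = 0.0
        out = generator_forward(_pet_volume(rng), gen)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_unpreprocessed_range_rejected(self, models, rng):
        gen, _ = models
        bad = Volume(rng.uniform(0, 100, size=(EXTENT,) * 3))
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            generator_forward(bad, gen)

    def test_sobel_ablation_changes_output(self, rng):
        """The edge channel must actually be wired into the decoder."""
        cfg = make_config("desk", extent=EXTENT, branch_channels=2, channels_2d=4,
                          decoder_channels=(4, 4, 2), disc_channels=(4, 8))
        gen, _ = build_models(cfg, np.random.default_rng(7))
        pet = _pet_volume(rng)
        full = generator_forward(pet, gen)
        gen.use_sobel = False
        ablated = generator_forward(pet, gen)
        gen.use_sobel = True
        assert not np.allclose(full.data, ablated.data)

    def test_decoder_input_assembly(self, models, rng):
        gen, _ = models
        n = 2
        fused = Tensor(rng.normal(size=(n, EXTENT, EXTENT)).astype(np.float32))
        edges = Tensor(rng.uniform(0, 1, size=(n, 1) + (EXTENT,) * 3).astype(np.float32))
        out = gen.assemble_decoder_input(fused, edges)
        assert out.shape == (n, 2) + (EXTENT,) * 3
        # channel 1 is the fused map tiled along the axial axis
        for k in range(EXTENT):
            np.testing.assert_allclose(out.data[:, 0, :, :, k], fused.data, atol=1e-7)

    def test_zero_fused_map_zero_channel(self, models):
        gen, _ = models
        fused = Tensor(np.zeros((1, EXTENT, EXTENT), dtype=np.float32))
        edges = Tensor(np.zeros((1, 1) + (EXTENT,) * 3, dtype=np.float32))
        out = gen.assemble_decoder_input(fused, edges)
        np.testing.assert_array_equal(out.data[:, 0], 0.0)


class TestDiscriminator:
    def test_probability_range_and_determinism(self, models, rng):
        _, disc = models
        pet, mri = _pet_volume(rng), _pet_volume(rng)
        p1 = discriminate(pet, mri, disc)
        p2 = discriminate(pet, mri, disc)
        assert 0.0 < p1 < 1.0
        assert p1 == p2

    def test_zero_weights_half(self, rng):
        cfg = make_config("desk", extent=EXTENT, branch_channels=2, channels_2d=4,
                          decoder_channels=(4, 4, 2), disc_channels=(4, 8))
        _, disc = build_models(cfg, np.random.default_rng(0))
        for p in disc.parameters():
            p.data[...] = 0.0
        assert discriminate(_pet_volume(rng), _pet_volume(rng), disc) == pytest.approx(0.5)

    def test_shape_mismatch(self, models):
        _, disc = models
        a = Tensor(np.zeros((1, 1, 8, 8, 8), dtype=np.float32))
        b = Tensor(np.zeros((1, 1, 8, 8, 6), dtype=np.float32))
        with pytest.raises(ValueError):
            disc(a, b)


class TestEndToEndGradients:
    def test_all_parameters_receive_gradient(self, rng):
        """No detached subgraph: one hybrid-loss backward pass reaches every
        generator parameter, and the discriminator loss every disc parameter."""
        from egan3d.losses import adversarial_losses, l2_loss

        cfg = make_config("desk", extent=EXTENT, branch_channels=2, channels_2d=4,
                          decoder_channels=(4, 4, 2), disc_channels=(4, 8))
        gen, disc = build_models(cfg, np.random.default_rng(3))
        x = rng.uniform(-1, 1, size=(2, 1) + (EXTENT,) * 3).astype(np.float32)
        mri = rng.uniform(-1, 1, size=(2, 1) + (EXTENT,) * 3).astype(np.float32)
        pet, edges = Tensor(x), Tensor(edge_channel(x))
        fake = gen(pet, edges)
        d_fake = disc(pet, fake)
        _, adv = adversarial_losses(Tensor(np.ones(1)), d_fake)
        hybrid = adv + 0.5 * l2_loss(fake, Tensor(mri))
        hybrid.backward()
        for name, p in gen.named_parameters().items():
            assert p.grad is not None and np.any(p.grad != 0), f"dead generator param {name}"
        gen.zero_grad()
        disc.zero_grad()
        d_real = disc(pet, Tensor(mri))
        d_fake2 = disc(pet, fake.detach())
        loss_d, _ = adversarial_losses(d_real, d_fake2)
        loss_d.backward()
        for name, p in disc.named_parameters().items():
            assert p.grad is not None and np.any(p.grad != 0), f"dead disc param {name}"
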