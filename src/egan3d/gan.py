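"""Generator and conditional discriminator of the translation GAN.

The generator is encoder + decoder.  The Elicit encoder collapses the
PET volume to three view feature maps which are fused into one c x c
map ``l`` (see :mod:`egan3d.encoder`).  The decoder input has two
channels on the full volume grid:

1. ``l`` tiled along the axial axis (the minimal 2D->3D bridge), and
2. the Sobel gradient-magnitude field of the PET, passed through a
   learnable 3x3x3 convolution that fixes the scale of the edges.

Four 3x3x3 convolutions (BatchNorm + LeakyReLU(0.2) between them, tanh
at the end) decode the MRI in [-1, 1].  An ablation switch zeroes the
edge channel so the contribution of the geometric pathway can be
measured.

The discriminator is a 3D fully-convolutional classifier over the
(PET, MRI) pair stacked as two channels: strided 4x4x4 convolutions
with LeakyReLU, a 1x1x1 projection, global average and a sigmoid, so it
outputs one probability per pair, conditioned on the PET.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, concat
from .encoder import ElicitEncoder, EncoderConfig, fuse_triple
from .sobel3d import apply_sobel
from .volume import Volume

RANGE_TOL = 1e-3


class Generator(nn.Module):
    """PET -> MRI translator (Elicit encoder, edge channel, 3D decoder)."""

    def __init__(
        self,
        cfg: EncoderConfig,
        rng: np.random.Generator,
        decoder_channels: tuple[int, ...] = (64, 32, 16),
        std: float = nn.INIT_STD,
        use_sobel: bool = True,
    ):
        super().__init__()
        self.cfg = cfg
        self.use_sobel = use_sobel
        self.encoder = ElicitEncoder(cfg, rng, std=std)
        self.post_sobel = nn.Conv3d(1, 1, 3, rng, padding=1, std=std)
        chans = (2, *decoder_channels, 1)
        self.decoder_convs = [
            nn.Conv3d(chans[i], chans[i + 1], 3, rng, padding=1, std=std)
            for i in range(len(chans) - 1)
        ]
        self.decoder_bns = [nn.BatchNorm3d(c) for c in chans[1:-1]]

    def assemble_decoder_input(self, fused_l: Tensor, edges: Tensor) -> Tensor:
        """Build the two-channel decoder input on the volume grid.

        ``fused_l``: [N, c, c] fusion map; ``edges``: [N, 1, D, H, W]
        Sobel magnitude.  Channel 1 tiles the fusion map along the axial
        axis; channel 2 is the edge field after the learnable post-Sobel
        convolution (zeroed under ablation).
        """
        e = self.cfg.volume_extent
        n = fused_l.shape[0]
        if fused_l.shape[1] != e:
            raise ValueError(
                f"fused map side {fused_l.shape[1]} != volume extent {e} (tile mode)"
            )
        ch1 = fused_l.reshape((n, 1, e, e, 1)).broadcast_to((n, 1, e, e, e))
        if self.use_sobel:
            ch2 = self.post_sobel(edges)
        else:  # ablation: the geometric channel is identically zero
            ch2 = Tensor(np.zeros((n, 1, e, e, e), dtype=edges.dtype))
        return concat([ch1, ch2], axis=1)

    def __call__(self, pet: Tensor, edges: Tensor) -> Tensor:
        """``pet``, ``edges``: [N, 1, D, H, W] -> generated MRI, same grid."""
        maps = self.encoder(pet)
        fused = fuse_triple(*maps, eps=self.cfg.eps)
        h = self.assemble_decoder_input(fused.l, edges)
        for i, conv in enumerate(self.decoder_convs[:-1]):
            h = self.decoder_bns[i](conv(h)).leaky_relu()
        return self.decoder_convs[-1](h).tanh()


class Discriminator(nn.Module):
    """Conditional 3D fully-convolutional real/fake classifier."""

    def __init__(
        self,
        rng: np.random.Generator,
        channels: tuple[int, ...] = (64, 128, 256),
        std: float = nn.INIT_STD,
    ):
        super().__init__()
        chans = (2, *channels)
        self.convs = [
            nn.Conv3d(chans[i], chans[i + 1], 4, rng, stride=2, padding=1, std=std)
            for i in range(len(chans) - 1)
        ]
        self.head = nn.Conv3d(chans[-1], 1, 1, rng, std=std)

    def __call__(self, pet: Tensor, mri: Tensor) -> Tensor:
        """Probability (0, 1) that ``mri`` is the real pair of ``pet``; [N]."""
        if pet.shape != mri.shape:
            raise ValueError(f"shape mismatch: {pet.shape} vs {mri.shape}")
        h = concat([pet, mri], axis=1)
        for conv in self.convs:
            h = conv(h).leaky_relu()
        logits = self.head(h).mean(axis=(1, 2, 3, 4))
        return logits.sigmoid()


def _check_range(data: np.ndarray, name: str):
    lo, hi = float(data.min()), float(data.max())
    if lo < -1 - RANGE_TOL or hi > 1 + RANGE_TOL:
        raise ValueError(
            f"{name} must be preprocessed to [-1, 1]; range is [{lo:.3g}, {hi:.3g}]"
        )


def edge_channel(pet_batch: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude per batch item, [N,1,D,H,W] -> same shape."""
    return np.stack(
        [apply_sobel(p[0])[None] for p in pet_batch], axis=0
    ).astype(pet_batch.dtype)


def generator_forward(pet: Volume, gen: Generator) -> Volume:
    """Translate one preprocessed PET volume (eval mode, deterministic)."""
    _check_range(pet.data, "PET input")
    was_training = gen.training
    gen.eval()
    try:
        x = pet.data[None, None].astype(nn.DTYPE)
        out = gen(Tensor(x), Tensor(edge_channel(x)))
    finally:
        gen.train(was_training)
    return Volume(out.data[0, 0].astype(np.float64), pet.affine.copy())


def discriminate(pet: Volume, mri: Volume, disc: Discriminator) -> float:
    """Probability that (pet, mri) is a real pair (eval mode)."""
    was_training = disc.training
    disc.eval()
    try:
        p = Tensor(pet.data[None, None].astype(nn.DTYPE))
        m = Tensor(mri.data[None, None].astype(nn.DTYPE))
        out = disc(p, m)
    finally:
        disc.train(was_training)
    return float(out.data[0])
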