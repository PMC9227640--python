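"""The Elicit encoder: per-view separable convolutions and tanh fusion.

A 3D PET volume is collapsed to three 2D feature maps, one per
anatomical view (sagittal = axis 0, coronal = axis 1, axial = axis 2).
Each view runs two parallel separable-convolution branches along its
axis:

* a *long-range* branch whose 1D kernel spans the full axis extent
  (e.g. 90 voxels), collapsing the axis in one step;
* a *local* branch whose kernel spans half the extent (e.g. 45) with
  stride equal to the kernel, producing two block responses that a
  second length-2 kernel collapses.

Branch outputs are concatenated as channels of an in-plane map and two
3x3 2D convolutions reduce them to a single c x c feature map per view
(c equals the in-plane extent).  LeakyReLU(0.2) follows every
convolution except the last.

The three maps are fused pairwise by a tanh-normalised Hadamard
product, a self-attention-like mixing without learned projections:

    g(i,j) = tanh(x(i,j) * yT(i,j)) / sum_i' tanh(x(i',j) * yT(i',j))

then the axial map joins the same way, l = fuse(g, zT).  Each column of
g and l sums to 1 whenever its normaliser is well-conditioned; a signed
epsilon keeps the division finite when the tanh terms cancel.  Note the
fusion is *not* scale invariant: the tanh saturates, so doubling the
inputs changes the output (unlike a softmax attention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concat
from .volume import Volume

DEFAULT_EPS = 1e-8


@dataclass
class EncoderConfig:
    """Shape configuration of the Elicit encoder.

    ``long_kernel`` must equal ``volume_extent`` (it collapses the whole
    axis); ``local_kernel`` must divide it.  ``c`` is the side of the
    output feature maps and equals the in-plane extent for this
    architecture.
    """

    volume_extent: int = 90
    long_kernel: int = 90
    local_kernel: int = 45
    branch_channels: int = 4
    channels_2d: int = 8
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        if self.long_kernel != self.volume_extent:
            raise ValueError("long_kernel must equal volume_extent")
        if self.local_kernel > self.volume_extent or self.volume_extent % self.local_kernel:
            raise ValueError("local_kernel must divide volume_extent")
        if self.volume_extent < 2:
            raise ValueError("volume_extent must be >= 2")

    @property
    def c(self) -> int:
        return self.volume_extent


@dataclass
class ViewFeatureMaps:
    """The (sagittal, coronal, axial) triple of c x c feature maps."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray


@dataclass
class FusedMap:
    """Two-view fusion ``g`` and the full three-view fusion ``l``."""

    g: np.ndarray
    l: np.ndarray


def _transpose_last2(t: Tensor) -> Tensor:
    axes = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return t.transpose(axes)


def fuse_pair(x, y, eps: float = DEFAULT_EPS):
    """Tanh-normalised Hadamard fusion of two square maps.

    Accepts numpy arrays or Tensors (``[..., c, c]``); returns the same
    kind.  Columns of the result sum to ~1 when the column normaliser is
    well away from zero.
    """
    as_array = not isinstance(x, Tensor)
    xt = Tensor(np.asarray(x, dtype=float)) if as_array else x
    yt = Tensor(np.asarray(y, dtype=float)) if as_array else y
    if xt.shape != yt.shape or xt.shape[-1] != xt.shape[-2]:
        raise ValueError(f"fuse_pair needs equal square maps, got {xt.shape} vs {yt.shape}")
    t = (xt * _transpose_last2(yt)).tanh()
    denom = t.sum(axis=-2, keepdims=True)
    sign = np.where(denom.data >= 0, 1.0, -1.0).astype(denom.dtype)
    g = t / (denom + Tensor(eps * sign))
    return g.data if as_array else g


def fuse_triple(x, y, z, eps: float = DEFAULT_EPS) -> FusedMap:
    """Fuse three view maps: g = fuse(x, y), then l = fuse(g, z)."""
    as_array = not isinstance(x, Tensor)
    g = fuse_pair(x, y, eps)
    l = fuse_pair(g if not as_array else g, z, eps)
    if as_array:
        return FusedMap(g=np.asarray(g), l=np.asarray(l))
    return FusedMap(g=g, l=l)


class ElicitEncoder(nn.Module):
    """Separable-convolution per-view encoder producing three c x c maps."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 std: float = nn.INIT_STD):
        super().__init__()
        self.cfg = cfg
        ch = cfg.branch_channels
        nb = cfg.volume_extent // cfg.local_kernel
        self.long_convs = [nn.AxisConv(1, ch, cfg.long_kernel, rng, std) for _ in range(3)]
        self.local_convs = [nn.AxisConv(1, ch, cfg.local_kernel, rng, std) for _ in range(3)]
        self.block_convs = [nn.AxisConv(ch, ch, nb, rng, std) for _ in range(3)]
        self.conv2d_a = [nn.Conv2d(2 * ch, cfg.channels_2d, 3, rng, padding=1, std=std)
                         for _ in range(3)]
        self.conv2d_b = [nn.Conv2d(cfg.channels_2d, 1, 3, rng, padding=1, std=std)
                         for _ in range(3)]

    def _encode_view(self, x: Tensor, axis: int) -> Tensor:
        # long-range branch: one full-extent kernel collapses the axis
        a = self.long_convs[axis](x, axis=axis, collapse=True).leaky_relu()
        # local branch: half-extent blocks, then collapse the block axis
        b = self.local_convs[axis](x, axis=axis, collapse=False).leaky_relu()
        b = self.block_convs[axis](b, axis=axis, collapse=True).leaky_relu()
        m = concat([a, b], axis=1)
        m = self.conv2d_a[axis](m).leaky_relu()
        m = self.conv2d_b[axis](m)  # [N, 1, c, c]
        n = m.shape[0]
        return m.reshape((n, m.shape[2], m.shape[3]))

    def __call__(self, vol: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """``vol``: [N, 1, D, H, W] -> three [N, c, c] view maps."""
        e = self.cfg.volume_extent
        if vol.shape[2:] != (e, e, e):
            raise ValueError(f"expected {(e, e, e)} volume, got {vol.shape[2:]}")
        return tuple(self._encode_view(vol, ax) for ax in range(3))


def encode_views(v: Volume, encoder: ElicitEncoder) -> ViewFeatureMaps:
    """Run the encoder on one volume, returning plain-array view maps."""
    x = Tensor(v.data[None, None].astype(nn.DTYPE))
    mx, my, mz = encoder(x)
    return ViewFeatureMaps(x=mx.data[0], y=my.data[0], z=mz.data[0])
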