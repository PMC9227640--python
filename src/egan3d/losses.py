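"""Adversarial, L2 and hybrid objectives, plus Jensen-Shannon divergence.

The adversarial game is the standard conditional-GAN min-max: the
discriminator maximises  E log D(p, m) + E log(1 - D(p, G(p)));  at the
optimal discriminator this objective equals 2*JSD(p_g || p_r) - 2 ln 2,
so minimising it drives the generated distribution toward the real one
in Jensen-Shannon divergence.  The generator uses the non-saturating
form -log D(p, G(p)), which keeps gradients alive when the
discriminator wins early (the saturation problem).

The full training objective weights the adversarial and voxelwise terms

    alpha1 * L_GAN + alpha2 * L2,     defaults alpha1 = 1, alpha2 = 0.5.

L2 is the *mean* squared voxel difference, so alpha2 does not depend on
the volume resolution.  ``jsd`` is exposed as a monitoring metric over
discretised intensity histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

LOG_EPS = 1e-7


@dataclass
class LossWeights:
    """Weights of the hybrid objective (adversarial, L2)."""

    alpha1: float = 1.0
    alpha2: float = 0.5

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0 or (self.alpha1 == 0 and self.alpha2 == 0):
            raise ValueError("weights must be >= 0 and not both zero")


def _clamp(t: Tensor) -> Tensor:
    # keep probabilities away from {0, 1} before the log
    data = np.clip(t.data, LOG_EPS, 1.0 - LOG_EPS)
    out = Tensor(data, requires_grad=t.requires_grad)
    if t.requires_grad:
        inside = (t.data > LOG_EPS) & (t.data < 1.0 - LOG_EPS)

        def backward(g):
            t._accum(np.where(inside, g, 0.0))

        out._prev = (t,)
        out._backward = backward
    return out


def adversarial_losses(d_real, d_fake) -> tuple:
    """Discriminator and (non-saturating) generator losses from D outputs.

    Accepts floats, arrays or Tensors of probabilities in (0, 1); both
    losses are means over the batch.  Returns ``(loss_D, loss_G)``.
    """
    dr = d_real if isinstance(d_real, Tensor) else Tensor(np.atleast_1d(np.asarray(d_real, float)))
    df = d_fake if isinstance(d_fake, Tensor) else Tensor(np.atleast_1d(np.asarray(d_fake, float)))
    dr, df = _clamp(dr), _clamp(df)
    loss_d = -(dr.log().mean() + (1.0 - df).log().mean())
    loss_g = -(df.log().mean())
    if isinstance(d_real, Tensor) or isinstance(d_fake, Tensor):
        return loss_d, loss_g
    return float(loss_d.data), float(loss_g.data)


def saturating_generator_loss(d_fake) -> Tensor:
    """The original minimax generator term  log(1 - D(p, G(p)))  (mean).

    Kept for the loss-variant ablation; it saturates when D is strong.
    """
    df = d_fake if isinstance(d_fake, Tensor) else Tensor(np.atleast_1d(np.asarray(d_fake, float)))
    out = _clamp(1.0 - df).log().mean()
    return out if isinstance(d_fake, Tensor) else float(out.data)


def l2_loss(gen, real):
    """Mean squared voxelwise difference (resolution independent)."""
    g_t = gen if isinstance(gen, Tensor) else Tensor(np.asarray(gen, float))
    r_t = real if isinstance(real, Tensor) else Tensor(np.asarray(real, float))
    if g_t.shape != r_t.shape:
        raise ValueError(f"shape mismatch: {g_t.shape} vs {r_t.shape}")
    out = ((g_t - r_t) ** 2).mean()
    return out if isinstance(gen, Tensor) else float(out.data)


def hybrid_loss(loss_gan, loss_l2, w: LossWeights = LossWeights()):
    """alpha1 * adversarial + alpha2 * L2."""
    return w.alpha1 * loss_gan + w.alpha2 * loss_l2


def _validate_dist(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be a vector")
    if np.any(p < 0):
        raise ValueError(f"{name} has negative mass")
    s = p.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        raise ValueError(f"{name} must sum to 1, got {s}")
    return p / s


def kl_divergence(p, q) -> float:
    """KL(p || q) in nats, with the 0 log 0 = 0 convention."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def jsd(p, q) -> float:
    """Jensen-Shannon divergence in nats: symmetric, in [0, ln 2].

    JSD(p || q) = KL(p || m)/2 + KL(q || m)/2  with  m = (p + q)/2.
    """
    p = _validate_dist(p, "p")
    q = _validate_dist(q, "q")
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    m = 0.5 * (p + q)
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


def intensity_histogram(data: np.ndarray, bins: int = 64,
                        value_range=(-1.0, 1.0)) -> np.ndarray:
    """Normalised intensity histogram, for JSD monitoring between volumes."""
    h, _ = np.histogram(np.asarray(data).ravel(), bins=bins, range=value_range)
    h = h.astype(float)
    return h / h.sum()
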