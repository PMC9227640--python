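"""Intensity and geometric preprocessing.

The translation network expects both modalities on a common cubic grid
with intensities in [-1, 1].  PET additionally gets a global-mean
intensity normalisation (each voxel divided by the volume mean), the
standard way of removing the arbitrary scanner/dose scale from uptake
images before any cross-subject learning.

Order of operations: PET — global-mean normalise, resize, rescale to
[-1, 1]; MRI — resize, rescale.  Resizing is anti-aliased (Gaussian
prefilter matched to the downscale factor, then linear interpolation).
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .volume import PairedSample, Volume


class DegenerateInputError(ValueError):
    """Raised for inputs whose preprocessing is ill-defined (e.g. constants)."""


def intensity_normalize_pet(v: Volume) -> Volume:
    """Divide every voxel by the global mean intensity.

    Postcondition: the returned volume has mean 1 (to ~1e-6 relative),
    which makes the op idempotent.
    """
    mu = float(v.data.mean())
    if mu <= 0:
        raise DegenerateInputError(f"global mean must be positive, got {mu}")
    return v.with_data(v.data / mu)


def rescale_to_range(v: Volume, lo: float = -1.0, hi: float = 1.0) -> Volume:
    """Affine intensity map onto [lo, hi] (monotone, exact at the extremes)."""
    vmin = float(v.data.min())
    vmax = float(v.data.max())
    if vmax <= vmin:
        raise DegenerateInputError("constant volume cannot be rescaled to a range")
    out = (v.data - vmin) * ((hi - lo) / (vmax - vmin)) + lo
    return v.with_data(out)


def resize_antialias(
    v: Volume,
    target_shape: tuple[int, int, int] = (90, 90, 90),
    allow_upsample: bool = False,
) -> Volume:
    """Resize to ``target_shape`` with Gaussian anti-aliasing.

    Constant volumes pass through exactly; an identity target returns a
    copy.  Upsampling is refused unless ``allow_upsample`` is set, since
    the pipeline is designed as a down-sizing step.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 3 for t in target_shape):
        raise ValueError(f"target dims must be >= 3, got {target_shape}")
    if not allow_upsample and any(t > s for t, s in zip(target_shape, v.shape)):
        raise ValueError(
            f"upsampling {v.shape} -> {target_shape} requested but not allowed"
        )
    if target_shape == v.shape:
        return v.with_data(v.data.copy())
    ptp = float(v.data.max() - v.data.min())
    if ptp == 0.0:  # interpolation of a constant is that constant
        out = np.full(target_shape, v.data.flat[0], dtype=v.data.dtype)
    else:
        out = _sk_resize(
            v.data,
            target_shape,
            order=1,
            anti_aliasing=True,
            mode="reflect",
            preserve_range=True,
        )
    # update the affine scale so world extent is preserved
    aff = v.affine.copy()
    scale = np.array(v.shape, dtype=float) / np.array(target_shape, dtype=float)
    aff[:3, :3] = aff[:3, :3] @ np.diag(scale)
    return Volume(out, aff)


def preprocess_pet(v: Volume, target_shape=(90, 90, 90)) -> Volume:
    """Full PET chain: global-mean normalise -> resize -> [-1, 1]."""
    v = intensity_normalize_pet(v)
    if v.shape != tuple(target_shape):
        v = resize_antialias(v, target_shape)
    return rescale_to_range(v)


def preprocess_mri(v: Volume, target_shape=(90, 90, 90)) -> Volume:
    """Full MRI chain: resize -> [-1, 1] (no global-mean step)."""
    if v.shape != tuple(target_shape):
        v = resize_antialias(v, target_shape)
    return rescale_to_range(v)


def preprocess_pair(pair: PairedSample, target_shape=(90, 90, 90)) -> PairedSample:
    return PairedSample(
        pet=preprocess_pet(pair.pet, target_shape),
        mri=preprocess_mri(pair.mri, target_shape),
        subject_id=pair.subject_id,
    )
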