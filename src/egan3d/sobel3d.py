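"""Fixed 3x3x3 Sobel kernels and the 3D gradient-magnitude edge channel.

The 3D Sobel kernel for derivative axis a is the separable outer product
of the smoothing stencil [1, 2, 1] on the two transverse axes with the
central-difference stencil [1, 0, -1] on axis a.  For the z axis this
gives the three slices

    K[:, :, 0] = [[1,2,1],[2,4,2],[1,2,1]]      (offset -1)
    K[:, :, 1] = 0                               (offset  0)
    K[:, :, 2] = -K[:, :, 0]                     (offset +1)

and the x/y kernels are axis permutations of the same construction.
The edge channel of the generator is the per-voxel gradient magnitude
sqrt(Gx^2 + Gy^2 + Gz^2) with reflective border handling, so the output
grid matches the input and a locally constant region maps to zero.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import Volume

_AXES = {"x": 0, "y": 1, "z": 2}
_SMOOTH = np.array([1, 2, 1])
_DERIV = np.array([1, 0, -1])


def sobel_kernel(axis: str) -> np.ndarray:
    """Return the signed integer 3x3x3 Sobel kernel for ``axis`` in {x,y,z}.

    Entries sum to zero; the kernel is antisymmetric along its derivative
    axis and symmetric along the two smoothing axes.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    a = _AXES[axis]
    stencils = [_SMOOTH, _SMOOTH, _SMOOTH]
    stencils[a] = _DERIV
    k = np.einsum("i,j,k->ijk", *stencils)
    return k.astype(np.int64)


def directional_response(v: Volume | np.ndarray, axis: str) -> np.ndarray:
    """Cross-correlation of the volume with one Sobel kernel (reflect borders)."""
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=float)
    return ndimage.correlate(data.astype(float), sobel_kernel(axis).astype(float),
                             mode="reflect")


def apply_sobel(v: Volume | np.ndarray) -> Volume | np.ndarray:
    """3D Sobel gradient magnitude of a volume (the geometric edge channel)."""
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=float)
    if any(s < 3 for s in data.shape):
        raise ValueError(f"volume must be at least 3x3x3, got {data.shape}")
    gx = directional_response(data, "x")
    gy = directional_response(data, "y")
    gz = directional_response(data, "z")
    mag = np.sqrt(gx * gx + gy * gy + gz * gz)
    return Volume(mag, v.affine.copy()) if isinstance(v, Volume) else mag
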