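"""Intrinsic evaluation: image-quality metrics, 3D texture, tissue means.

Quality metrics between a generated and a reference volume:

* PSNR  = 10 log10(data_range^2 / MSE), infinite for identical inputs;
* SSIM  — windowed structural similarity with a 3D Gaussian window
  (delegated to scikit-image);
* MAE   — mean absolute voxel difference;
* normalized cross-correlation — zero-mean Pearson correlation over all
  voxels, in [-1, 1].

Texture is summarised by a grey-level co-occurrence matrix (GLCM)
computed in 3D: intensities are discretised into ``levels`` equal-width
bins over the volume's [min, max], and voxel pairs separated by
``distance`` steps along an ``offset`` direction are accumulated
symmetrically.  Haralick features (energy, homogeneity, dissimilarity,
contrast) follow from the normalised matrix.  The single-direction
60-degree in-plane offset used for texture figures is available, and a
13-direction 3D average is the default for summary tables.

Tissue analysis clusters intensities into three classes (CSF-like,
GM-like, WM-like, ordered by mean) with k-means and compares per-class
mean voxel values between generated and real volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity
from sklearn.cluster import KMeans

from .volume import Volume


def _data(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v, dtype=float)


def _check_same_shape(a: np.ndarray, b: np.ndarray):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclass
class MetricsReport:
    """PSNR (dB), SSIM, MAE and normalised cross-correlation for one pair."""

    psnr: float
    ssim: float
    mae: float
    xcorr: float

    def as_dict(self) -> dict:
        return {"psnr": self.psnr, "ssim": self.ssim, "mae": self.mae, "xcorr": self.xcorr}


def psnr(a, b, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical inputs."""
    a, b = _data(a), _data(b)
    _check_same_shape(a, b)
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(a, b, data_range: float = 1.0) -> float:
    """Mean structural similarity with a 3D Gaussian window (sigma 1.5)."""
    a, b = _data(a), _data(b)
    _check_same_shape(a, b)
    return float(
        structural_similarity(
            a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
    )


def mae(a, b) -> float:
    """Mean absolute voxelwise error."""
    a, b = _data(a), _data(b)
    _check_same_shape(a, b)
    return float(np.mean(np.abs(a - b)))


def norm_xcorr(a, b) -> float:
    """Zero-mean normalised (Pearson) cross-correlation over all voxels."""
    a, b = _data(a), _data(b)
    _check_same_shape(a, b)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        raise ValueError("zero-variance input has no defined correlation")
    return float((ac * bc).sum() / denom)


def metrics_report(gen, real, data_range: float = 1.0) -> MetricsReport:
    """All four quality metrics, computed on a common intensity scale."""
    return MetricsReport(
        psnr=psnr(gen, real, data_range),
        ssim=ssim(gen, real, data_range),
        mae=mae(gen, real),
        xcorr=norm_xcorr(gen, real),
    )


# ---------------------------------------------------------------------------
# GLCM / Haralick texture
# ---------------------------------------------------------------------------

#: offset for the in-plane 60-degree direction at distance 3:
#: round(3 * (cos 60, sin 60, 0)) = (2, 3, 0)
OFFSET_60_DEG = (2, 3, 0)

#: the 13 unique nearest-neighbour directions of the 3D lattice
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass
class GLCMatrix:
    """A symmetric grey-level co-occurrence matrix and its provenance."""

    levels: int
    offset: tuple[int, int, int]
    counts: np.ndarray
    normalized: np.ndarray


@dataclass
class HaralickFeatures:
    energy: float
    homogeneity: float
    dissimilarity: float
    contrast: float

    def as_dict(self) -> dict:
        return {
            "energy": self.energy, "homogeneity": self.homogeneity,
            "dissimilarity": self.dissimilarity, "contrast": self.contrast,
        }


def quantize(data: np.ndarray, levels: int = 8) -> np.ndarray:
    """Equal-width discretisation of [min, max] into ``levels`` bins."""
    data = np.asarray(data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros(data.shape, dtype=np.int64)
    q = np.floor((data - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm_3d(
    v,
    levels: int = 8,
    distance: int = 3,
    direction: tuple[int, int, int] = (1, 0, 0),
    _quantized: np.ndarray | None = None,
) -> GLCMatrix:
    """3D grey-level co-occurrence matrix at one offset.

    The offset is ``distance * direction`` rounded to lattice steps; the
    pair (i, j) and its reverse are both accumulated (symmetric GLCM),
    and counts are normalised by the total number of pairs.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    direction = tuple(int(round(d)) for d in direction)
    if all(d == 0 for d in direction):
        raise ValueError("direction must be a nonzero lattice vector")
    data = _data(v)
    offset = tuple(distance * d for d in direction)
    if any(abs(o) >= s for o, s in zip(offset, data.shape)):
        raise ValueError(f"offset {offset} does not fit in volume {data.shape}")
    q = quantize(data, levels) if _quantized is None else _quantized

    # two views shifted by the offset
    src_sl, dst_sl = [], []
    for o in offset:
        if o >= 0:
            src_sl.append(slice(0, data.shape[len(src_sl)] - o))
            dst_sl.append(slice(o, data.shape[len(dst_sl)]))
        else:
            src_sl.append(slice(-o, data.shape[len(src_sl)]))
            dst_sl.append(slice(0, data.shape[len(dst_sl)] + o))
    i = q[tuple(src_sl)].ravel()
    j = q[tuple(dst_sl)].ravel()
    counts = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    counts = counts + counts.T  # symmetric accumulation
    total = counts.sum()
    return GLCMatrix(
        levels=levels, offset=offset, counts=counts,
        normalized=counts.astype(float) / total,
    )


def glcm_3d_average(v, levels: int = 8, distance: int = 3,
                    directions=DIRECTIONS_13) -> GLCMatrix:
    """Mean normalised GLCM over a set of directions (summary default)."""
    data = _data(v)
    q = quantize(data, levels)
    mats = [glcm_3d(data, levels, distance, d, _quantized=q) for d in directions]
    counts = np.sum([m.counts for m in mats], axis=0)
    norm = np.mean([m.normalized for m in mats], axis=0)
    return GLCMatrix(levels=levels, offset=(0, 0, 0), counts=counts, normalized=norm)


def haralick(m: GLCMatrix) -> HaralickFeatures:
    """Energy, homogeneity, dissimilarity and contrast of a GLCM."""
    p = np.asarray(m.normalized, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"GLCM must be normalised (sum={p.sum()})")
    idx = np.arange(p.shape[0])
    di = idx[:, None] - idx[None, :]
    return HaralickFeatures(
        energy=float(np.sum(p**2)),
        homogeneity=float(np.sum(p / (1.0 + di**2))),
        dissimilarity=float(np.sum(np.abs(di) * p)),
        contrast=float(np.sum(di**2 * p)),
    )


# ---------------------------------------------------------------------------
# tissue analysis
# ---------------------------------------------------------------------------

def segment_three_class(v, seed: int = 0, mask: np.ndarray | None = None) -> np.ndarray:
    """Three-class intensity clustering (0 = CSF-like, 1 = GM-like, 2 = WM-like).

    K-means on voxel intensities with labels reordered by ascending
    class mean; deterministic under ``seed``.  With ``mask`` given (a
    boolean head/brain mask), only masked voxels are clustered and
    voxels outside receive label -1; without it the air background joins
    the darkest class.  This is a simple intensity-only stand-in for a
    full tissue segmentation pipeline.
    """
    data = _data(v)
    if mask is None:
        sel = np.ones(data.shape, dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool)
        _check_same_shape(data, sel)
    vals = data[sel].reshape(-1, 1)
    if np.unique(vals).size < 3:
        raise ValueError("need at least 3 distinct intensities to form 3 classes")
    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    raw = km.fit_predict(vals)
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(3, dtype=np.int64)
    remap[order] = np.arange(3)
    out = np.full(data.shape, -1, dtype=np.int64)
    out[sel] = remap[raw]
    return out


def tissue_mean_report(gen, real, labels) -> dict[int, dict]:
    """Per-class mean voxel value in the generated and real volumes.

    Returns ``{class: {"gen_mean", "real_mean", "count"}}``; an empty
    class is flagged with count 0 and NaN means.
    """
    g, r = _data(gen), _data(real)
    lab = np.asarray(_data(labels)).astype(np.int64)
    _check_same_shape(g, r)
    _check_same_shape(g, lab)
    out: dict[int, dict] = {}
    for cls in sorted(np.unique(lab)):
        mask = lab == cls
        n = int(mask.sum())
        out[int(cls)] = {
            "gen_mean": float(g[mask].mean()) if n else float("nan"),
            "real_mean": float(r[mask].mean()) if n else float("nan"),
            "count": n,
        }
    return out
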