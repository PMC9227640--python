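"""Paired pseudo-PET / pseudo-MRI head phantoms.

Each phantom is a nested-ellipsoid "head": an outer CSF shell, a
grey-matter shell and a white-matter core, with per-subject random axis
lengths and rotation.  The pseudo-MRI assigns each tissue its T1-like
intensity (CSF < GM < WM) plus Gaussian noise.  The pseudo-PET applies
a grey-matter-dominated uptake weighting to the same label map
(GM > WM > CSF, mimicking FDG metabolism), then Gaussian smoothing
(the scanner's limited resolution / partial-volume blur) and noise.

Geometry is physical: the field of view is fixed at 180 mm (a 90-voxel
grid at 2 mm spacing), so voxel size is ``180 / extent`` mm and the
scanner point-spread function is given in mm (``smoothing_fwhm_mm``,
default 6 mm FWHM, a typical clinical PET resolution) and converted to
voxels per grid.  Shrinking the extent therefore coarsens the sampling
without changing the simulated physics.

Both volumes share one geometry, so the pairs are perfectly
co-registered, the tissue ground truth is exact, and the PET -> MRI
mapping is learnable at desk scale: the translator has to undo the
tissue re-weighting and re-sharpen boundaries — exactly the job the
edge channel exists for.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import PairedSample, Volume

CSF, GM, WM = 1, 2, 3  # label values; 0 = background

FOV_MM = 180.0  # fixed head field of view; 90 voxels at 2 mm
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Generative settings for one phantom cohort.

    ``tissue_intensities`` are MRI-like means for (CSF, GM, WM) and must
    increase; ``pet_weights`` are uptake factors for the same triple and
    must be GM-dominant (GM > WM > CSF).  ``smoothing_fwhm_mm`` is the
    PET point-spread FWHM in mm; ``noise_sigma`` is in intensity units.
    """

    extent: int = 32
    tissue_intensities: tuple[float, float, float] = (0.25, 0.55, 0.9)
    pet_weights: tuple[float, float, float] = (0.15, 1.0, 0.45)
    smoothing_fwhm_mm: float = 6.0
    noise_sigma: float = 0.03
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self):
        c, g, w = self.tissue_intensities
        if not (c < g < w):
            raise ValueError("tissue intensities must increase CSF < GM < WM")
        pc, pg, pw = self.pet_weights
        if not (pg > pw > pc):
            raise ValueError("PET weights must be GM-dominant (GM > WM > CSF)")
        if self.smoothing_fwhm_mm < 0 or self.noise_sigma < 0:
            raise ValueError("smoothing/noise parameters must be >= 0")
        if self.extent < 12:
            raise ValueError("extent must be >= 12")

    @property
    def voxel_size_mm(self) -> float:
        return FOV_MM / self.extent

    @property
    def smoothing_sigma(self) -> float:
        """PSF standard deviation in voxels on this grid."""
        return self.smoothing_fwhm_mm * FWHM_TO_SIGMA / self.voxel_size_mm


def _ellipsoid_mask(extent: int, radii: np.ndarray, rot: np.ndarray) -> np.ndarray:
    half = (extent - 1) / 2.0
    coords = np.stack(
        np.meshgrid(*([np.arange(extent) - half] * 3), indexing="ij"), axis=-1
    )
    local = coords @ rot  # rotate the lattice into the ellipsoid frame
    return (np.sum((local / radii) ** 2, axis=-1) <= 1.0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_label_map(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Nested-ellipsoid tissue label map (0 bg, 1 CSF, 2 GM, 3 WM)."""
    e = spec.extent
    for _ in range(spec.max_retries):
        base = rng.uniform(0.36, 0.46) * e  # outer semi-axis, voxels
        outer = base * rng.uniform(0.88, 1.0, size=3)
        gm = outer - rng.uniform(1.0, 1.0 + 0.04 * e)  # CSF shell thickness
        wm = gm - rng.uniform(1.2, 1.2 + 0.06 * e)  # GM shell thickness
        # nested if the core keeps a usable size on every axis
        if np.all(wm >= 1.2):
            rot = _random_rotation(rng)
            labels = np.zeros((e, e, e), dtype=np.int8)
            labels[_ellipsoid_mask(e, outer, rot)] = CSF
            labels[_ellipsoid_mask(e, gm, rot)] = GM
            labels[_ellipsoid_mask(e, wm, rot)] = WM
            if (labels == GM).any() and (labels == WM).any() and (labels == CSF).any():
                return labels
    raise RuntimeError("could not sample nested shells within the retry limit")


def make_paired_phantom(spec: PhantomSpec) -> tuple[PairedSample, Volume]:
    """One (pseudo-PET, pseudo-MRI) pair plus its tissue label map.

    Deterministic in ``spec.seed``.  With both sigmas zero, the PET is an
    exact per-tissue intensity remap of the label map.
    """
    rng = np.random.default_rng(spec.seed)
    labels = make_label_map(spec, rng)

    mri = np.zeros(labels.shape, dtype=np.float64)
    pet = np.zeros(labels.shape, dtype=np.float64)
    for lab, (t1, uptake) in enumerate(
        zip((0.0,) + tuple(spec.tissue_intensities), (0.0,) + tuple(spec.pet_weights))
    ):
        mask = labels == lab
        mri[mask] = t1
        pet[mask] = uptake

    if spec.smoothing_sigma > 0:
        pet = ndimage.gaussian_filter(pet, spec.smoothing_sigma)
    if spec.noise_sigma > 0:
        mri = mri + rng.normal(0.0, spec.noise_sigma, mri.shape)
        pet = pet + rng.normal(0.0, spec.noise_sigma, pet.shape)
        mri = np.clip(mri, 0.0, None)
        pet = np.clip(pet, 0.0, None)

    vs = spec.voxel_size_mm  # 2 mm at the reference 90-voxel grid
    affine = np.diag([vs, vs, vs, 1.0])
    pair = PairedSample(
        pet=Volume(pet, affine.copy()),
        mri=Volume(mri, affine.copy()),
        subject_id=f"phantom-{spec.seed:05d}",
    )
    return pair, Volume(labels.astype(np.float64), affine.copy())


@dataclass
class PhantomDataset:
    pairs: list[PairedSample]
    labels: list[Volume]
    manifest: "object" = None  # pandas DataFrame when written to disk


def make_dataset(
    n: int,
    spec: PhantomSpec,
    out_dir: str | Path | None = None,
) -> PhantomDataset:
    """Generate ``n`` pairs with seeds ``spec.seed .. spec.seed + n - 1``.

    With ``out_dir`` set, writes NIfTI files plus a TSV manifest
    (subject_id, pet_path, mri_path) that round-trips through
    :func:`egan3d.volume.load_pairs`.
    """
    import pandas as pd

    from .volume import save_volume

    if n < 1:
        raise ValueError("n must be >= 1")
    pairs, labels, rows = [], [], []
    for i in range(n):
        sub = PhantomSpec(**{**spec.__dict__, "seed": spec.seed + i})
        pair, lab = make_paired_phantom(sub)
        pairs.append(pair)
        labels.append(lab)
        rows.append(pair.subject_id)

    manifest = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records = []
        for pair in pairs:
            pet_p = out / f"{pair.subject_id}_pet.nii.gz"
            mri_p = out / f"{pair.subject_id}_mri.nii.gz"
            if pet_p.exists() or mri_p.exists():
                raise FileExistsError(f"refusing to overwrite {pet_p} / {mri_p}")
            save_volume(pair.pet, pet_p)
            save_volume(pair.mri, mri_p)
            records.append(
                {"subject_id": pair.subject_id, "pet_path": pet_p.name, "mri_path": mri_p.name}
            )
        manifest = pd.DataFrame.from_records(records)
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return PhantomDataset(pairs=pairs, labels=labels, manifest=manifest)
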