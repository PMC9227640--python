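"""Volumes, paired samples, NIfTI I/O and dataset manifests.

A :class:`Volume` is the universal currency of the package: a 3D scalar
grid with its affine.  Loading goes through nibabel and reorients to RAS
(so axis 0 = sagittal/x, axis 1 = coronal/y, axis 2 = axial/z — the
convention the per-view encoder relies on), widens to floating point and
validates finiteness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class VolumeValidationError(ValueError):
    """Raised when a volume violates a structural contract."""


@dataclass
class Volume:
    """3D scalar grid with spatial metadata.

    Parameters
    ----------
    data : ndarray
        3D floating-point intensity grid.
    affine : ndarray, optional
        4x4 voxel-to-world transform; identity if omitted.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeValidationError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if any(s < 3 for s in self.data.shape):
            raise VolumeValidationError(
                f"all dimensions must be >= 3, got shape {self.data.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if bad:
            raise VolumeValidationError(f"volume contains {bad} non-finite voxels")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing in mm, from the affine column norms."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.affine.copy())


@dataclass
class PairedSample:
    """A co-registered (PET, MRI) pair for one subject."""

    pet: Volume
    mri: Volume
    subject_id: str = ""

    def __post_init__(self):
        if self.pet.shape != self.mri.shape:
            raise VolumeValidationError(
                f"PET shape {self.pet.shape} != MRI shape {self.mri.shape}"
            )
        if not np.allclose(self.pet.affine, self.mri.affine, atol=1e-4):
            raise VolumeValidationError("PET and MRI affines differ beyond tolerance")


def load_volume(path: str | Path) -> Volume:
    """Load a NIfTI volume, reorient to RAS, and validate it.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`VolumeValidationError` for non-3D images or non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeValidationError(f"{path.name}: expected 3D image, got {img.ndim}D")
    img = nib.as_closest_canonical(img)  # RAS orientation
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if not np.all(np.isfinite(data)):
        bad = int(data.size - np.isfinite(data).sum())
        raise VolumeValidationError(f"{path.name}: {bad} non-finite voxels")
    return Volume(data, img.affine)


def save_volume(v: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(v.data, v.affine), str(path))
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest (CSV/TSV: subject_id, pet_path, mri_path)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    missing = {"subject_id", "pet_path", "mri_path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_pairs(manifest: str | Path) -> list[PairedSample]:
    """Load all pairs listed in a manifest; paths relative to the manifest."""
    mpath = Path(manifest)
    df = read_manifest(mpath)
    pairs = []
    for row in df.itertuples(index=False):
        pet = load_volume(_resolve(row.pet_path, mpath.parent))
        mri = load_volume(_resolve(row.mri_path, mpath.parent))
        pairs.append(PairedSample(pet=pet, mri=mri, subject_id=str(row.subject_id)))
    return pairs


def _resolve(p: str, base: Path) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p
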