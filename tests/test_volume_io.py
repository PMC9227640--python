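"""NIfTI round-trips, validation, and the preprocessing chain."""

import nibabel as nib
import numpy as np
import pytest

from egan3d.preprocess import (
    DegenerateInputError,
    intensity_normalize_pet,
    preprocess_pair,
    rescale_to_range,
    resize_antialias,
)
from egan3d.volume import (
    PairedSample,
    Volume,
    VolumeValidationError,
    load_pairs,
    load_volume,
    save_volume,
)


class TestVolumeIO:
    def test_write_read_round_trip(self, tmp_path, random_volume):
        v = random_volume((8, 9, 10))
        p = save_volume(v, tmp_path / "vol.nii.gz")
        back = load_volume(p)
        np.testing.assert_array_equal(back.data, v.data)
        np.testing.assert_allclose(back.affine, v.affine)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "nope.nii.gz")

    def test_4d_image_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 2)), np.eye(4))
        nib.save(img, str(tmp_path / "vol4d.nii.gz"))
        with pytest.raises(VolumeValidationError, match="3D"):
            load_volume(tmp_path / "vol4d.nii.gz")

    def test_nan_voxels_rejected_with_count(self, tmp_path):
        data = np.ones((5, 5, 5))
        data[0, 0, 0] = np.nan
        data[1, 2, 3] = np.nan
        data[4, 4, 4] = np.inf
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "bad.nii.gz"))
        with pytest.raises(VolumeValidationError, match="3 non-finite"):
            load_volume(tmp_path / "bad.nii.gz")

    def test_small_dimension_rejected(self):
        with pytest.raises(VolumeValidationError):
            Volume(np.zeros((2, 5, 5)))

    def test_pair_shape_mismatch(self):
        with pytest.raises(VolumeValidationError):
            PairedSample(pet=Volume(np.zeros((4, 4, 4))), mri=Volume(np.zeros((5, 4, 4))))


class TestPetNormalization:
    def test_constant_volume_maps_to_one(self):
        out = intensity_normalize_pet(Volume(np.full((4, 4, 4), 7.0)))
        np.testing.assert_allclose(out.data, 1.0)

    def test_output_mean_is_one(self, random_volume):
        out = intensity_normalize_pet(random_volume((5, 6, 7), lo=0.1, hi=9.0))
        assert out.data.mean() == pytest.approx(1.0, rel=1e-6)

    def test_hand_division_oracle(self):
        # values 1..8 on the first voxels of a legal 3^3 grid, rest ones
        data = np.ones((3, 3, 3))
        data.flat[:8] = np.arange(1.0, 9.0)
        mean = (np.arange(1.0, 9.0).sum() + 19.0) / 27.0  # hand mean
        out = intensity_normalize_pet(Volume(data))
        assert out.data.flat[7] == pytest.approx(8.0 / mean)

    def test_idempotent(self, random_volume):
        v = random_volume((5, 5, 5), lo=0.5, hi=3.0)
        once = intensity_normalize_pet(v)
        twice = intensity_normalize_pet(once)
        np.testing.assert_allclose(twice.data, once.data, rtol=1e-6)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DegenerateInputError):
            intensity_normalize_pet(Volume(np.full((4, 4, 4), -1.0)))


class TestRescale:
    def test_endpoints_and_midpoint(self):
        data = np.zeros((3, 3, 3))
        data.flat[0] = 0.0
        data.flat[1] = 10.0
        data.flat[2] = 5.0
        out = rescale_to_range(Volume(data))
        assert out.data.min() == pytest.approx(-1.0)
        assert out.data.max() == pytest.approx(1.0)
        assert out.data.flat[2] == pytest.approx(0.0)

    def test_affine_map_oracle(self):
        data = np.full((3, 3, 3), 4.0)
        data.flat[0] = 2.0
        data.flat[1] = 6.0
        out = rescale_to_range(Volume(data))
        assert out.data.flat[0] == pytest.approx(-1.0)
        assert out.data.flat[1] == pytest.approx(1.0)
        assert out.data.flat[2] == pytest.approx(0.0)

    def test_monotone(self, random_volume):
        v = random_volume((4, 4, 4))
        out = rescale_to_range(v)
        order_in = np.argsort(v.data.ravel())
        order_out = np.argsort(out.data.ravel())
        np.testing.assert_array_equal(order_in, order_out)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            rescale_to_range(Volume(np.ones((4, 4, 4))))


class TestResize:
    def test_constant_preserved_exactly(self):
        v = Volume(np.full((40, 40, 40), 0.5))
        out = resize_antialias(v, (12, 12, 12))
        assert out.shape == (12, 12, 12)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-12)

    def test_identity_target(self, random_volume):
        v = random_volume((10, 10, 10))
        out = resize_antialias(v, (10, 10, 10))
        np.testing.assert_array_equal(out.data, v.data)

    def test_upsample_forbidden_by_default(self, random_volume):
        with pytest.raises(ValueError, match="upsampling"):
            resize_antialias(random_volume((8, 8, 8)), (12, 12, 12))

    def test_low_frequency_mean_preserved(self):
        x = np.linspace(0, 2 * np.pi, 48)
        data = 1.0 + 0.5 * np.sin(x)[:, None, None] * np.ones((48, 48, 48))
        v = Volume(data)
        out = resize_antialias(v, (16, 16, 16))
        assert out.data.mean() == pytest.approx(data.mean(), rel=0.01)

    def test_affine_spacing_scales(self):
        v = Volume(np.random.default_rng(0).uniform(size=(30, 30, 30)),
                   affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        out = resize_antialias(v, (10, 10, 10))
        assert out.spacing == pytest.approx((6.0, 6.0, 6.0))


def test_preprocess_pair_chain(small_phantom):
    pair, _ = small_phantom
    out = preprocess_pair(pair, (12, 12, 12))
    assert out.pet.shape == out.mri.shape == (12, 12, 12)
    for v in (out.pet, out.mri):
        assert v.data.min() == pytest.approx(-1.0)
        assert v.data.max() == pytest.approx(1.0)


def test_manifest_round_trip(tmp_path, small_phantom):
    from egan3d.phantoms import PhantomSpec, make_dataset

    ds = make_dataset(3, PhantomSpec(extent=16, seed=11), out_dir=tmp_path)
    pairs = load_pairs(tmp_path / "manifest.tsv")
    assert len(pairs) == 3
    np.testing.assert_allclose(pairs[0].pet.data, ds.pairs[0].pet.data, atol=1e-6)
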