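"""Loading, isotropic resampling, and ROI partitioning contracts."""

import numpy as np
import pytest

from radrep.errors import EmptyRoiError, FormatError
from radrep.io import write_image
from radrep.preprocess import ImageCase, load_case, partition_roi, resample_isotropic
from radrep.synthetic import NoduleSpec, generate_case


def test_write_load_roundtrip(tmp_path, sphere_case):
    case, _ = sphere_case
    for ext in (".nrrd", ".nii.gz"):
        img, msk = tmp_path / f"i{ext}", tmp_path / f"m{ext}"
        write_image(case.volume, case.spacing, img)
        write_image(case.mask.astype(np.uint8), case.spacing, msk)
        loaded = load_case(img, msk, status="benign", case_id="rt")
        np.testing.assert_allclose(loaded.volume, case.volume, atol=1e-4)
        assert np.array_equal(loaded.mask, case.mask)
        assert loaded.spacing == pytest.approx(case.spacing, abs=1e-6)


def test_empty_mask_rejected(tmp_path):
    vol = np.zeros((8, 8, 8))
    write_image(vol, (1, 1, 1), tmp_path / "i.nrrd")
    write_image(vol.astype(np.uint8), (1, 1, 1), tmp_path / "m.nrrd")
    with pytest.raises(EmptyRoiError):
        load_case(tmp_path / "i.nrrd", tmp_path / "m.nrrd")


def test_grid_mismatch_rejected(tmp_path):
    write_image(np.zeros((8, 8, 8)), (1, 1, 1), tmp_path / "i.nrrd")
    m = np.zeros((9, 8, 8), dtype=np.uint8)
    m[4, 4, 4] = 1
    write_image(m, (1, 1, 1), tmp_path / "m.nrrd")
    with pytest.raises(FormatError):
        load_case(tmp_path / "i.nrrd", tmp_path / "m.nrrd")


def test_resample_constant_volume_stays_constant():
    mask = np.zeros((20, 20, 10), dtype=np.uint8)
    mask[8:12, 8:12, 4:6] = 1
    case = ImageCase("c", np.full((20, 20, 10), -120.0), mask, (0.7, 0.7, 2.0))
    out = resample_isotropic(case, 2.0)
    np.testing.assert_allclose(out.volume, -120.0, atol=1e-9)
    assert out.spacing == (2.0, 2.0, 2.0)


def test_resample_preserves_sphere_volume(sphere_case):
    """Resampling to 2 mm keeps the sphere's physical volume.

    The native anisotropic rasterization overestimates a 10 mm sphere by a
    few percent (partial-volume bias at 2 mm slices), so the resampled mask
    is compared both against the analytic sphere volume (tight) and against
    the native mask volume (rasterization-bias allowance).
    """
    case, spec = sphere_case
    out = resample_isotropic(case, 2.0)
    assert abs(out.physical_volume - spec.analytic_volume) <= 2 * out.voxel_volume
    assert abs(out.physical_volume - case.physical_volume) <= 0.05 * case.physical_volume + 16.0


def test_resample_identity_at_native_spacing():
    mask = np.zeros((10, 10, 10), dtype=np.uint8)
    mask[4:6, 4:6, 4:6] = 1
    vol = np.random.default_rng(0).normal(size=(10, 10, 10))
    case = ImageCase("c", vol, mask, (2.0, 2.0, 2.0))
    out = resample_isotropic(case, 2.0)
    np.testing.assert_allclose(out.volume, vol, atol=1e-12)
    assert np.array_equal(out.mask, case.mask)


def test_resample_idempotent(sphere_case):
    case, _ = sphere_case
    once = resample_isotropic(case, 2.0)
    twice = resample_isotropic(once, 2.0)
    np.testing.assert_allclose(twice.volume, once.volume, atol=1e-6)
    assert np.array_equal(twice.mask, once.mask)


def test_resample_vanishing_nodule_is_empty_roi_error():
    mask = np.zeros((30, 30, 30), dtype=np.uint8)
    mask[15, 15, 15] = 1
    case = ImageCase("c", np.zeros((30, 30, 30)), mask, (0.5, 0.5, 0.5))
    with pytest.raises(EmptyRoiError):
        resample_isotropic(case, 8.0)


def test_partition_ratio_near_two_thirds_on_large_sphere():
    spec = NoduleSpec(center=(24.0, 24.0, 24.0), equivalent_diameter=16.0,
                      texture_amplitude=0.0)
    case = generate_case(spec, (1.0, 1.0, 1.0), (49, 49, 49), noise_sd=0.0,
                         rng=np.random.default_rng(2))
    part = partition_roi(case)
    ratio = part.inner.sum() / part.whole.sum()
    assert abs(ratio - 2.0 / 3.0) <= 0.10
    assert not part.degenerate


def test_partition_conserves_whole(sphere_case):
    case, _ = sphere_case
    part = partition_roi(case)
    assert np.array_equal(part.inner | part.outer, part.whole)
    assert not (part.inner & part.outer).any()


def test_single_voxel_mask_partitions_degenerately():
    mask = np.zeros((9, 9, 9), dtype=np.uint8)
    mask[4, 4, 4] = 1
    case = ImageCase("c", np.zeros((9, 9, 9)), mask, (1.0, 1.0, 1.0))
    part = partition_roi(case)
    assert part.degenerate
    assert part.inner.sum() == 1
    assert part.outer.sum() == 0


def test_all_negative_nodule_has_empty_positive_mask():
    mask = np.zeros((9, 9, 9), dtype=np.uint8)
    mask[3:6, 3:6, 3:6] = 1
    case = ImageCase("c", np.full((9, 9, 9), -500.0), mask, (1.0, 1.0, 1.0))
    part = partition_roi(case)
    assert not part.positive.any()
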