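"""Texture matrices against independent brute-force enumeration oracles."""


import numpy as np
import pytest

from radrep.features.texture import (
    OFFSETS_13,
    glcm_features,
    glcm_matrix,
    iszm_features,
    iszm_matrix,
    ngtdm_features,
    ngtdm_table,
)

from oracles import brute_glcm, brute_ngtdm, brute_zones  # noqa: E402


# ---------------------------------------------------------------- GLCM

def _random_roi(shape, fill=0.8, seed=0):
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < fill
    mask[tuple(s // 2 for s in shape)] = True
    volume = rng.normal(0, 100, size=shape)
    return volume, mask


@pytest.mark.parametrize("shape,seed", [((5, 5, 5), 1), ((6, 6, 6), 2), ((4, 6, 3), 3)])
def test_glcm_matches_brute_force(shape, seed):
    volume, mask = _random_roi(shape, seed=seed)
    ours = glcm_matrix(volume, mask, 8)
    oracle = brute_glcm(volume, mask, 8)
    np.testing.assert_allclose(ours, oracle, atol=1e-9)


def test_glcm_feature_values_match_brute_force():
    volume, mask = _random_roi((6, 6, 6), seed=7)
    ours = glcm_features(glcm_matrix(volume, mask, 8))
    oracle = glcm_features(brute_glcm(volume, mask, 8))
    for k in ours:
        assert ours[k] == pytest.approx(oracle[k], abs=1e-9)


def test_constant_roi_glcm_is_point_mass():
    mask = np.ones((3, 3, 3), dtype=bool)
    mat = glcm_matrix(np.full((3, 3, 3), 55.0), mask, 8)
    assert mat[0, 0] == pytest.approx(1.0)
    feats = glcm_features(mat)
    assert feats["entropy"] == pytest.approx(0.0)
    assert feats["energy"] == pytest.approx(1.0)
    assert feats["homogeneity"] == pytest.approx(1.0)
    assert feats["contrast"] == pytest.approx(0.0)
    assert feats["dissimilarity"] == pytest.approx(0.0)


def test_two_voxel_roi_symmetric_halves():
    volume = np.zeros((2, 1, 1))
    volume[1, 0, 0] = 100.0
    mask = np.ones((2, 1, 1), dtype=bool)
    mat = glcm_matrix(volume, mask, 8)
    assert mat[0, 7] == pytest.approx(0.5)
    assert mat[7, 0] == pytest.approx(0.5)


def test_isolated_voxels_are_degenerate():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[0, 0, 0] = mask[4, 4, 4] = True  # no neighbour pairs
    assert glcm_matrix(np.zeros((5, 5, 5)), mask, 8) is None


def test_hand_computed_2x2_glcm():
    """Uniform 2x2 GLCM: entropy 2 bits, difference entropy 1 bit."""
    mat = np.full((2, 2), 0.25)
    feats = glcm_features(mat)
    assert feats["entropy"] == pytest.approx(2.0)
    assert feats["difference_entropy"] == pytest.approx(1.0)
    assert feats["energy"] == pytest.approx(0.25)
    assert feats["contrast"] == pytest.approx(0.5)
    assert feats["correlation"] == pytest.approx(0.0)


def test_correlation_bounded():
    for seed in range(5):
        volume, mask = _random_roi((5, 5, 5), seed=seed)
        feats = glcm_features(glcm_matrix(volume, mask, 8))
        assert -1.0 - 1e-9 <= feats["correlation"] <= 1.0 + 1e-9


def test_offsets_cover_13_unique_directions():
    assert len(OFFSETS_13) == 13
    assert len({o for o in OFFSETS_13} | {tuple(-x for x in o) for o in OFFSETS_13}) == 26


# ---------------------------------------------------------------- ISZM

def test_constant_roi_single_zone():
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[:3, :3, :3] = True  # 27 voxels
    vals = iszm_features(np.full((4, 4, 4), 10.0), mask, 32)
    assert vals["iszm.zone_percentage"].value == pytest.approx(1 / 27)
    assert vals["iszm.large_zone_emphasis"].value == pytest.approx(27.0 ** 2)


def test_checkerboard_zones_all_size_one():
    shape = (4, 4, 4)
    idx = np.indices(shape).sum(axis=0)
    volume = (idx % 2).astype(float) * 100
    mask = np.ones(shape, dtype=bool)
    # 26-connectivity: same-parity diagonal neighbours touch, so use the
    # brute-force flood fill as the oracle rather than assuming size 1
    zones = brute_zones(volume, mask, 2)
    Z = iszm_matrix(volume, mask, 2)
    assert Z.sum() == len(zones)
    for lev in (0, 1):
        oracle_sizes = sorted(s for l, s in zones if l == lev)
        ours = [s + 1 for s in range(256) for _ in range(int(Z[lev, s]))]
        assert sorted(ours) == [min(s, 256) for s in oracle_sizes]


def test_zone_sizes_partition_roi():
    volume, mask = _random_roi((6, 6, 6), seed=11)
    zones = brute_zones(volume, mask, 4)
    assert sum(s for _, s in zones) == int(mask.sum())
    Z = iszm_matrix(volume, mask, 4)
    assert Z.sum() == len(zones)


def test_iszm_matrix_matches_brute_force_zones():
    volume, mask = _random_roi((5, 6, 4), seed=13)
    zones = brute_zones(volume, mask, 4)
    Z = iszm_matrix(volume, mask, 4)
    expected = np.zeros_like(Z)
    for lev, size in zones:
        expected[lev, min(size, 256) - 1] += 1
    np.testing.assert_array_equal(Z, expected)


# ---------------------------------------------------------------- NGTDM

def test_ngtdm_single_interior_voxel_matches_hand_enumeration():
    rng = np.random.default_rng(21)
    volume = rng.normal(0, 50, size=(3, 3, 3))
    mask = np.ones((3, 3, 3), dtype=bool)
    ours = ngtdm_table(volume, mask, 8)
    oracle = brute_ngtdm(volume, mask, 8)
    np.testing.assert_allclose(ours[0], oracle[0], atol=1e-12)
    np.testing.assert_allclose(ours[1], oracle[1], atol=1e-9)
    assert ours[0].sum() == 1  # exactly one complete neighbourhood


@pytest.mark.parametrize("seed", [31, 32])
def test_ngtdm_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    volume = rng.normal(0, 50, size=(6, 6, 6))
    mask = np.ones((6, 6, 6), dtype=bool)
    mask[tuple(rng.integers(0, 6, size=3))] = False  # notch one voxel
    ours = ngtdm_table(volume, mask, 8)
    oracle = brute_ngtdm(volume, mask, 8)
    np.testing.assert_allclose(ours[0], oracle[0], atol=1e-12)
    np.testing.assert_allclose(ours[1], oracle[1], atol=1e-9)


def test_constant_roi_ngtdm():
    mask = np.ones((4, 4, 4), dtype=bool)
    vals = ngtdm_features(np.full((4, 4, 4), 5.0), mask, 32)
    assert vals["ngtdm.contrast"].value == pytest.approx(0.0)
    assert vals["ngtdm.coarseness"].value == pytest.approx(1e12)  # 1/eps cap


def test_two_voxel_roi_fails():
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1, 1, 1] = mask[1, 1, 2] = True
    vals = ngtdm_features(np.zeros((4, 4, 4)), mask, 32)
    assert all(v.failure == "too_few_voxels" for v in vals.values())


def test_failure_monotone_under_mask_growth():
    """If NGTDM succeeds on a sphere it succeeds on any enclosing sphere."""
    x, y, z = np.ogrid[:15, :15, :15]
    d2 = (x - 7) ** 2 + (y - 7) ** 2 + (z - 7) ** 2
    volume = np.random.default_rng(3).normal(size=(15, 15, 15))
    succeeded = False
    for r in (1.0, 1.5, 2.5, 4.0, 6.0):
        vals = ngtdm_features(volume, d2 <= r ** 2, 8)
        ok = not any(v.failed for v in vals.values())
        assert ok or not succeeded  # once succeeded, never fails again
        succeeded = succeeded or ok
    assert succeeded
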