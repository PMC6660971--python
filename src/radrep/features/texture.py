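"""Texture matrices and their features: GLCM, ISZM, NGTDM.

GLCM: intensities are binned equal-width over the ROI min-max; co-occurrences
are accumulated over the 13 unique 3D index-space offsets at Chebyshev
distance 1 and their opposites (symmetric), pooled into one matrix and
normalized to sum 1.  Eleven Haralick-style measures are computed with
base-2 logs and the 0*log0 := 0 convention.

ISZM: zones are 26-connected components of equal binned intensity (32 bins);
the zone matrix is 32 x 256 with zone sizes above 256 accumulated in the
last column.  NGTDM follows Amadasun-King with a full 26-neighbourhood:
only voxels whose entire neighbourhood lies inside the ROI contribute.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

from radrep.features._base import FeatureValue, bin_minmax, fail_all, xlog2x_sum

#: the 13 unique 3D offsets (one per +/- direction pair) at distance 1
OFFSETS_13 = tuple(
    off for off in product((-1, 0, 1), repeat=3) if off > (0, 0, 0)
)

GLCM_MEASURES = (
    "energy", "entropy", "contrast", "homogeneity", "dissimilarity",
    "correlation", "cluster_shade", "cluster_prominence", "cluster_tendency",
    "difference_entropy", "imc1",
)
ISZM_NAMES = ("zone_percentage", "large_zone_emphasis")
NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

ISZM_SIZE_CAP = 256
_EPS = 1e-12


# ---------------------------------------------------------------- GLCM

def glcm_matrix(volume: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Symmetric direction-merged co-occurrence matrix, normalized to sum 1.

    Returns None when the ROI has no in-ROI neighbour pair (degenerate).
    """
    mask = np.asarray(mask) > 0
    if mask.sum() < 2:
        return None
    levels = np.full(mask.shape, -1, dtype=np.int64)
    levels[mask] = bin_minmax(np.asarray(volume, dtype=np.float64)[mask], n_bins)
    mat = np.zeros((n_bins, n_bins), dtype=np.float64)
    for off in OFFSETS_13:
        sl_a = tuple(slice(max(0, -o), levels.shape[d] - max(0, o)) for d, o in enumerate(off))
        sl_b = tuple(slice(max(0, o), levels.shape[d] - max(0, -o)) for d, o in enumerate(off))
        a, b = levels[sl_a], levels[sl_b]
        valid = (a >= 0) & (b >= 0)
        if valid.any():
            np.add.at(mat, (a[valid], b[valid]), 1.0)
            np.add.at(mat, (b[valid], a[valid]), 1.0)
    total = mat.sum()
    if total == 0:
        return None
    return mat / total


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """Eleven Haralick-style measures of a normalized, symmetric GLCM."""
    n = glcm.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = glcm.sum(axis=1)
    mu_x = float((i * px).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    # symmetric matrix: marginals coincide
    mu_y, sd_y, py = mu_x, sd_x, px

    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), glcm.ravel())

    entropy = xlog2x_sum(glcm.ravel())
    hx = xlog2x_sum(px)
    nz = glcm > 0
    pxy = px[:, None] * py[None, :]
    hxy1 = float(-(glcm[nz] * np.log2(np.where(pxy[nz] > 0, pxy[nz], 1.0))).sum())

    if sd_x > 0:
        correlation = float(((ii - mu_x) * (jj - mu_y) * glcm).sum() / (sd_x * sd_y))
    else:
        correlation = 0.0  # single occupied level: no variance to correlate

    csum = ii + jj - mu_x - mu_y
    return {
        "energy": float((glcm ** 2).sum()),
        "entropy": entropy,
        "contrast": float(((ii - jj) ** 2 * glcm).sum()),
        "homogeneity": float((glcm / (1.0 + np.abs(ii - jj))).sum()),
        "dissimilarity": float((np.abs(ii - jj) * glcm).sum()),
        "correlation": correlation,
        "cluster_shade": float((csum ** 3 * glcm).sum()),
        "cluster_prominence": float((csum ** 4 * glcm).sum()),
        "cluster_tendency": float((csum ** 2 * glcm).sum()),
        "difference_entropy": xlog2x_sum(p_diff),
        "imc1": (entropy - hxy1) / max(hx, _EPS) if hx > 0 else 0.0,
    }


def _subsample(volume: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x block down-sampling: mean-pool intensities, majority-pool the mask."""
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    v = volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    m = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pads = [(0, (-d) % 2) for d in v.shape]
    v = np.pad(v, pads, mode="edge")
    m = np.pad(m, pads)
    sh = (v.shape[0] // 2, 2, v.shape[1] // 2, 2, v.shape[2] // 2, 2)
    v_pool = v.reshape(sh).mean(axis=(1, 3, 5))
    m_pool = m.reshape(sh).sum(axis=(1, 3, 5)) >= 4  # majority of 8, ties kept
    return v_pool, m_pool


def glcm_family(partition, volume: np.ndarray, n_bins: int,
                subsample: bool = False) -> dict[str, FeatureValue]:
    """44 GLCM features: 11 measures on whole/inner/outer plus their delta.

    With ``subsample`` the ROI grid is first block-down-sampled by 2 per axis
    (the family whose failures on small nodules the audit inspects); names
    are prefixed ``glcm_sub`` instead of ``glcm``.
    """
    prefix = "glcm_sub" if subsample else "glcm"
    out: dict[str, FeatureValue] = {}
    regions = {"whole": partition.whole, "inner": partition.inner, "outer": partition.outer}
    computed: dict[str, dict[str, float] | str] = {}
    for region, rmask in regions.items():
        if region != "whole" and partition.degenerate:
            computed[region] = "too_few_voxels"
            continue
        if not rmask.any():
            computed[region] = "empty_roi"
            continue
        vol, msk = (volume, rmask) if not subsample else _subsample(volume, rmask)
        if msk.sum() < 2:
            computed[region] = "too_few_voxels"
            continue
        mat = glcm_matrix(vol, msk, n_bins)
        computed[region] = glcm_features(mat) if mat is not None else "degenerate_matrix"
    for region in ("whole", "inner", "outer"):
        res = computed[region]
        for meas in GLCM_MEASURES:
            out[f"{prefix}.{region}.{meas}"] = (
                FeatureValue.fail(res) if isinstance(res, str)
                else FeatureValue.ok(res[meas])
            )
    for meas in GLCM_MEASURES:
        o, i_ = computed["outer"], computed["inner"]
        if isinstance(o, str) or isinstance(i_, str):
            reason = o if isinstance(o, str) else i_
            out[f"{prefix}.delta.{meas}"] = FeatureValue.fail(reason)
        else:
            out[f"{prefix}.delta.{meas}"] = FeatureValue.ok(o[meas] - i_[meas])
    return out


# ---------------------------------------------------------------- ISZM

def iszm_matrix(volume: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Intensity size zone matrix: n_bins x 256 zone counts (sizes capped)."""
    mask = np.asarray(mask) > 0
    levels = np.full(mask.shape, -1, dtype=np.int64)
    levels[mask] = bin_minmax(np.asarray(volume, dtype=np.float64)[mask], n_bins)
    Z = np.zeros((n_bins, ISZM_SIZE_CAP), dtype=np.float64)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connected zones
    for lev in np.unique(levels[mask]):
        lab, n_zones = ndimage.label(levels == lev, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            Z[lev, min(int(s), ISZM_SIZE_CAP) - 1] += 1.0
    return Z


def iszm_features(volume: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> dict[str, FeatureValue]:
    """Zone percentage and large-zone emphasis of the ISZM."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        return fail_all([f"iszm.{n}" for n in ISZM_NAMES], "empty_roi")
    Z = iszm_matrix(volume, mask, n_bins)
    n_zones = Z.sum()
    sizes = np.arange(1, ISZM_SIZE_CAP + 1, dtype=np.float64)
    lze = float((Z * sizes[None, :] ** 2).sum() / n_zones)
    values = {"zone_percentage": float(n_zones / mask.sum()), "large_zone_emphasis": lze}
    return {f"iszm.{n}": FeatureValue.ok(values[n]) for n in ISZM_NAMES}


# ---------------------------------------------------------------- NGTDM

def ngtdm_table(volume: np.ndarray, mask: np.ndarray, n_bins: int = 32):
    """Amadasun-King per-level occurrence counts n_i and difference sums s_i.

    Levels are 1-based bin indices.  Returns (n_i, s_i) arrays of length
    n_bins, or None when no voxel has a complete in-ROI 26-neighbourhood.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        return None
    levels = np.zeros(mask.shape, dtype=np.float64)
    levels[mask] = bin_minmax(np.asarray(volume, dtype=np.float64)[mask], n_bins) + 1.0
    valid = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if not valid.any():
        return None
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_mean = ndimage.convolve(levels, kernel, mode="constant") / 26.0
    diffs = np.abs(levels - nbr_mean)
    n_i = np.zeros(n_bins)
    s_i = np.zeros(n_bins)
    lev_valid = (levels[valid] - 1).astype(int)
    np.add.at(n_i, lev_valid, 1.0)
    np.add.at(s_i, lev_valid, diffs[valid])
    return n_i, s_i


def ngtdm_features(volume: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> dict[str, FeatureValue]:
    """Coarseness, contrast, busyness, complexity, strength (Amadasun-King)."""
    names = [f"ngtdm.{n}" for n in NGTDM_NAMES]
    mask = np.asarray(mask) > 0
    if not mask.any():
        return fail_all(names, "empty_roi")
    table = ngtdm_table(volume, mask, n_bins)
    if table is None:
        return fail_all(names, "too_few_voxels")
    n_i, s_i = table
    N = n_i.sum()
    p = n_i / N
    lv = np.arange(1, n_bins + 1, dtype=np.float64)
    occupied = p > 0
    Ngp = int(occupied.sum())

    coarseness = 1.0 / max((p * s_i).sum(), _EPS)
    if Ngp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        li, lj = np.meshgrid(lv, lv, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = (float((pi * pj * (li - lj) ** 2).sum()) / (Ngp * (Ngp - 1))
                    * float(s_i.sum()) / N)
        denom_busy = float(np.abs(li * pi - lj * pj)[both].sum())
        busyness = float((p * s_i).sum()) / denom_busy if denom_busy > 0 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            comp_terms = (np.abs(li - lj) / (N * (pi + pj))
                          * (pi * s_i[:, None] + pj * s_i[None, :]))
        complexity = float(comp_terms[both].sum())
        strength = float(((pi + pj) * (li - lj) ** 2)[both].sum()) / max(float(s_i.sum()), _EPS)
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    values = {"coarseness": coarseness, "contrast": contrast, "busyness": busyness,
              "complexity": complexity, "strength": strength}
    return {f"ngtdm.{n}": FeatureValue.ok(values[n]) for n in NGTDM_NAMES}
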