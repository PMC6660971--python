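"""Fractal descriptors: box-counting dimension, gliding-box lacunarity, and
the blanket-method fractal signature of the intensity surface.

Box counting runs over dyadic box sizes s in {1, 2, 4, 8, 16} clipped to the
mask bounding box; the dimension is the negative slope of log N(s) against
log s.  Lacunarity uses gliding (stride-1) boxes of size r in {2..8}:
Lambda(r) = var(M_r)/mean(M_r)^2 + 1 where M_r is the mask mass per box.
The fractal signature S(eps) for eps in {2..8} derives from upper/lower
blanket surfaces grown around the intensity surface of the largest axial
cross-section; a flat surface has S(eps) = 2 at every scale.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from numpy.lib.stride_tricks import sliding_window_view

from radrep.features._base import FeatureValue, fail_all

LACUNARITY_SIZES = tuple(range(2, 9))
BLANKET_SCALES = tuple(range(2, 9))


def fractal_names():
    return (["fractal.box_counting_dimension"]
            + [f"fractal.lacunarity.r{r}" for r in LACUNARITY_SIZES]
            + [f"fractal.fsd.e{e}" for e in BLANKET_SCALES])


def _crop_bbox(mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def box_counting_dimension(mask: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary mask (bounding-box cropped)."""
    m = _crop_bbox(np.asarray(mask) > 0)
    max_dim = max(m.shape)
    sizes = [s for s in (1, 2, 4, 8, 16) if s <= max_dim]
    if len(sizes) < 2:
        sizes = [1, 2]
    counts = []
    for s in sizes:
        pads = [(0, (-d) % s) for d in m.shape]
        mp = np.pad(m, pads)
        blocks = mp.reshape(mp.shape[0] // s, s, mp.shape[1] // s, s,
                            mp.shape[2] // s, s)
        counts.append(int(blocks.any(axis=(1, 3, 5)).sum()))
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


def gliding_box_lacunarity(mask: np.ndarray, r: int) -> float:
    """Lacunarity at gliding-box size r; boxes are clipped to the bounding box.

    When the bounding box is smaller than r along an axis the box degenerates
    to the full extent there (single position, variance 0, Lambda -> 1).
    """
    m = _crop_bbox(np.asarray(mask) > 0).astype(np.float64)
    win = tuple(min(r, d) for d in m.shape)
    masses = sliding_window_view(m, win).sum(axis=(-3, -2, -1)).ravel()
    mean = masses.mean()
    if mean == 0:
        return np.nan
    return float(masses.var() / mean ** 2 + 1.0)


def blanket_signature(surface: np.ndarray, region: np.ndarray,
                      scales=BLANKET_SCALES) -> list[float]:
    """Fractal signature S(eps) of a 2D intensity surface restricted to a mask.

    Upper and lower blankets grow by one grey unit plus a morphological
    dilation/erosion per step; the blanket area A(eps) is the inter-blanket
    volume over the mask divided by 2*eps, and S(eps) is 2 minus the log-log
    slope of A between consecutive scales.
    """
    f = np.asarray(surface, dtype=np.float64)
    u = f.copy()
    b = f.copy()
    foot = np.ones((3, 3))
    max_eps = max(scales)
    out = []
    area_at = {}
    for eps in range(1, max_eps + 1):
        u = np.maximum(u + 1.0, ndimage.grey_dilation(u, footprint=foot))
        b = np.minimum(b - 1.0, ndimage.grey_erosion(b, footprint=foot))
        area_at[eps] = float((u - b)[region].sum()) / (2.0 * eps)
    for eps in scales:
        a1, a0 = area_at[eps], area_at[eps - 1]
        if a1 <= 0 or a0 <= 0:
            out.append(np.nan)
        else:
            out.append(2.0 - (np.log(a1) - np.log(a0)) / (np.log(eps) - np.log(eps - 1)))
    return out


def fractal_features(mask: np.ndarray, volume: np.ndarray) -> dict[str, FeatureValue]:
    """All 15 fractal features; masks with a bounding box under 4 voxels on
    any axis fail with too_few_voxels."""
    names = fractal_names()
    mask = np.asarray(mask) > 0
    if not mask.any():
        return fail_all(names, "empty_roi")
    idx = np.argwhere(mask)
    extent = idx.max(axis=0) - idx.min(axis=0) + 1
    if (extent < 4).any():
        return fail_all(names, "too_few_voxels")

    out = {"fractal.box_counting_dimension": FeatureValue.ok(box_counting_dimension(mask))}
    for r in LACUNARITY_SIZES:
        out[f"fractal.lacunarity.r{r}"] = FeatureValue.ok(gliding_box_lacunarity(mask, r))

    # intensity surface of the largest axial cross-section, over its bbox
    counts = mask.sum(axis=(0, 1))
    k = int(np.argmax(counts))
    sl_mask = mask[:, :, k]
    ii = np.argwhere(sl_mask)
    lo, hi = ii.min(axis=0), ii.max(axis=0) + 1
    region = sl_mask[lo[0]:hi[0], lo[1]:hi[1]]
    surf = volume[lo[0]:hi[0], lo[1]:hi[1], k]
    sig = blanket_signature(surf, region)
    for e, s in zip(BLANKET_SCALES, sig):
        out[f"fractal.fsd.e{e}"] = (FeatureValue.ok(s) if np.isfinite(s)
                                    else FeatureValue.fail("degenerate_matrix"))
    return out
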