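"""3D and 2D morphology of the nodule mask.

Surface area comes from a marching-cubes mesh of the binary mask in physical
coordinates; sphericity and its reciprocal (spherical disproportion) compare
that surface with the surface of the volume-equivalent sphere; the maximum
3D diameter is the largest pairwise Euclidean distance between surface
voxels.  Three further statistics are taken on the axial slice with the
largest cross-section.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from radrep.features._base import FeatureValue, fail_all

SHAPE3D_NAMES = (
    "volume", "surface_area", "surface_to_volume_ratio", "compactness",
    "sphericity", "spherical_disproportion", "max_3d_diameter",
    "equivalent_spherical_diameter", "elongation", "flatness",
)
SHAPE2D_NAMES = ("area", "perimeter", "circularity")


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices of mask voxels with at least one 6-neighbour outside."""
    core = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1))
    return np.argwhere(mask & ~core)


def max_3d_diameter(mask: np.ndarray, spacing) -> float:
    pts = surface_voxels(mask) * np.asarray(spacing)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar) point sets: fall through to full pdist
    return float(pdist(pts).max())


def shape3d_features(mask: np.ndarray, spacing) -> dict[str, FeatureValue]:
    """The ten 3D shape descriptors (mm, mm^2, mm^3 and unitless ratios)."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        return fail_all([f"shape3d.{n}" for n in SHAPE3D_NAMES], "empty_roi")
    spacing = np.asarray(spacing, dtype=float)
    voxvol = float(np.prod(spacing))
    volume = float(mask.sum()) * voxvol

    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))

    sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)
    coords = np.argwhere(mask) * spacing
    if len(coords) > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    else:
        elongation = flatness = 1.0

    values = {
        "volume": volume,
        "surface_area": area,
        "surface_to_volume_ratio": area / volume,
        "compactness": volume / (np.sqrt(np.pi) * area ** 1.5),
        "sphericity": sphericity,
        "spherical_disproportion": 1.0 / sphericity,
        "max_3d_diameter": max_3d_diameter(mask, spacing),
        "equivalent_spherical_diameter": float((6.0 * volume / np.pi) ** (1 / 3)),
        "elongation": elongation,
        "flatness": flatness,
    }
    return {f"shape3d.{n}": FeatureValue.ok(values[n]) for n in SHAPE3D_NAMES}


def shape2d_features(mask: np.ndarray, spacing) -> dict[str, FeatureValue]:
    """Area, perimeter and circularity of the largest axial cross-section.

    Ties for largest slice resolve to the lower slice index.  Requires equal
    in-plane spacing (the two in-plane components are averaged otherwise).
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        return fail_all([f"shape2d.{n}" for n in SHAPE2D_NAMES], "empty_roi")
    counts = mask.sum(axis=(0, 1))
    k = int(np.argmax(counts))  # argmax returns the first (lowest) index on ties
    sl = mask[:, :, k]
    pix = float(np.mean(spacing[:2]))
    area = float(sl.sum()) * pix * pix
    perimeter = float(measure.perimeter_crofton(sl, directions=4)) * pix
    circ = 4.0 * np.pi * area / perimeter ** 2 if perimeter > 0 else np.nan
    values = {"area": area, "perimeter": perimeter, "circularity": circ}
    return {f"shape2d.{n}": FeatureValue.ok(values[n]) for n in SHAPE2D_NAMES}
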