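"""Case loading, isotropic resampling, and ROI partitioning.

A nodule ROI is partitioned by volume into an inner core (closest achievable
to 2/3 of the whole volume under iterative 6-connected erosion), an outer rim
(the remainder), and the positive-HU sub-mask.  These partitions feed the
regional histogram and texture feature families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from radrep.errors import EmptyRoiError, FormatError
from radrep.io import read_image


@dataclass
class ImageCase:
    """One volume + mask + spacing + status label; the unit of processing.

    ``volume`` holds HU intensities, ``mask`` is binary on the same grid, and
    ``spacing`` is the (x, y, z) voxel size in mm with z the slice axis.
    """

    case_id: str
    volume: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    status: str = "unknown"

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float64)
        self.mask = np.asarray(self.mask) > 0
        if self.volume.shape != self.mask.shape:
            raise FormatError(
                f"{self.case_id}: volume shape {self.volume.shape} != mask shape {self.mask.shape}"
            )
        if not self.mask.any():
            raise EmptyRoiError(f"{self.case_id}: mask has no foreground voxels")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def physical_volume(self) -> float:
        """Mask volume in mm^3 (voxel count x voxel volume)."""
        return float(self.mask.sum()) * self.voxel_volume


@dataclass
class RoiPartition:
    """Whole / inner (~2/3 by volume) / outer (~1/3) / positive-HU masks."""

    whole: np.ndarray
    inner: np.ndarray
    outer: np.ndarray
    positive: np.ndarray
    degenerate: bool = False
    erosion_depth: int = field(default=0)


def load_case(image_path, mask_path, status: str = "unknown", case_id: str | None = None) -> ImageCase:
    """Load an image/mask pair; the mask is binarized at > 0.

    Raises :class:`FormatError` on grid or spacing mismatch and
    :class:`EmptyRoiError` if the mask has no foreground.
    """
    volume, spacing_v = read_image(image_path)
    mask, spacing_m = read_image(mask_path)
    if volume.shape != mask.shape:
        raise FormatError(
            f"grid mismatch: image {volume.shape} vs mask {mask.shape}"
        )
    if not np.allclose(spacing_v, spacing_m, rtol=0, atol=1e-4):
        raise FormatError(f"spacing mismatch: image {spacing_v} vs mask {spacing_m}")
    if case_id is None:
        case_id = str(image_path)
    return ImageCase(case_id=case_id, volume=volume, mask=mask, spacing=spacing_v, status=status)


def resample_isotropic(case: ImageCase, target_spacing: float = 2.0) -> ImageCase:
    """Resample a case to isotropic voxels of ``target_spacing`` mm.

    Intensities are linearly interpolated; the mask is resampled as a
    partial-volume fraction (linear interpolation of the binary field) and
    re-binarized at 0.5, so an output voxel belongs to the nodule only if
    the majority of the volume it represents does.  Down-sampling small
    voxels to the common 2 mm grid (rather than up-sampling) keeps
    interpolation bias low and gives texture features a uniform
    neighbourhood geometry.

    Raises :class:`EmptyRoiError` if the nodule is smaller than one target
    voxel and the resampled mask comes out empty; callers treating extraction
    failures as data should record this per case.
    """
    t = float(target_spacing)
    factors = np.asarray(case.spacing, dtype=float) / t
    if np.allclose(factors, 1.0, atol=1e-12):
        return ImageCase(case.case_id, case.volume.copy(), case.mask.copy(),
                         (t, t, t), case.status)
    new_shape = np.maximum(1, np.round(np.array(case.volume.shape) * factors)).astype(int)
    exact = new_shape / np.array(case.volume.shape)
    volume = ndimage.zoom(case.volume, exact, order=1, mode="nearest", grid_mode=True)
    mask = ndimage.zoom(case.mask.astype(np.float64), exact, order=1, mode="nearest",
                        grid_mode=True) >= 0.5
    if not mask.any():
        raise EmptyRoiError(
            f"{case.case_id}: resampled mask empty at {t} mm (nodule below one voxel)"
        )
    return ImageCase(case.case_id, volume, mask, (t, t, t), case.status)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


def partition_roi(case: ImageCase) -> RoiPartition:
    """Split the ROI into inner ~2/3 and outer ~1/3 by volume.

    The inner core is found by iterative binary erosion with a 6-connected
    element, stopping at the depth whose volume is nearest to 2/3 of the
    whole; equidistant depths resolve to the deeper (smaller) core.  If a
    single erosion already empties the mask the partition is degenerate: the
    voxel nearest the centroid becomes the inner core and a flag is set.
    """
    whole = case.mask.astype(bool)
    n_whole = int(whole.sum())
    target = 2.0 * n_whole / 3.0

    eroded = ndimage.binary_erosion(whole, structure=_STRUCT6)
    if not eroded.any():
        # degenerate: single-voxel core at the centroid
        idx = np.argwhere(whole)
        centroid = idx.mean(axis=0)
        center = idx[np.argmin(((idx - centroid) ** 2).sum(axis=1))]
        inner = np.zeros_like(whole)
        inner[tuple(center)] = True
        outer = whole & ~inner
        positive = whole & (case.volume > 0)
        return RoiPartition(whole, inner, outer, positive, degenerate=True, erosion_depth=0)

    best, best_depth, best_err = eroded, 1, abs(int(eroded.sum()) - target)
    current, depth = eroded, 1
    while True:
        nxt = ndimage.binary_erosion(current, structure=_STRUCT6)
        depth += 1
        err = abs(int(nxt.sum()) - target)
        if err <= best_err:  # tie -> deeper (smaller inner)
            best, best_depth, best_err = nxt, depth, err
        if not nxt.any():
            break
        current = nxt

    inner = best
    outer = whole & ~inner
    positive = whole & (case.volume > 0)
    return RoiPartition(whole, inner, outer, positive, degenerate=False,
                        erosion_depth=best_depth)
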