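"""Shared feature-value plumbing: failure-aware values and binning config."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: failure reasons a feature computation can record instead of raising
FAILURE_REASONS = ("none", "empty_roi", "too_few_voxels", "degenerate_matrix",
                   "fit_nonconvergence")


@dataclass(frozen=True)
class FeatureValue:
    """A named feature value or a marked failure (never an exception)."""

    value: float
    failure: str = "none"

    def __post_init__(self) -> None:
        if self.failure not in FAILURE_REASONS:
            raise ValueError(f"unknown failure reason {self.failure!r}")

    @property
    def failed(self) -> bool:
        return self.failure != "none"

    @staticmethod
    def ok(value: float) -> "FeatureValue":
        return FeatureValue(float(value))

    @staticmethod
    def fail(reason: str) -> "FeatureValue":
        return FeatureValue(math.nan, reason)


@dataclass(frozen=True)
class BinningSpec:
    """Histogram discretization settings for the panel.

    Histogram features bin over the fixed CT range [-1024, 3071] HU, so the
    default 4096 bins give exactly 1 HU per bin; GLCM and ISZM bin equal-width
    over the per-ROI min-max.
    """

    histogram_bins: int = 4096
    glcm_bins: int = 256
    iszm_bins: int = 32
    histogram_range: tuple[float, float] = (-1024.0, 3071.0)

    def __post_init__(self) -> None:
        for n in (self.histogram_bins, self.glcm_bins, self.iszm_bins):
            if n < 2:
                raise ValueError("all bin counts must be >= 2")


def fail_all(names, reason: str) -> dict[str, FeatureValue]:
    return {n: FeatureValue.fail(reason) for n in names}


def bin_minmax(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning over the sample min-max; returns levels 0..n_bins-1.

    A constant sample maps entirely to level 0 (single occupied level).
    """
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    levels = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(levels, 0, n_bins - 1)


def xlog2x_sum(p: np.ndarray) -> float:
    """-sum p*log2(p) with the 0*log0 := 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())
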