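"""Laplacian-of-Gaussian filter response statistics.

The volume is convolved with a 3D LoG at sigma = 0.5..3.5 voxels in 0.5
steps; within the mask, nine statistics are taken per scale.  Entropy and
uniformity use a 256-bin histogram over the response min-max.  Small sigmas
emphasize fine blob-like structure and are the scales that remain usable on
very small nodules.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from radrep.features._base import FeatureValue, fail_all, xlog2x_sum

SIGMAS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
LOG_STATS = ("mean", "sd", "skewness", "kurtosis", "minimum", "maximum",
             "energy", "entropy", "uniformity")
_ENTROPY_BINS = 256


def log_names(sigmas=SIGMAS):
    return [f"log.sigma_{s:.1f}.{stat}" for s in sigmas for stat in LOG_STATS]


def log_filter_features(volume: np.ndarray, mask: np.ndarray,
                        sigmas=SIGMAS) -> dict[str, FeatureValue]:
    """Nine response statistics per LoG scale (sigma in voxel units)."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        return fail_all(log_names(sigmas), "empty_roi")
    volume = np.asarray(volume, dtype=np.float64)
    out: dict[str, FeatureValue] = {}
    for s in sigmas:
        resp = ndimage.gaussian_laplace(volume, sigma=s)[mask]
        sd = float(resp.std())
        lo, hi = float(resp.min()), float(resp.max())
        if hi > lo:
            hist, _ = np.histogram(resp, bins=_ENTROPY_BINS, range=(lo, hi))
            p = hist / resp.size
            entropy, uniformity = xlog2x_sum(p), float((p ** 2).sum())
        else:
            entropy, uniformity = 0.0, 1.0
        values = {
            "mean": float(resp.mean()),
            "sd": sd,
            "skewness": float(stats.skew(resp)) if sd > 0 else 0.0,
            "kurtosis": float(stats.kurtosis(resp, fisher=False)) if sd > 0 else 0.0,
            "minimum": lo,
            "maximum": hi,
            "energy": float((resp ** 2).sum()),
            "entropy": entropy,
            "uniformity": uniformity,
        }
        for stat in LOG_STATS:
            out[f"log.sigma_{s:.1f}.{stat}"] = FeatureValue.ok(values[stat])
    return out
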