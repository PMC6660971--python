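"""First-order (histogram) intensity statistics on ROI sub-regions.

The full 19-statistic set is computed on the whole ROI; reduced subsets on
the positive-HU voxels (14), and on the inner core and outer rim (9 each);
the rim-minus-core difference (delta) gives a further 9.  Entropy and
uniformity are computed on the histogram binned over the fixed CT range so
that the bin width, not the sample, defines the discretization.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from radrep.features._base import BinningSpec, FeatureValue, fail_all, xlog2x_sum

#: the 19 whole-ROI statistics, in roster order
HIST_19 = (
    "mean", "sd", "variance", "skewness", "kurtosis", "minimum", "maximum",
    "range", "median", "p10", "p25", "p75", "p90", "iqr", "energy", "entropy",
    "uniformity", "rms", "mad",
)
#: the 9-statistic subset used for inner/outer/delta ROIs
HIST_9 = ("mean", "sd", "skewness", "kurtosis", "minimum", "maximum",
          "median", "energy", "entropy")
#: the 14-statistic subset used for the positive-voxel ROI
HIST_14 = tuple(n for n in HIST_19 if n not in ("variance", "mad", "p10", "p90", "rms"))


def _stats(x: np.ndarray, bins: BinningSpec) -> dict[str, float]:
    x = np.asarray(x, dtype=np.float64)
    sd = float(x.std())
    hist, _ = np.histogram(np.clip(x, *bins.histogram_range),
                           bins=bins.histogram_bins, range=bins.histogram_range)
    p = hist / x.size
    q10, q25, q50, q75, q90 = np.percentile(x, [10, 25, 50, 75, 90])
    return {
        "mean": float(x.mean()),
        "sd": sd,
        "variance": sd * sd,
        # moments of a constant sample are defined as 0, not propagated as NaN
        "skewness": float(stats.skew(x)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(x, fisher=False)) if sd > 0 else 0.0,
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "median": float(q50),
        "p10": float(q10),
        "p25": float(q25),
        "p75": float(q75),
        "p90": float(q90),
        "iqr": float(q75 - q25),
        # per-voxel (intensive) energy so rim-minus-core deltas compare
        # intensity distributions, not region sizes
        "energy": float((x ** 2).mean()),
        "entropy": xlog2x_sum(p),
        "uniformity": float((p ** 2).sum()),
        "rms": float(np.sqrt((x ** 2).mean())),
        "mad": float(np.abs(x - x.mean()).mean()),
    }


def histogram_features(intensities: np.ndarray, bins: BinningSpec,
                       subset=HIST_19) -> dict[str, FeatureValue]:
    """The named first-order statistics of an intensity sample.

    An empty sample yields every statistic FAILED(empty_roi).
    """
    intensities = np.asarray(intensities, dtype=np.float64).ravel()
    if intensities.size == 0:
        return fail_all(subset, "empty_roi")
    values = _stats(intensities, bins)
    return {n: FeatureValue.ok(values[n]) for n in subset}


def histogram_family(partition, volume: np.ndarray, bins: BinningSpec) -> dict[str, FeatureValue]:
    """All 60 histogram features: whole(19) + positive(14) + inner/outer/delta(9 each)."""
    out: dict[str, FeatureValue] = {}
    whole_vals = volume[partition.whole]
    for k, v in histogram_features(whole_vals, bins, HIST_19).items():
        out[f"histogram.whole.{k}"] = v
    pos_vals = volume[partition.positive]
    for k, v in histogram_features(pos_vals, bins, HIST_14).items():
        out[f"histogram.positive.{k}"] = v
    if partition.degenerate:
        for region in ("inner", "outer", "delta"):
            out.update({f"histogram.{region}.{k}": FeatureValue.fail("too_few_voxels")
                        for k in HIST_9})
        return out
    inner = histogram_features(volume[partition.inner], bins, HIST_9)
    outer = histogram_features(volume[partition.outer], bins, HIST_9)
    for k in HIST_9:
        out[f"histogram.inner.{k}"] = inner[k]
        out[f"histogram.outer.{k}"] = outer[k]
        if inner[k].failed or outer[k].failed:
            out[f"histogram.delta.{k}"] = FeatureValue.fail("too_few_voxels")
        else:
            out[f"histogram.delta.{k}"] = FeatureValue.ok(outer[k].value - inner[k].value)
    return out
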