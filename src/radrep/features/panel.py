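"""The full 252-feature panel: roster definition and per-case extraction.

Roster arithmetic under the default configuration:

    60  histogram   (19 whole + 14 positive + 9 inner + 9 outer + 9 delta)
    19  shape       (10 3D + 3 2D + 6 sigmoid margin)
    15  fractal     (1 box-counting + 7 lacunarity + 7 blanket signature)
    44  GLCM        (11 measures x whole/inner/outer/delta)
    44  GLCM        (same, on the 2x block-down-sampled ROI)
     2  ISZM
     5  NGTDM
    63  LoG filter  (9 statistics x 7 sigmas)
   ---
   252

Failures are recorded per feature and never raised; a feature vector always
has the full roster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from radrep.features._base import BinningSpec, FeatureValue
from radrep.features.fractal import fractal_features, fractal_names
from radrep.features.histogram import HIST_9, HIST_14, HIST_19, histogram_family
from radrep.features.logfilter import log_filter_features, log_names
from radrep.features.margin import margin_names, sigmoid_margin_features
from radrep.features.shape import SHAPE2D_NAMES, SHAPE3D_NAMES, shape2d_features, shape3d_features
from radrep.features.texture import (
    GLCM_MEASURES,
    ISZM_NAMES,
    NGTDM_NAMES,
    glcm_family,
    iszm_features,
    ngtdm_features,
)
from radrep.preprocess import ImageCase, partition_roi

#: feature families that depend on a histogram binning choice
BIN_DEPENDENT_FAMILIES = {
    "histogram": "histogram_bins",
    "glcm": "glcm_bins",
    "glcm_sub": "glcm_bins",
    "iszm": "iszm_bins",
}

FAMILIES = ("histogram", "shape", "fractal", "glcm", "glcm_sub", "iszm", "ngtdm", "log")


def default_roster() -> list[str]:
    """The ordered names of all 252 panel features."""
    names: list[str] = []
    names += [f"histogram.whole.{k}" for k in HIST_19]
    names += [f"histogram.positive.{k}" for k in HIST_14]
    for region in ("inner", "outer", "delta"):
        names += [f"histogram.{region}.{k}" for k in HIST_9]
    names += [f"shape3d.{k}" for k in SHAPE3D_NAMES]
    names += [f"shape2d.{k}" for k in SHAPE2D_NAMES]
    names += margin_names()
    names += fractal_names()
    for prefix in ("glcm", "glcm_sub"):
        for region in ("whole", "inner", "outer", "delta"):
            names += [f"{prefix}.{region}.{k}" for k in GLCM_MEASURES]
    names += [f"iszm.{k}" for k in ISZM_NAMES]
    names += [f"ngtdm.{k}" for k in NGTDM_NAMES]
    names += log_names()
    return names


def family_of(name: str) -> str:
    """Map a roster name to its family (shape3d/shape2d/margin -> 'shape')."""
    head = name.split(".", 1)[0]
    if head in ("shape3d", "shape2d", "margin"):
        return "shape"
    return head


@dataclass
class FeatureVector:
    """All panel values for one (case, extraction-setting) pair."""

    case_id: str
    setting_id: str
    values: dict[str, FeatureValue] = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return sum(v.failed for v in self.values.values())

    def value_series(self) -> pd.Series:
        return pd.Series({k: v.value for k, v in self.values.items()}, name=self.case_id)

    def failure_series(self) -> pd.Series:
        return pd.Series({k: v.failure for k, v in self.values.items()}, name=self.case_id)


def extract_all(case: ImageCase, bins: BinningSpec | None = None,
                setting_id: str = "default", families=None) -> FeatureVector:
    """Compute the feature panel for one case.

    ``families`` restricts extraction to a subset of
    :data:`FAMILIES` (used when sweeping a binning setting that only touches
    some families); the returned vector then holds only those features.
    Per-feature failures are recorded in the vector, never raised.
    """
    bins = bins or BinningSpec()
    wanted = set(FAMILIES if families is None else families)
    unknown = wanted - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")

    part = partition_roi(case)
    values: dict[str, FeatureValue] = {}
    if "histogram" in wanted:
        values.update(histogram_family(part, case.volume, bins))
    if "shape" in wanted:
        values.update(shape3d_features(case.mask, case.spacing))
        values.update(shape2d_features(case.mask, case.spacing))
        values.update(sigmoid_margin_features(case.volume, case.mask, case.spacing))
    if "fractal" in wanted:
        values.update(fractal_features(case.mask, case.volume))
    if "glcm" in wanted:
        values.update(glcm_family(part, case.volume, bins.glcm_bins, subsample=False))
    if "glcm_sub" in wanted:
        values.update(glcm_family(part, case.volume, bins.glcm_bins, subsample=True))
    if "iszm" in wanted:
        values.update(iszm_features(case.volume, part.whole, bins.iszm_bins))
    if "ngtdm" in wanted:
        values.update(ngtdm_features(case.volume, part.whole, bins.iszm_bins))
    if "log" in wanted:
        values.update(log_filter_features(case.volume, case.mask))

    if families is None:
        roster = default_roster()
        values = {name: values[name] for name in roster}
    return FeatureVector(case_id=case.case_id, setting_id=setting_id, values=values)


def vectors_to_frames(vectors) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack feature vectors into (values, failure-reasons) DataFrames.

    Failed entries are NaN in the values frame; the failures frame holds the
    reason strings ('none' where the value is present).
    """
    values = pd.DataFrame([v.value_series() for v in vectors])
    failures = pd.DataFrame([v.failure_series() for v in vectors])
    values.index.name = failures.index.name = "case_id"
    return values, failures


def write_feature_table(values: pd.DataFrame, failures: pd.DataFrame, path) -> None:
    """CSV serialization: failed cells empty, plus <name>__failure columns."""
    extra = {
        f"{col}__failure": failures[col].where(failures[col] != "none", "")
        for col in failures.columns
        if (failures[col] != "none").any()
    }
    pd.concat([values, pd.DataFrame(extra, index=values.index)], axis=1).to_csv(path)
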