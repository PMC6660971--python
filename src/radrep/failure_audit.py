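"""Audit of failed texture-feature computations.

Very small nodules lack the voxel neighbourhood structure that NGTDM and
sub-sampled GLCM features require.  The audit splits the cohort into an
error group (>= 1 failed feature of the audited family) and a non-error
group, compares 26 always-computable features (19 whole-ROI histogram + 7
shape) between the groups with one-tailed Welch t-tests, and derives
minimum-size guidelines from the 95% confidence interval of the size-related
features in the non-error group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from radrep.features.histogram import HIST_19

logger = logging.getLogger(__name__)

#: families whose failures the audit inspects, keyed to roster prefixes
AUDIT_FAMILIES = {"ngtdm": "ngtdm.", "subsampled_glcm": "glcm_sub."}

#: the 7 shape descriptors used for group comparison
AUDIT_SHAPE = (
    "shape3d.volume", "shape3d.max_3d_diameter", "shape3d.surface_area",
    "shape3d.surface_to_volume_ratio", "shape3d.compactness",
    "shape3d.sphericity", "shape3d.spherical_disproportion",
)


def audit_features() -> list[str]:
    """The 26 comparison features: 19 whole-ROI histogram + 7 shape."""
    return [f"histogram.whole.{k}" for k in HIST_19] + list(AUDIT_SHAPE)


@dataclass
class GroupComparison:
    family_audited: str
    feature_name: str
    mean_error: float
    mean_nonerror: float
    t_statistic: float
    one_sided_p: float
    ci95_nonerror: tuple[float, float]
    direction_tested: str  # {nonerror_greater, error_greater}


def split_error_groups(failures: pd.DataFrame, family: str):
    """Partition case ids by whether any feature of the family failed."""
    prefix = AUDIT_FAMILIES[family]
    cols = [c for c in failures.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"table has no {family} failure columns")
    is_error = (failures[cols] != "none").any(axis=1)
    return list(failures.index[is_error]), list(failures.index[~is_error])


def _mean_ci95(x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    m = x.mean()
    half = stats.t.ppf(0.975, n - 1) * x.std(ddof=1) / math.sqrt(n)
    return float(m - half), float(m + half)


def compare_groups(values: pd.DataFrame, error_ids, nonerror_ids,
                   family: str, features=None) -> list[GroupComparison]:
    """One-tailed Welch t-tests on the audit features between the groups.

    The tested direction follows the sign of the observed mean difference.
    Features with zero variance in both groups are skipped (logged); groups
    under 3 cases raise.
    """
    features = audit_features() if features is None else features
    if min(len(error_ids), len(nonerror_ids)) < 3:
        raise ValueError("each group needs >= 3 cases for the comparison")
    out: list[GroupComparison] = []
    for feat in features:
        err = values.loc[error_ids, feat].dropna().to_numpy()
        non = values.loc[nonerror_ids, feat].dropna().to_numpy()
        if len(err) < 3 or len(non) < 3:
            logger.info("audit: skipping %s (too few complete values)", feat)
            continue
        if err.std(ddof=1) == 0 and non.std(ddof=1) == 0:
            logger.info("audit: skipping %s (zero variance in both groups)", feat)
            continue
        direction = "nonerror_greater" if non.mean() >= err.mean() else "error_greater"
        alternative = "greater" if direction == "nonerror_greater" else "less"
        t, p = stats.ttest_ind(non, err, equal_var=False, alternative=alternative)
        out.append(GroupComparison(
            family_audited=family, feature_name=feat,
            mean_error=float(err.mean()), mean_nonerror=float(non.mean()),
            t_statistic=float(t), one_sided_p=float(p),
            ci95_nonerror=_mean_ci95(non), direction_tested=direction,
        ))
    return out


#: rounding-down precision (units of the feature) for each guideline
GUIDELINE_FEATURES = {
    "shape3d.volume": 100.0,  # mm^3
    "shape3d.max_3d_diameter": 1.0,  # mm
    "shape3d.surface_area": 10.0,  # mm^2
}


def recommend_thresholds(comparisons: list[GroupComparison]) -> dict[str, float]:
    """Minimum-size guidelines from the non-error group's 95% CI lower bound.

    Each size-related feature's recommended minimum is the lower CI bound
    of the non-error group, rounded down to a feature-appropriate precision
    (e.g. a volume CI lower bound of 1045 mm^3 becomes a >= 1000 mm^3
    guideline).
    """
    guidelines: dict[str, float] = {}
    for comp in comparisons:
        step = GUIDELINE_FEATURES.get(comp.feature_name)
        if step is None:
            continue
        lo = comp.ci95_nonerror[0]
        guidelines[comp.feature_name] = math.floor(lo / step) * step
    return guidelines


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({
            "family": c.family_audited, "feature": c.feature_name,
            "mean_error": c.mean_error, "mean_nonerror": c.mean_nonerror,
            "t": c.t_statistic, "one_sided_p": c.one_sided_p,
            "ci95_low": c.ci95_nonerror[0], "ci95_high": c.ci95_nonerror[1],
            "direction": c.direction_tested,
        })
    return pd.DataFrame(rows)
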