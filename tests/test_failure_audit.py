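"""Failure-audit group splits, Welch t statistics and CI-based guidelines."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radrep.failure_audit import (
    GroupComparison,
    audit_features,
    compare_groups,
    recommend_thresholds,
    split_error_groups,
)


def test_audit_roster_is_26():
    feats = audit_features()
    assert len(feats) == 26
    assert sum(f.startswith("histogram.whole.") for f in feats) == 19
    assert sum(f.startswith("shape3d.") for f in feats) == 7


def _failure_frame(ids, error_ids):
    cols = ["ngtdm.coarseness", "ngtdm.contrast", "glcm_sub.whole.energy"]
    df = pd.DataFrame("none", index=ids, columns=cols)
    df.loc[error_ids, "ngtdm.coarseness"] = "too_few_voxels"
    return df


def test_split_matches_planted_failures():
    ids = [f"c{i}" for i in range(10)]
    fails = _failure_frame(ids, ["c1", "c4"])
    err, non = split_error_groups(fails, "ngtdm")
    assert set(err) == {"c1", "c4"}
    assert set(non) == set(ids) - {"c1", "c4"}
    # no sub-sampled GLCM failures -> empty error group there
    err2, _ = split_error_groups(fails, "subsampled_glcm")
    assert err2 == []


def test_small_nodules_are_the_error_group():
    """On a synthetic cohort the NGTDM error group is exactly the small-nodule set."""
    from radrep.features import extract_all, vectors_to_frames
    from radrep.preprocess import resample_isotropic
    from radrep.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_cases=16, class_balance=0.5, small_nodule_fraction=0.375,
                       rng_seed=17)
    cases, truth = generate_cohort(cfg)
    vectors = []
    for case in cases:
        vectors.append(extract_all(resample_isotropic(case, 2.0)))
    values, fails = vectors_to_frames(vectors)
    err, non = split_error_groups(fails, "ngtdm")
    small_ids = set(truth.index[truth.small_nodule])
    assert set(err) == small_ids


def _toy_values(ids_err, ids_non, err_vals, non_vals, feature="shape3d.volume"):
    values = pd.DataFrame(index=ids_err + ids_non, columns=audit_features(),
                          dtype=float)
    values[:] = 1.0
    values.loc[ids_err, feature] = err_vals
    values.loc[ids_non, feature] = non_vals
    return values


def test_hand_computed_t_and_ci():
    """3 + 3 cases: Welch t and the non-error CI match closed forms."""
    err_ids, non_ids = ["e1", "e2", "e3"], ["n1", "n2", "n3"]
    err_vals, non_vals = [400.0, 470.0, 540.0], [1000.0, 1200.0, 1400.0]
    values = _toy_values(err_ids, non_ids, err_vals, non_vals)
    comps = compare_groups(values, err_ids, non_ids, "ngtdm",
                           features=["shape3d.volume"])
    assert len(comps) == 1
    c = comps[0]
    t_ref, p_ref = stats.ttest_ind(non_vals, err_vals, equal_var=False,
                                   alternative="greater")
    assert c.t_statistic == pytest.approx(float(t_ref))
    assert c.one_sided_p == pytest.approx(float(p_ref))
    # hand CI: mean 1200, sd 200, t_{0.975,2} = 4.3027 -> 1200 +/- 496.84
    half = 4.302652729911275 * 200.0 / np.sqrt(3)
    assert c.ci95_nonerror[0] == pytest.approx(1200.0 - half, rel=1e-6)
    assert c.ci95_nonerror[1] == pytest.approx(1200.0 + half, rel=1e-6)
    assert c.direction_tested == "nonerror_greater"


def test_direction_follows_observed_sign():
    err_ids, non_ids = ["e1", "e2", "e3"], ["n1", "n2", "n3"]
    values = _toy_values(err_ids, non_ids, [10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
    c = compare_groups(values, err_ids, non_ids, "ngtdm",
                       features=["shape3d.volume"])[0]
    assert c.direction_tested == "error_greater"
    assert c.one_sided_p < 0.05


def test_groups_below_three_rejected():
    values = _toy_values(["e1"], ["n1", "n2", "n3"], [1.0], [2.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        compare_groups(values, ["e1"], ["n1", "n2", "n3"], "ngtdm")


def test_guideline_is_floored_ci_lower_bound():
    comp = GroupComparison(
        family_audited="ngtdm", feature_name="shape3d.volume",
        mean_error=470.0, mean_nonerror=1228.0, t_statistic=5.0,
        one_sided_p=1e-5, ci95_nonerror=(1045.5, 1412.3),
        direction_tested="nonerror_greater")
    out = recommend_thresholds([comp])
    assert out["shape3d.volume"] == 1000.0


def test_guideline_deterministic_toy_sample():
    """{1000, 1200, 1400}: guideline = floor of the hand-computed t-interval."""
    err_ids, non_ids = ["e1", "e2", "e3"], ["n1", "n2", "n3"]
    values = _toy_values(err_ids, non_ids, [1.0, 2.0, 3.0], [1000.0, 1200.0, 1400.0])
    comps = compare_groups(values, err_ids, non_ids, "ngtdm",
                           features=["shape3d.volume"])
    out = recommend_thresholds(comps)
    lo = 1200.0 - 4.302652729911275 * 200.0 / np.sqrt(3)  # 703.16
    assert out["shape3d.volume"] == np.floor(lo / 100) * 100 == 700.0


def test_type_i_error_calibrated_small():
    """Null groups from one distribution: rejection rate stays near 5%."""
    rng = np.random.default_rng(0)
    rejections = 0
    reps = 200
    for _ in range(reps):
        err = rng.normal(size=25)
        non = rng.normal(size=25)
        direction = "greater" if non.mean() >= err.mean() else "less"
        _, p = stats.ttest_ind(non, err, equal_var=False, alternative=direction)
        rejections += p < 0.05
    # one-sided test in the data-chosen direction doubles the nominal rate
    assert rejections / reps == pytest.approx(0.10, abs=0.05)
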