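"""Reproducibility screening and signature selection.

Features are screened by the intra-class correlation between two extraction
settings (two-way random-effects, absolute-agreement, single-measurement
ICC, the settings acting as raters); features with ICC >= 0.7 pass.  Within
the passing set an L1-penalized logistic regression (LASSO) selects the
features that explain nodule status per setting, and the cross-setting
intersection forms the signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class SettingPair:
    """Two feature tables over the same case set, one per extraction setting."""

    setting_a: str
    setting_b: str
    table_a: pd.DataFrame
    table_b: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table_a.index.equals(self.table_b.index):
            raise ValueError("setting pair requires identical case ids")
        if list(self.table_a.columns) != list(self.table_b.columns):
            raise ValueError("setting pair requires an identical feature roster")


@dataclass
class SignatureReport:
    """ICC map, per-setting LASSO selections, and their intersection."""

    icc_per_feature: dict[str, float]
    icc_pass_set: list[str]
    lasso_selected: dict[str, list[str]]
    signature: list[str]
    provenance: dict = field(default_factory=dict)


def icc(paired: np.ndarray) -> float | None:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    ``paired`` is (n cases x k measurements); rows with any NaN are dropped
    pairwise.  Returns None when fewer than 3 complete rows remain; returns
    1.0 for identical constant measurements (zero total variance).
    """
    x = np.asarray(paired, dtype=np.float64)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        return None
    grand = x.mean()
    if np.allclose(x, grand):
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_r = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_e = (resid ** 2).sum() / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        return 1.0
    return float((ms_r - ms_e) / denom)


def icc_screen(pair: SettingPair, threshold: float = 0.7):
    """ICC per feature across the two settings; keep those >= threshold.

    Features with fewer than 3 complete pairs are excluded (logged).
    Returns ``(pass_list, icc_map)`` with the pass list in roster order.
    """
    icc_map: dict[str, float] = {}
    passed: list[str] = []
    for col in pair.table_a.columns:
        value = icc(np.column_stack([pair.table_a[col], pair.table_b[col]]))
        if value is None:
            logger.info("ICC undefined for %s (fewer than 3 complete pairs)", col)
            continue
        icc_map[col] = value
        if value >= threshold:
            passed.append(col)
    return passed, icc_map


def lasso_select(table: pd.DataFrame, status: pd.Series, seed: int = 0,
                 folds: int = 10, Cs: int = 25) -> list[str]:
    """Features with nonzero coefficients in a CV-tuned L1 logistic model.

    ``table`` should be z-scored and restricted to ICC-passing features;
    cases with any missing candidate value are dropped (complete-case,
    logged).  The penalty is chosen by stratified ``folds``-fold CV at the
    minimum mean deviance with a fixed fold seed.
    """
    complete = table.notna().all(axis=1)
    if (~complete).any():
        logger.info("lasso_select: dropping %d incomplete cases", int((~complete).sum()))
    X = table.loc[complete]
    y = (status.loc[X.index] == "malignant").astype(int).to_numpy()
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("lasso_select requires >= 2 cases per class")
    n_splits = min(folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        l1_ratios=(1.0,), solver="liblinear", Cs=np.logspace(-2.5, 1.5, Cs),
        cv=cv, scoring="neg_log_loss", max_iter=2000, refit=True,
        random_state=seed, use_legacy_attributes=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X.to_numpy(), y)
    coef = model.coef_.ravel()
    selected = [c for c, w in zip(X.columns, coef) if abs(w) > 1e-8]
    if not selected:
        logger.warning("lasso_select: no penalty yielded a nonzero model")
    return selected


def intersect_signatures(selections: dict[str, list[str]],
                         roster: list[str] | None = None) -> list[str]:
    """Intersection of per-setting selections, in deterministic roster order."""
    if len(selections) < 2:
        raise ValueError("need selections from at least 2 settings")
    sets = [set(s) for s in selections.values()]
    common = set.intersection(*sets)
    if not common:
        logger.warning("signature intersection is empty")
    order = roster if roster is not None else sorted(common)
    ordered = [f for f in order if f in common]
    # features outside the supplied roster keep a sorted deterministic tail
    ordered += sorted(common - set(ordered))
    return ordered
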