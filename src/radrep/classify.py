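"""Random-forest validation of a feature signature.

A 200-tree random forest is trained on the training cohort restricted to
the signature features and evaluated on the held-out test cohort with ROC
metrics (malignant = positive class).  Feature contribution is assessed by
out-of-bag permutation importance: the mean decrease in OOB accuracy when a
feature is permuted, averaged over trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.utils import check_random_state

POSITIVE = "malignant"


@dataclass
class ClassificationMetrics:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: list[tuple[float, float]]
    threshold_used: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN

    def as_dict(self) -> dict:
        return {"auc": self.auc, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "threshold": self.threshold_used}


@dataclass
class FittedModel:
    forest: RandomForestClassifier
    features: list[str]
    train_X: np.ndarray
    train_y: np.ndarray


def _encode(status: pd.Series) -> np.ndarray:
    return (status == POSITIVE).astype(int).to_numpy()


def train_rf(train_table: pd.DataFrame, status: pd.Series, n_trees: int = 200,
             seed: int = 0) -> FittedModel:
    """Fit a seeded 200-tree random forest on the signature columns.

    Complete-case: rows with missing signature values are dropped.  Raises
    on single-class training data.
    """
    complete = train_table.notna().all(axis=1)
    X = train_table.loc[complete]
    y = _encode(status.loc[X.index])
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        random_state=seed, n_jobs=1, bootstrap=True,
    )
    forest.fit(X.to_numpy(), y)
    return FittedModel(forest=forest, features=list(train_table.columns),
                       train_X=X.to_numpy(), train_y=y)


def evaluate(model: FittedModel, test_table: pd.DataFrame, status: pd.Series,
             threshold: float = 0.5) -> ClassificationMetrics:
    """ROC metrics on a held-out cohort at the given probability threshold."""
    complete = test_table.notna().all(axis=1)
    X = test_table.loc[complete, model.features]
    y = _encode(status.loc[X.index])
    if len(np.unique(y)) < 2:
        raise ValueError("test data must contain both classes for ROC metrics")
    scores = model.forest.predict_proba(X.to_numpy())[:, 1]
    fpr, tpr, _ = roc_curve(y, scores)
    auc_value = float(trapezoid_auc(fpr, tpr))
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ClassificationMetrics(
        auc=auc_value,
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        threshold_used=threshold,
        confusion=(tp, fp, tn, fn),
    )


def _bootstrap_indices(tree_state, n: int) -> np.ndarray:
    # replicates sklearn's per-tree bootstrap draw
    return check_random_state(tree_state).randint(0, n, n)


def oob_importance(model: FittedModel, seed: int = 0) -> pd.Series:
    """Per-feature mean decrease in OOB accuracy under permutation.

    For each tree, accuracy on its out-of-bag samples is compared with the
    accuracy after permuting one feature column (seeded); the decrease is
    averaged over trees.  Deterministic for a fixed model and seed.
    """
    X, y = model.train_X, model.train_y
    n = len(y)
    rng = np.random.default_rng(seed)
    drops = np.zeros((len(model.forest.estimators_), X.shape[1]))
    for t, tree in enumerate(model.forest.estimators_):
        oob = np.ones(n, dtype=bool)
        oob[_bootstrap_indices(tree.random_state, n)] = False
        if not oob.any():
            continue
        Xo, yo = X[oob], y[oob]
        base = (tree.predict(Xo) == yo).mean()
        for j in range(X.shape[1]):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            drops[t, j] = base - (tree.predict(Xp) == yo).mean()
    return pd.Series(drops.mean(axis=0), index=model.features, name="oob_importance")
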