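"""Z-score normalization of feature tables using training-set parameters."""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)


def zscore_normalize(train: pd.DataFrame, apply: pd.DataFrame | None = None):
    """Normalize each feature column to z-scores using training mean/SD.

    NaN (failed) entries stay NaN.  Features whose training SD is zero are
    constant and excluded from both outputs (logged); SD uses ddof=1.

    Returns ``(train_z, apply_z, params, excluded)`` where ``params`` has one
    row per retained feature with its training mean and SD.
    """
    mean = train.mean(skipna=True)
    sd = train.std(skipna=True, ddof=1)
    n_ok = train.notna().sum()
    constant = (sd == 0) | sd.isna() | (n_ok < 2)
    excluded = list(train.columns[constant])
    if excluded:
        logger.warning("excluding %d constant/undersampled features from normalization",
                       len(excluded))
    keep = [c for c in train.columns if c not in set(excluded)]
    params = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    train_z = (train[keep] - mean[keep]) / sd[keep]
    apply_z = None if apply is None else (apply[keep] - mean[keep]) / sd[keep]
    return train_z, apply_z, params, excluded
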