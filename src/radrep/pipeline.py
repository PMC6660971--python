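"""End-to-end orchestration: voxel-geometry experiment, binning experiment,
and the failure audit, with persisted intermediates and a provenance manifest.

The training and test cohorts are independent (mirroring an external-
validation design with separate local and public cohorts) rather than a
split of one cohort.  Every stage consumes and emits plain CSV/JSON so each
is independently re-runnable; identical configuration reproduces identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from radrep.classify import evaluate, oob_importance, train_rf
from radrep.errors import EmptyRoiError, RadrepError
from radrep.failure_audit import (
    AUDIT_FAMILIES,
    compare_groups,
    comparisons_to_frame,
    recommend_thresholds,
    split_error_groups,
)
from radrep.features import (
    BinningSpec,
    default_roster,
    extract_all,
    vectors_to_frames,
    write_feature_table,
    zscore_normalize,
)
from radrep.preprocess import ImageCase, load_case, resample_isotropic
from radrep.reproducibility import (
    SettingPair,
    SignatureReport,
    icc_screen,
    intersect_signatures,
    lasso_select,
)
from radrep.synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

BIN_SWEEP_FAMILIES = ("glcm", "glcm_sub")


@dataclass
class RunConfig:
    """Study configuration: cohorts, settings, thresholds and seeds."""

    train_cohort: CohortConfig = field(default_factory=lambda: CohortConfig(rng_seed=11))
    test_cohort: CohortConfig = field(
        default_factory=lambda: CohortConfig(n_cases=80, class_balance=50.0 / 80.0,
                                             rng_seed=23))
    iso_spacing: float = 2.0
    bins: BinningSpec = field(default_factory=BinningSpec)
    glcm_sweep: tuple[int, ...] = (32, 64, 128)
    icc_threshold: float = 0.7
    max_failure_rate: float = 0.2  # features failing more often are not analyzed
    lasso_seed: int = 7
    lasso_folds: int = 10
    rf_trees: int = 200
    rf_seed: int = 13
    out_dir: str = "radrep_out"

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, cls in (("train_cohort", CohortConfig), ("test_cohort", CohortConfig),
                         ("bins", BinningSpec)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = cls(**kwargs[key])
        if "glcm_sweep" in kwargs:
            kwargs["glcm_sweep"] = tuple(kwargs["glcm_sweep"])
        return RunConfig(**kwargs)

    def to_jsonable(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=str))


def load_cohort_dir(directory) -> tuple[list[ImageCase], pd.DataFrame]:
    """Load a directory of <id>_image/<id>_mask pairs plus truth.csv."""
    truth = pd.read_csv(os.path.join(directory, "truth.csv"), index_col="case_id")
    cases = []
    for case_id, row in truth.iterrows():
        paths = {}
        for kind in ("image", "mask"):
            for ext in (".nrrd", ".nii.gz", ".nii"):
                p = os.path.join(directory, f"{case_id}_{kind}{ext}")
                if os.path.exists(p):
                    paths[kind] = p
                    break
        if len(paths) < 2:
            raise RadrepError(f"missing image/mask files for {case_id}")
        cases.append(load_case(paths["image"], paths["mask"],
                               status=row["status"], case_id=str(case_id)))
    return cases, truth


def extract_table(cases: list[ImageCase], bins: BinningSpec, setting_id: str,
                  iso_spacing: float | None = None):
    """Extract the panel for every case; returns (values, failures, exclusions).

    With ``iso_spacing`` each case is first resampled; cases whose mask
    vanishes at the target spacing are excluded and recorded.
    """
    vectors, exclusions = [], []
    for case in cases:
        work = case
        if iso_spacing is not None:
            try:
                work = resample_isotropic(case, iso_spacing)
            except EmptyRoiError as exc:
                exclusions.append({"case_id": case.case_id, "stage": setting_id,
                                   "reason": str(exc)})
                continue
        vectors.append(extract_all(work, bins, setting_id=setting_id))
    values, failures = vectors_to_frames(vectors)
    return values, failures, exclusions


def _statuses(cases: list[ImageCase]) -> pd.Series:
    return pd.Series({c.case_id: c.status for c in cases}, name="status")


def _analyzable(tables: list[pd.DataFrame], max_failure_rate: float) -> list[str]:
    """Features whose failure (NaN) rate stays within bounds in every table.

    Mirrors dropping whole feature groups with high error rates before any
    reproducibility analysis; the remaining occasional failures are handled
    by pairwise/complete-case deletion downstream.
    """
    keep = tables[0].columns
    for tab in tables:
        rate = tab.isna().mean()
        keep = [c for c in keep if rate[c] <= max_failure_rate]
    return list(keep)


def _select_for_setting(values: pd.DataFrame, status: pd.Series, candidates,
                        seed: int, folds: int):
    """Z-score then LASSO-select within the candidate features.

    If complete-case deletion over the candidates would leave fewer than two
    cases of a class, the candidate set is narrowed to fully complete
    columns instead (logged), keeping the cohort.
    """
    table = values[candidates]
    y = status.loc[table.index]
    complete = table.notna().all(axis=1)
    counts = y[complete].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        full_cols = table.columns[table.notna().all(axis=0)]
        logger.warning("complete-case deletion too destructive; restricting to "
                       "%d fully observed candidate features", len(full_cols))
        table = table[full_cols]
    train_z, _, params, excluded = zscore_normalize(table)
    selected = lasso_select(train_z, status, seed=seed, folds=folds)
    return selected, params, excluded


def _classify_setting(train_vals, test_vals, train_status, test_status,
                      signature, cfg: RunConfig, seed_offset: int = 0):
    train_z, test_z, _, _ = zscore_normalize(train_vals[signature], test_vals[signature])
    model = train_rf(train_z, train_status, n_trees=cfg.rf_trees,
                     seed=cfg.rf_seed + seed_offset)
    metrics = evaluate(model, test_z, test_status)
    importance = oob_importance(model, seed=cfg.rf_seed + seed_offset)
    return model, metrics, importance


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_experiment1(cfg: RunConfig, train_cases, test_cases, out_dir=None):
    """Original-vs-isotropic voxel geometry: screen, select, intersect, classify."""
    roster = default_roster()
    train_status, test_status = _statuses(train_cases), _statuses(test_cases)
    tables = {}
    exclusions = []
    for setting, iso in (("original", None), ("isotropic", cfg.iso_spacing)):
        tr = extract_table(train_cases, cfg.bins, setting, iso_spacing=iso)
        te = extract_table(test_cases, cfg.bins, setting, iso_spacing=iso)
        tables[setting] = {"train": tr[:2], "test": te[:2]}
        exclusions += tr[2] + te[2]

    # pair on the cases extracted under both settings; screen only the
    # features whose failure rate is analyzable
    common = tables["original"]["train"][0].index.intersection(
        tables["isotropic"]["train"][0].index)
    candidates = _analyzable(
        [tables[s]["train"][0].loc[common] for s in ("original", "isotropic")],
        cfg.max_failure_rate)
    pair = SettingPair("original", "isotropic",
                       tables["original"]["train"][0].loc[common, candidates],
                       tables["isotropic"]["train"][0].loc[common, candidates])
    pass_set, icc_map = icc_screen(pair, threshold=cfg.icc_threshold)

    selections, metrics, importances = {}, {}, {}
    for setting in ("original", "isotropic"):
        train_vals = tables[setting]["train"][0]
        selected, _, _ = _select_for_setting(train_vals, train_status, pass_set,
                                             cfg.lasso_seed, cfg.lasso_folds)
        selections[setting] = selected

    signature = intersect_signatures(selections, roster=roster)
    report = SignatureReport(
        icc_per_feature=icc_map, icc_pass_set=pass_set,
        lasso_selected=selections, signature=signature,
        provenance={"icc_threshold": cfg.icc_threshold, "lasso_seed": cfg.lasso_seed,
                    "rf_seed": cfg.rf_seed, "iso_spacing": cfg.iso_spacing},
    )
    if signature:
        for i, setting in enumerate(("original", "isotropic")):
            _, m, imp = _classify_setting(
                tables[setting]["train"][0], tables[setting]["test"][0],
                train_status, test_status, signature, cfg, seed_offset=0)
            metrics[setting] = m
            importances[setting] = imp
    else:
        logger.warning("experiment 1: empty signature, classifier stage skipped")

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        pd.Series(icc_map, name="icc").to_csv(os.path.join(out_dir, "icc.csv"))
        for setting in tables:
            write_feature_table(*tables[setting]["train"],
                                os.path.join(out_dir, f"features_train_{setting}.csv"))
            write_feature_table(*tables[setting]["test"],
                                os.path.join(out_dir, f"features_test_{setting}.csv"))
            with open(os.path.join(out_dir, f"selected_{setting}.txt"), "w") as fh:
                fh.write("\n".join(selections[setting]) + "\n")
            if setting in metrics:
                _write_json(metrics[setting].as_dict(),
                            os.path.join(out_dir, f"metrics_{setting}.json"))
                importances[setting].to_csv(
                    os.path.join(out_dir, f"importance_{setting}.csv"))
        with open(os.path.join(out_dir, "signature.txt"), "w") as fh:
            fh.write("\n".join(signature) + "\n")
        pd.DataFrame(exclusions).to_csv(os.path.join(out_dir, "exclusions.csv"),
                                        index=False)
    return report, metrics, tables


def _swap_bin_families(cases, base_values, base_failures, bins: BinningSpec,
                       setting_id: str, iso_spacing: float):
    """Recompute only the GLCM families at swept bins; splice into the table."""
    vectors = []
    for case in cases:
        try:
            work = resample_isotropic(case, iso_spacing)
        except EmptyRoiError:
            continue
        vectors.append(extract_all(work, bins, setting_id=setting_id,
                                   families=BIN_SWEEP_FAMILIES))
    new_vals, new_fails = vectors_to_frames(vectors)
    values = base_values.copy()
    failures = base_failures.copy()
    idx = values.index.intersection(new_vals.index)
    values.loc[idx, new_vals.columns] = new_vals.loc[idx]
    failures.loc[idx, new_fails.columns] = new_fails.loc[idx]
    return values, failures


def run_experiment2(cfg: RunConfig, train_cases, test_cases,
                    iso_tables=None, out_dir=None):
    """Default-vs-changed GLCM binning at the fixed isotropic geometry.

    Histogram and ISZM features stay at their default bins; only the GLCM
    bin count sweeps.  The signature is the intersection of the per-sweep
    LASSO selections.
    """
    roster = default_roster()
    train_status, test_status = _statuses(train_cases), _statuses(test_cases)
    if iso_tables is None:
        tr = extract_table(train_cases, cfg.bins, "isotropic", iso_spacing=cfg.iso_spacing)
        te = extract_table(test_cases, cfg.bins, "isotropic", iso_spacing=cfg.iso_spacing)
        iso_tables = {"train": tr[:2], "test": te[:2]}

    base_train_vals, base_train_fails = iso_tables["train"]
    base_test_vals, base_test_fails = iso_tables["test"]

    selections, metrics, icc_maps, sweep_tables = {}, {}, {}, {}
    for b in cfg.glcm_sweep:
        setting = f"glcm{b}"
        bins_b = BinningSpec(histogram_bins=cfg.bins.histogram_bins,
                             glcm_bins=b, iszm_bins=cfg.bins.iszm_bins)
        train_b = _swap_bin_families(train_cases, base_train_vals, base_train_fails,
                                     bins_b, setting, cfg.iso_spacing)
        test_b = _swap_bin_families(test_cases, base_test_vals, base_test_fails,
                                    bins_b, setting, cfg.iso_spacing)
        sweep_tables[setting] = {"train": train_b, "test": test_b}
        candidates = _analyzable([base_train_vals, train_b[0]], cfg.max_failure_rate)
        pair = SettingPair("default", setting, base_train_vals[candidates],
                           train_b[0][candidates])
        pass_set, icc_map = icc_screen(pair, threshold=cfg.icc_threshold)
        icc_maps[setting] = icc_map
        selected, _, _ = _select_for_setting(train_b[0], train_status, pass_set,
                                             cfg.lasso_seed, cfg.lasso_folds)
        selections[setting] = selected

    signature = intersect_signatures(selections, roster=roster)
    report = SignatureReport(
        icc_per_feature=icc_maps[f"glcm{cfg.glcm_sweep[0]}"],
        icc_pass_set=sorted(set.intersection(*(set(
            [f for f, v in icc_maps[f"glcm{b}"].items() if v >= cfg.icc_threshold])
            for b in cfg.glcm_sweep))),
        lasso_selected=selections, signature=signature,
        provenance={"glcm_sweep": list(cfg.glcm_sweep),
                    "icc_threshold": cfg.icc_threshold, "lasso_seed": cfg.lasso_seed},
    )
    if signature:
        for b in cfg.glcm_sweep:
            setting = f"glcm{b}"
            _, m, _ = _classify_setting(
                sweep_tables[setting]["train"][0], sweep_tables[setting]["test"][0],
                train_status, test_status, signature, cfg, seed_offset=0)
            metrics[setting] = m
    else:
        logger.warning("experiment 2: empty signature, classifier stage skipped")

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        for setting, icc_map in icc_maps.items():
            pd.Series(icc_map, name="icc").to_csv(
                os.path.join(out_dir, f"icc_{setting}.csv"))
            with open(os.path.join(out_dir, f"selected_{setting}.txt"), "w") as fh:
                fh.write("\n".join(selections[setting]) + "\n")
            if setting in metrics:
                _write_json(metrics[setting].as_dict(),
                            os.path.join(out_dir, f"metrics_{setting}.json"))
        with open(os.path.join(out_dir, "signature.txt"), "w") as fh:
            fh.write("\n".join(signature) + "\n")
    return report, metrics


def run_audit(values: pd.DataFrame, failures: pd.DataFrame, out_dir=None):
    """Failure audit over both inspected families; returns comparisons and guidelines."""
    results = {}
    guidelines = {}
    for family in AUDIT_FAMILIES:
        error_ids, nonerror_ids = split_error_groups(failures, family)
        if min(len(error_ids), len(nonerror_ids)) < 3:
            logger.warning("audit %s skipped: one group has < 3 cases "
                           "(%d error / %d non-error)", family,
                           len(error_ids), len(nonerror_ids))
            continue
        comparisons = compare_groups(values, error_ids, nonerror_ids, family)
        results[family] = comparisons
        guidelines[family] = recommend_thresholds(comparisons)
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            comparisons_to_frame(comparisons).to_csv(
                os.path.join(out_dir, f"failure_audit_{family}.csv"), index=False)
    if out_dir and guidelines:
        _write_json(guidelines, os.path.join(out_dir, "guidelines.json"))
    return results, guidelines


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Simulate both cohorts, run both experiments and the audit; write a manifest."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    train_cases, train_truth = generate_cohort(cfg.train_cohort)
    test_cases, test_truth = generate_cohort(cfg.test_cohort)
    train_truth.to_csv(os.path.join(cfg.out_dir, "truth_train.csv"))
    test_truth.to_csv(os.path.join(cfg.out_dir, "truth_test.csv"))

    exp1_dir = os.path.join(cfg.out_dir, "exp1")
    report1, metrics1, tables = run_experiment1(cfg, train_cases, test_cases,
                                                out_dir=exp1_dir)
    exp2_dir = os.path.join(cfg.out_dir, "exp2")
    iso_tables = {"train": tables["isotropic"]["train"],
                  "test": tables["isotropic"]["test"]}
    report2, metrics2 = run_experiment2(cfg, train_cases, test_cases,
                                        iso_tables=iso_tables, out_dir=exp2_dir)

    audit_dir = os.path.join(cfg.out_dir, "audit")
    # audit on the native-geometry training extraction, where small-nodule
    # failures actually occur
    audit_vals, audit_fails = tables["original"]["train"]
    _, guidelines = run_audit(audit_vals, audit_fails, out_dir=audit_dir)

    manifest = {
        "config": cfg.to_jsonable(),
        "signature_exp1": report1.signature,
        "signature_exp2": report2.signature,
        "metrics_exp1": {k: m.as_dict() for k, m in metrics1.items()},
        "metrics_exp2": {k: m.as_dict() for k, m in metrics2.items()},
        "guidelines": guidelines,
        "checksums": {},
    }
    for root, _, files in os.walk(cfg.out_dir):
        for name in sorted(files):
            if name == "manifest.json":
                continue
            p = os.path.join(root, name)
            manifest["checksums"][os.path.relpath(p, cfg.out_dir)] = _sha256(p)
    _write_json(manifest, os.path.join(cfg.out_dir, "manifest.json"))
    return manifest
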