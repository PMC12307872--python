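"""Desk-scale end-to-end synthetic study runner.

Simulates a small two-sensor T2D cohort, preprocesses it onto the common
5-min grid, builds windows per prediction horizon, and runs leave-one-day-out
cross-validation for unimodal and multimodal forecasters plus the last-value
persistence baseline. This is the scaled-down analogue of the full cohort
experiment: 12 patients over 10 days, a slimmed network, and a subset of the
folds, sized so the whole comparison runs in minutes on one CPU core (the
architecture, preprocessing and validation protocol are unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess, synth
from .evaluate import (FoldResult, cross_validate, mean_absolute_point_error,
                       persistence_predictions, pool_fold_results,
                       stratified_metrics)
from .nn.network import ModelConfig
from .synth import VARIABLE_SETS, SyntheticCohortConfig
from .windows import HorizonSpec, WindowedDataset, make_windows

# Scaled-down study conditions (fixed; see docs/methods.md).
STUDY_COHORT = dict(n_patients=12, n_sensor1=4, duration_days=(10, 10),
                    missing_fraction=0.05, baseline_effect_scale=1.0,
                    attrition=False)
STUDY_MODEL = dict(lstm_hidden=16, cnn_filters=24, baseline_hidden=(16, 8),
                   fusion_hidden=32, epochs=40, batch_size=128,
                   learning_rate=3e-3, variable_set=1)
STUDY_FOLD_SUBSET = [3, 7]          # of the 10 leave-one-day-out folds
STUDY_MAX_TRAIN_WINDOWS = 12000


def prepare_cohort_windows(cohort_config: SyntheticCohortConfig,
                           horizons: list[int]
                           ) -> tuple[dict[int, WindowedDataset], pd.DataFrame]:
    """Simulate, preprocess and window a cohort for each horizon (mg/dL)."""
    series_list, baseline_df, _truth = synth.simulate_cohort(cohort_config)
    prepared = []
    for s in series_list:
        if preprocess.is_excluded(s):
            continue
        s5 = preprocess.resample_to_grid(s)
        prepared.append(preprocess.interpolate_missing(s5))
    datasets = {}
    for h in horizons:
        spec = HorizonSpec(h)
        datasets[h] = WindowedDataset.concatenate(
            [make_windows(s, spec) for s in prepared])
    return datasets, baseline_df


def baseline_matrix(dataset: WindowedDataset, baseline_df: pd.DataFrame,
                    variable_set: int) -> np.ndarray:
    """Per-window raw baseline vectors for the active variable set."""
    cols = VARIABLE_SETS[variable_set]
    table = baseline_df[cols]
    return table.loc[dataset.patient_ids.astype(str)].to_numpy(dtype=float)


@dataclass
class StudyResult:
    horizon_minutes: int
    mode: str                      # unimodal / multimodal / persistence
    seed: int
    mae_mgdl: float
    mape_percent: float
    report: dict = field(default_factory=dict)
    actual: np.ndarray | None = None      # pooled test-set mg/dL
    predicted: np.ndarray | None = None


def run_synthetic_study(base_seed: int,
                        horizons: list[int] = (15, 30, 60),
                        seeds: list[int] | None = None,
                        cohort_overrides: dict | None = None,
                        model_overrides: dict | None = None,
                        fold_subset: list[int] | None = None,
                        max_train_windows: int | None = None
                        ) -> list[StudyResult]:
    """Run the scaled synthetic comparison; returns one row per
    (horizon, mode, seed), with persistence reported once per horizon."""
    cohort_kwargs = {**STUDY_COHORT, **(cohort_overrides or {})}
    model_kwargs = {**STUDY_MODEL, **(model_overrides or {})}
    if fold_subset is None:
        fold_subset = STUDY_FOLD_SUBSET
    if max_train_windows is None:
        max_train_windows = STUDY_MAX_TRAIN_WINDOWS
    if seeds is None:
        seeds = [base_seed + k for k in range(3)]
    cohort_config = SyntheticCohortConfig(seed=(base_seed * 7919) % (2 ** 31),
                                          **cohort_kwargs)
    datasets, baseline_df = prepare_cohort_windows(cohort_config, list(horizons))
    variable_set = model_kwargs.get("variable_set", 1)

    results: list[StudyResult] = []
    for h in horizons:
        ds = datasets[h]
        records = baseline_matrix(ds, baseline_df, variable_set)
        # persistence baseline is deterministic: evaluate on the same folds
        from .windows import leave_one_day_out_folds
        folds = leave_one_day_out_folds(ds)
        test_idx = np.concatenate([folds[k][1] for k in fold_subset])
        pers_pred = persistence_predictions(ds.subset(test_idx))
        pers_actual = ds.targets[test_idx]
        results.append(StudyResult(
            horizon_minutes=h, mode="persistence", seed=base_seed,
            mae_mgdl=mean_absolute_point_error(pers_actual, pers_pred),
            mape_percent=stratified_metrics(pers_actual, pers_pred)["overall_mape_percent"],
            report=stratified_metrics(pers_actual, pers_pred),
            actual=pers_actual.copy(), predicted=pers_pred))
        for seed in seeds:
            for mode in ("unimodal", "multimodal"):
                config = ModelConfig(mode=mode, seed=seed,
                                     baseline_dim=len(VARIABLE_SETS[variable_set]),
                                     **model_kwargs)
                fold_results = cross_validate(
                    ds, records if mode == "multimodal" else None, config,
                    fold_subset=fold_subset,
                    max_train_windows=max_train_windows,
                    horizon_minutes=h)
                report = pool_fold_results(fold_results)
                results.append(StudyResult(
                    horizon_minutes=h, mode=mode, seed=seed,
                    mae_mgdl=report["overall_mae_mgdl"],
                    mape_percent=report["overall_mape_percent"],
                    report=report,
                    actual=np.concatenate([f.actual for f in fold_results]),
                    predicted=np.concatenate([f.predicted for f in fold_results])))
    return results


def study_table(results: list[StudyResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "horizon_min": r.horizon_minutes, "mode": r.mode, "seed": r.seed,
        "mae_mgdl": r.mae_mgdl, "mape_percent": r.mape_percent,
    } for r in results])
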