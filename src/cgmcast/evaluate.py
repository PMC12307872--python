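"""Cross-validated training/prediction and error metrics.

The study's error vocabulary is ambiguous: its "MAPE" formula is the mean
absolute *percentage* error, while the values it reports are in mg/dL (mean
absolute *point* error). Both metrics are therefore computed side by side
under unambiguous names, overall and stratified into hyperglycaemic
(actual > 180 mg/dL) and hypoglycaemic (actual < 70 mg/dL) subsets; empty
strata are reported as undefined (NaN), never zero. Architecture comparisons
use a paired two-sided t-test on per-point absolute errors, since competing
models score the identical test points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .nn.network import ModelConfig, predict, train
from .preprocess import ScalerState, apply_minmax, fit_minmax, invert_minmax
from .windows import WindowedDataset, leave_one_day_out_folds

HYPER_THRESHOLD = 180.0
HYPO_THRESHOLD = 70.0


@dataclass
class FoldResult:
    held_out_day: np.datetime64
    actual: np.ndarray            # mg/dL
    predicted: np.ndarray         # mg/dL
    patient_ids: np.ndarray
    mode: str
    horizon_minutes: int

    def __post_init__(self) -> None:
        if self.actual.shape != self.predicted.shape:
            raise ValueError("actual/predicted length mismatch")
        if not np.isfinite(self.predicted).all():
            raise ValueError("non-finite predictions")


def mape_percent(actual, predicted) -> float:
    """Mean absolute percentage error, 100 * mean(|A - P| / A)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.size == 0:
        raise ValueError("empty vectors")
    if (actual <= 0).any():
        raise ValueError("actual values must be strictly positive")
    return float(100.0 * np.mean(np.abs(actual - predicted) / actual))


def mean_absolute_point_error(actual, predicted) -> float:
    """Mean absolute error in mg/dL."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean(np.abs(actual - predicted)))


def stratified_metrics(actual, predicted) -> dict[str, float]:
    """Overall / hyperglycaemic / hypoglycaemic values of both metric forms.

    Stratification is on the ACTUAL (acquired) glucose; an empty stratum
    yields NaN ("undefined"), mirroring studies that omit hypoglycaemic
    scores when events are too rare.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    out: dict[str, float] = {}
    for name, mask in (("overall", np.ones_like(actual, dtype=bool)),
                       ("hyper", actual > HYPER_THRESHOLD),
                       ("hypo", actual < HYPO_THRESHOLD)):
        if mask.any():
            out[f"{name}_mape_percent"] = mape_percent(actual[mask], predicted[mask])
            out[f"{name}_mae_mgdl"] = mean_absolute_point_error(actual[mask],
                                                                predicted[mask])
        else:
            out[f"{name}_mape_percent"] = float("nan")
            out[f"{name}_mae_mgdl"] = float("nan")
        out[f"{name}_n"] = int(mask.sum())
    return out


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    stars: str
    degenerate: bool = False


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def paired_t_test(errors_a, errors_b) -> PairedTestResult:
    """Paired two-sided t-test on per-point absolute errors of two models.

    Zero-variance differences: p = 1 when all differences are exactly 0;
    otherwise the constant nonzero difference is degenerate evidence and is
    flagged with p -> 0.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("error vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired points")
    d = a - b
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return PairedTestResult(t=0.0, p=1.0, stars="")
        return PairedTestResult(t=float(np.sign(d[0]) * np.inf), p=0.0,
                                stars="***", degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(t), p=float(p), stars=significance_stars(p))


def persistence_predictions(dataset: WindowedDataset) -> np.ndarray:
    """Last-value (naive persistence) baseline: predict t5's glucose."""
    return dataset.inputs[:, -1].copy()


def cross_validate(dataset: WindowedDataset, records: np.ndarray | None,
                   config: ModelConfig,
                   fold_subset: list[int] | None = None,
                   max_train_windows: int | None = None,
                   horizon_minutes: int = 0) -> list[FoldResult]:
    """Leave-one-day-out training and prediction.

    Per fold: a Min-Max scaler is fitted on the training windows only, the
    model is retrained from a fresh fold-seeded initialisation, and test
    predictions are inverse-scaled back to mg/dL. ``dataset`` must hold raw
    mg/dL values. ``records`` is the (n, p) baseline matrix aligned with
    windows (multimodal only). ``fold_subset`` restricts which folds run;
    ``max_train_windows`` subsamples large training folds (seeded).
    """
    if config.mode == "multimodal":
        if records is None:
            raise ValueError("multimodal cross-validation needs baseline records")
        if np.isnan(np.asarray(records, dtype=float)).any():
            raise ValueError("baseline records contain absent variables")
    folds = leave_one_day_out_folds(dataset)
    days = np.unique(dataset.day_labels)
    chosen = range(len(folds)) if fold_subset is None else fold_subset
    results: list[FoldResult] = []
    for k in chosen:
        train_idx, test_idx = folds[k]
        if train_idx.size == 0:
            raise ValueError(f"fold {k}: empty training set")
        if max_train_windows is not None and train_idx.size > max_train_windows:
            sub_rng = np.random.default_rng(config.seed * 1009 + k)
            train_idx = sub_rng.choice(train_idx, size=max_train_windows,
                                       replace=False)
        scaler = fit_minmax(np.concatenate([dataset.inputs[train_idx].ravel(),
                                            dataset.targets[train_idx]]))
        fold_seed = (config.seed * 1000003 + 97 * k) % (2 ** 31)
        fold_config = ModelConfig(**{**config.__dict__, "seed": fold_seed})
        X_train = apply_minmax(dataset.inputs[train_idx], scaler)
        y_train = apply_minmax(dataset.targets[train_idx], scaler)
        rec_train = records[train_idx] if records is not None else None
        params, _ = train(X_train, y_train, rec_train, fold_config,
                          patient_ids=dataset.patient_ids[train_idx])
        X_test = apply_minmax(dataset.inputs[test_idx], scaler)
        rec_test = records[test_idx] if records is not None else None
        pred_scaled = predict(X_test, rec_test, params, fold_config)
        pred = invert_minmax(pred_scaled, scaler)
        results.append(FoldResult(
            held_out_day=days[k],
            actual=dataset.targets[test_idx].copy(),
            predicted=pred,
            patient_ids=dataset.patient_ids[test_idx].copy(),
            mode=config.mode,
            horizon_minutes=horizon_minutes))
    return results


def plot_error_violins(errors_by_label: dict[str, np.ndarray], ax=None,
                       title: str | None = None):
    """Violin plot of absolute point-error distributions with quartile dashes.

    ``errors_by_label`` maps a model label to its per-point absolute errors
    (mg/dL). Returns the matplotlib Axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * len(errors_by_label) + 2, 4))
    labels = list(errors_by_label)
    parts = ax.violinplot([np.asarray(errors_by_label[k], dtype=float)
                           for k in labels],
                          showextrema=False,
                          quantiles=[[0.25, 0.5, 0.75]] * len(labels))
    if "cquantiles" in parts:
        parts["cquantiles"].set_linestyle("--")
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("absolute point error (mg/dL)")
    if title:
        ax.set_title(title)
    return ax


def pool_fold_results(results: list[FoldResult]) -> dict[str, float]:
    """Pooled metrics over all folds plus per-fold traces."""
    actual = np.concatenate([r.actual for r in results])
    predicted = np.concatenate([r.predicted for r in results])
    report = stratified_metrics(actual, predicted)
    report["per_fold_mae_mgdl"] = [
        mean_absolute_point_error(r.actual, r.predicted) for r in results]
    report["per_fold_mape_percent"] = [
        mape_percent(r.actual, r.predicted) for r in results]
    return report
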