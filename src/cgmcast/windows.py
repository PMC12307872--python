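"""Supervised window construction and leave-one-day-out folds.

Each training example is six consecutive 5-min glucose samples (t0..t5,
spanning 25 min) and a target sample one prediction horizon (15/30/60 min)
after t5. Windows slide with a stride of one grid step. A window is dropped
when its input+target span crosses a calendar-day boundary (so the
leave-one-day-out folds are leakage-free by construction) or crosses an
imputed gap longer than 15 min (linear interpolation across long dropouts is
untrustworthy). Windows containing any imputed sample are kept but flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import CGMSeries, ScalerState, apply_minmax

logger = logging.getLogger(__name__)

INPUT_LEN = 6          # samples t0..t5 on the 5-min grid
MAX_GAP_MINUTES = 15   # imputed runs longer than this break windows


@dataclass(frozen=True)
class HorizonSpec:
    """Prediction horizon: minutes ahead of the last input sample t5."""

    horizon_minutes: int

    def __post_init__(self) -> None:
        if self.horizon_minutes not in (15, 30, 60):
            raise ValueError("horizon must be 15, 30 or 60 minutes")

    @property
    def horizon_steps(self) -> int:
        return self.horizon_minutes // 5


@dataclass
class WindowedDataset:
    """(input-window, target) pairs with patient/day bookkeeping.

    Glucose columns are scaled if a scaler was supplied at construction,
    otherwise raw mg/dL.
    """

    inputs: np.ndarray            # (n, 6)
    targets: np.ndarray           # (n,)
    patient_ids: np.ndarray       # (n,) str
    target_times: np.ndarray      # (n,) datetime64[s]
    day_labels: np.ndarray        # (n,) datetime64[D], date of the target
    interpolated_flags: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return self.targets.size

    @staticmethod
    def empty() -> "WindowedDataset":
        return WindowedDataset(
            inputs=np.empty((0, INPUT_LEN)), targets=np.empty(0),
            patient_ids=np.empty(0, dtype=object),
            target_times=np.empty(0, dtype="datetime64[s]"),
            day_labels=np.empty(0, dtype="datetime64[D]"),
            interpolated_flags=np.empty(0, dtype=bool))

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            return WindowedDataset.empty()
        return WindowedDataset(
            inputs=np.concatenate([p.inputs for p in parts]),
            targets=np.concatenate([p.targets for p in parts]),
            patient_ids=np.concatenate([p.patient_ids for p in parts]),
            target_times=np.concatenate([p.target_times for p in parts]),
            day_labels=np.concatenate([p.day_labels for p in parts]),
            interpolated_flags=np.concatenate([p.interpolated_flags for p in parts]))

    def subset(self, idx) -> "WindowedDataset":
        return WindowedDataset(
            inputs=self.inputs[idx], targets=self.targets[idx],
            patient_ids=self.patient_ids[idx], target_times=self.target_times[idx],
            day_labels=self.day_labels[idx],
            interpolated_flags=self.interpolated_flags[idx])


def make_windows(series: CGMSeries, horizon: HorizonSpec,
                 scaler: ScalerState | None = None) -> WindowedDataset:
    """Slide stride-1 windows over an imputed 5-min series.

    For a contiguous single-day stretch of L samples the number of windows is
    max(0, L - 6 - h + 1), h = horizon_steps.
    """
    if series.native_interval != 5:
        raise ValueError("series must be on the 5-min grid (resample first)")
    g = series.glucose
    if np.isnan(g).any():
        raise ValueError("series contains missing values (impute first)")
    h = horizon.horizon_steps
    n = g.size
    span = INPUT_LEN - 1 + h  # index offset from t0 to the target
    if n <= span:
        logger.warning("%s: series too short for windows (n=%d)", series.patient_id, n)
        return WindowedDataset.empty()

    interp = series.interpolated if series.interpolated is not None \
        else np.zeros(n, dtype=bool)
    long_gap = np.zeros(n, dtype=bool)
    for start, length in series.gaps:
        if length * 5 > MAX_GAP_MINUTES:
            long_gap[start:start + length] = True

    days = series.timestamps.astype("datetime64[D]")
    starts = np.arange(n - span)
    tgt = starts + span
    # same calendar day across the full input+target span
    same_day = days[starts] == days[tgt]
    # no long imputed gap anywhere in the span
    cum_long = np.concatenate([[0], np.cumsum(long_gap)])
    no_long_gap = (cum_long[tgt + 1] - cum_long[starts]) == 0
    keep = same_day & no_long_gap
    starts = starts[keep]
    tgt = tgt[keep]
    if starts.size == 0:
        return WindowedDataset.empty()

    X = np.stack([g[s:s + INPUT_LEN] for s in starts])
    y = g[tgt]
    if scaler is not None:
        X = apply_minmax(X, scaler)
        y = apply_minmax(y, scaler)
    cum_interp = np.concatenate([[0], np.cumsum(interp)])
    flags = (cum_interp[tgt + 1] - cum_interp[starts]) > 0
    return WindowedDataset(
        inputs=X, targets=y,
        patient_ids=np.array([series.patient_id] * starts.size, dtype=object),
        target_times=series.timestamps[tgt],
        day_labels=days[tgt],
        interpolated_flags=flags)


def leave_one_day_out_folds(dataset: WindowedDataset
                            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per distinct calendar day, pooled across patients.

    Test = windows whose target falls on the held-out day; train = everything
    else (days before and after). Test sets partition the dataset.
    """
    days = np.unique(dataset.day_labels)
    if days.size < 2:
        raise ValueError("leave-one-day-out needs at least 2 distinct days")
    folds = []
    idx = np.arange(len(dataset))
    for day in days:
        test = dataset.day_labels == day
        folds.append((idx[~test], idx[test]))
    return folds
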