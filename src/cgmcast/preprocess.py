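"""CGM loading, cleaning, resampling onto a 5-min grid, and scaling.

Both sensor dialects are brought onto a common 5-min grid: the 15-min sensor
is upsampled by linear interpolation (gaps stay gaps), the 1-min sensor is
downsampled to non-overlapping 5-min bin means (decimation available as an
option). Patients are excluded when more than 50% of their expected samples
are missing (strict: exactly 50% is retained). Glucose is Min-Max scaled to
[0, 1] for training; scalers must be fitted on training data only. An
augmented Dickey-Fuller check is provided for stationarity QC; it never gates
the pipeline.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

logger = logging.getLogger(__name__)

TARGET_INTERVAL_MIN = 5
SUPPORTED_INTERVALS = (1, 5, 15)
# Large-sample 5% critical value of the Dickey-Fuller t-statistic,
# constant-only regression.
ADF_CRITICAL_5PCT = -2.86
ADF_MIN_SAMPLES = 50


@dataclass
class CGMSeries:
    """One patient's timestamped glucose trace.

    ``glucose`` uses NaN as the missing marker. ``interpolated`` (when set)
    flags samples filled by imputation; ``gaps`` records the imputed runs as
    (start_index, length) pairs on the current grid.
    """

    patient_id: str
    timestamps: np.ndarray          # datetime64[s], strictly increasing
    glucose: np.ndarray             # mg/dL, NaN = missing
    sensor: str = "sensor2"
    native_interval: int = 5        # minutes
    interpolated: np.ndarray | None = None
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.timestamps.shape != self.glucose.shape:
            raise ValueError("timestamps and glucose must have equal length")
        if self.timestamps.size > 1:
            if not (np.diff(self.timestamps.astype("int64")) > 0).all():
                raise ValueError(f"{self.patient_id}: timestamps must be strictly increasing")
        obs = self.glucose[~np.isnan(self.glucose)]
        if obs.size and (obs <= 0).any():
            raise ValueError(f"{self.patient_id}: observed glucose must be positive")

    def __len__(self) -> int:
        return self.glucose.size

    @property
    def observed(self) -> np.ndarray:
        return self.glucose[~np.isnan(self.glucose)]

    @property
    def interval_minutes(self) -> np.ndarray:
        """Minutes since the first sample, per sample."""
        return (self.timestamps - self.timestamps[0]).astype("timedelta64[s]").astype(float) / 60.0


@dataclass(frozen=True)
class ScalerState:
    """Min-Max scaler mapping [min_value, max_value] -> [0, 1]."""

    min_value: float
    max_value: float

    @property
    def degenerate(self) -> bool:
        return self.max_value <= self.min_value


REQUIRED_CGM_COLUMNS = ("patient_id", "timestamp", "glucose_mgdl", "sensor")


def _infer_native_interval(ts: np.ndarray) -> int:
    if ts.size < 2:
        return TARGET_INTERVAL_MIN
    diffs = np.diff(ts.astype("int64")) / 60.0
    med = float(np.median(diffs))
    best = min(SUPPORTED_INTERVALS, key=lambda k: abs(k - med))
    return best


def load_cgm_csv(path) -> list[CGMSeries]:
    """Load a long-format CGM CSV into one CGMSeries per patient.

    Rows are sorted by timestamp; duplicate (patient, timestamp) rows are
    collapsed to their mean (sensor re-transmissions). The native interval is
    inferred from the median timestamp spacing and snapped to {1, 5, 15} min.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_CGM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    if df.empty:
        logger.warning("%s: empty CGM file", path)
        return []
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamps: {exc}") from exc
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        sensor = str(grp["sensor"].iloc[0])
        grp = (grp.groupby("timestamp", sort=True)["glucose_mgdl"]
               .mean().reset_index())
        ts = grp["timestamp"].to_numpy().astype("datetime64[s]")
        out.append(CGMSeries(patient_id=str(pid), timestamps=ts,
                             glucose=grp["glucose_mgdl"].to_numpy(float),
                             sensor=sensor,
                             native_interval=_infer_native_interval(ts)))
    return out


def load_baseline_csv(path) -> pd.DataFrame:
    """Load the per-patient baseline health-record table, indexed by patient."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: missing 'patient_id' column")
    return df.set_index("patient_id")


def missing_fraction(series: CGMSeries) -> float:
    """Missing fraction against the expected count span/native_interval + 1.

    Computed on the native grid, before any resampling.
    """
    if len(series) == 0:
        return 1.0
    span = series.interval_minutes[-1]
    expected = span / series.native_interval + 1
    observed = int((~np.isnan(series.glucose)).sum())
    return float(max(0.0, 1.0 - observed / expected))


def is_excluded(series: CGMSeries) -> bool:
    """Exclusion rule: more than 50% missing (strict inequality)."""
    if len(series) == 0:
        return True
    return missing_fraction(series) > 0.5


def resample_to_grid(series: CGMSeries,
                     target_interval: int = TARGET_INTERVAL_MIN,
                     downsample: str = "bin_mean") -> CGMSeries:
    """Bring a series onto the uniform ``target_interval`` grid.

    15-min data is upsampled by linear interpolation between adjacent native
    samples (a NaN neighbour keeps the in-between points missing); 1-min data
    is downsampled to non-overlapping bin means labelled by bin start
    (``downsample="decimate"`` takes the bin's first sample instead); 5-min
    data passes through unchanged.
    """
    if series.native_interval not in SUPPORTED_INTERVALS:
        raise ValueError(f"unsupported native interval {series.native_interval}")
    if target_interval != TARGET_INTERVAL_MIN:
        raise ValueError("only the 5-min target grid is supported")
    if series.native_interval == target_interval:
        return dataclasses.replace(series, glucose=series.glucose.copy())

    t0 = series.timestamps[0]
    if series.native_interval == 15:
        # Assume (and verify) a uniform native grid for interpolation.
        minutes = series.interval_minutes
        n_native = len(series)
        if not np.allclose(minutes, np.arange(n_native) * 15.0):
            raise ValueError(f"{series.patient_id}: 15-min series not on a uniform grid")
        span = minutes[-1]
        n_new = int(span // target_interval) + 1
        new_min = np.arange(n_new) * float(target_interval)
        pos = new_min / 15.0
        i0 = np.minimum(pos.astype(int), n_native - 1)
        frac = pos - i0
        g = series.glucose
        out = np.where(frac == 0.0, g[i0],
                       (1.0 - frac) * g[i0] + frac * g[np.minimum(i0 + 1, n_native - 1)])
    else:  # native 1-min -> bin over 5 samples
        k = target_interval // series.native_interval
        n_full = len(series) // k
        if n_full == 0:
            raise ValueError(f"{series.patient_id}: series too short to downsample")
        blocks = series.glucose[: n_full * k].reshape(n_full, k)
        if downsample == "bin_mean":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
                out = np.nanmean(blocks, axis=1)
        elif downsample == "decimate":
            out = blocks[:, 0]
        else:
            raise ValueError(f"unknown downsample method {downsample!r}")
        new_min = np.arange(n_full) * float(target_interval)

    ts = t0 + (new_min.astype("int64")).astype("timedelta64[m]")
    return CGMSeries(patient_id=series.patient_id, timestamps=ts.astype("datetime64[s]"),
                     glucose=out, sensor=series.sensor,
                     native_interval=target_interval)


def interpolate_missing(series: CGMSeries) -> CGMSeries:
    """Fill interior missing runs by linear interpolation on the uniform grid.

    Leading/trailing missing samples are dropped, not extrapolated. The result
    carries an ``interpolated`` mask and ``gaps`` metadata (start index, run
    length) on the trimmed grid, for gap-aware windowing.
    """
    g = series.glucose
    obs = ~np.isnan(g)
    if not obs.any():
        raise ValueError(f"{series.patient_id}: all samples missing")
    first, last = np.flatnonzero(obs)[[0, -1]]
    g = g[first:last + 1].copy()
    ts = series.timestamps[first:last + 1]
    nan_mask = np.isnan(g)
    if nan_mask.any():
        idx = np.arange(g.size, dtype=float)
        g[nan_mask] = np.interp(idx[nan_mask], idx[~nan_mask], g[~nan_mask])
    gaps: list[tuple[int, int]] = []
    i = 0
    while i < nan_mask.size:
        if nan_mask[i]:
            j = i
            while j < nan_mask.size and nan_mask[j]:
                j += 1
            gaps.append((i, j - i))
            i = j
        else:
            i += 1
    return CGMSeries(patient_id=series.patient_id, timestamps=ts, glucose=g,
                     sensor=series.sensor, native_interval=series.native_interval,
                     interpolated=nan_mask, gaps=gaps)


def fit_minmax(values: np.ndarray) -> ScalerState:
    """Fit a Min-Max scaler on (training) glucose values, ignoring NaNs."""
    values = np.asarray(values, dtype=float)
    obs = values[~np.isnan(values)]
    if obs.size == 0:
        raise ValueError("cannot fit scaler on empty data")
    lo, hi = float(obs.min()), float(obs.max())
    if hi <= lo:
        warnings.warn("degenerate scaler: max == min; all values map to 0")
    return ScalerState(min_value=lo, max_value=hi)


def apply_minmax(x, scaler: ScalerState):
    """Scale mg/dL to [0, 1] on the training range (no clipping at test time)."""
    x = np.asarray(x, dtype=float)
    if scaler.degenerate:
        return np.zeros_like(x)
    return (x - scaler.min_value) / (scaler.max_value - scaler.min_value)


def invert_minmax(y, scaler: ScalerState):
    y = np.asarray(y, dtype=float)
    if scaler.degenerate:
        return np.full_like(y, scaler.min_value)
    return y * (scaler.max_value - scaler.min_value) + scaler.min_value


@dataclass(frozen=True)
class AdfResult:
    statistic: float
    reject_unit_root: bool
    valid: bool
    n_obs: int


def adf_check(series: CGMSeries, max_lag: int = 12) -> AdfResult:
    """Augmented Dickey-Fuller stationarity QC (constant-only regression).

    The t-statistic on the level coefficient is compared with the embedded
    large-sample 5% critical value (-2.86); unit root rejected (series deemed
    stationary) iff statistic < critical value. Series with fewer than 50
    observed samples are flagged invalid rather than tested. QC only: the
    result never gates the pipeline.
    """
    x = series.observed
    if x.size < ADF_MIN_SAMPLES:
        return AdfResult(statistic=float("nan"), reject_unit_root=False,
                         valid=False, n_obs=int(x.size))
    stat = adfuller(x, maxlag=max_lag, regression="c", autolag=None)[0]
    return AdfResult(statistic=float(stat),
                     reject_unit_root=bool(stat < ADF_CRITICAL_5PCT),
                     valid=True, n_obs=int(x.size))
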