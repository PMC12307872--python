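"""Synthetic type 2 diabetes CGM cohort generator.

Real CGM studies of elderly T2D cohorts are rarely redistributable, so this
module fabricates cohorts with the same statistical skeleton: two sensor
populations (a 1-min-sampled and a 15-min-sampled device), 8-28 day monitoring
periods, a baseline health-record table whose variables follow published
cohort means/SDs, nested variable-availability attrition, contiguous sensor
dropouts, and glucose dynamics genuinely modulated by the baseline covariates
(so a multimodal forecaster has something to learn from the record).

The per-patient glucose trace is

    g(t) = B + A sin(2*pi*t/24h + phi) + sum_k M_k k(t - t_k) + eps(t)

clamped to [40, 400] mg/dL, where the basal level B is tied to HbA1c through
the standard ADAG estimated-average-glucose relation eAG = 28.7*HbA1c - 46.7,
k(u) = (u/tau) exp(1 - u/tau) is a gamma-like meal-response kernel peaking at
tau = 60 min, meals sit near 08:00/13:00/20:00 with +/-45 min daily jitter,
and eps is an AR(1) process on the sampling grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CGMSeries

# Baseline health-record variables: canonical name -> (mean, sd, low, high).
# Truncation bounds keep draws physiologically plausible and nonnegative.
TABLE1_VARIABLES: dict[str, tuple[float, float, float, float]] = {
    "Age (years)": (67.0, 9.0, 40.0, 100.0),
    "Weight (kg)": (80.42, 28.46, 35.0, 250.0),
    "Height (m)": (1.63, 0.12, 1.20, 2.20),
    "Waist circumference (cm)": (104.13, 16.5, 50.0, 200.0),
    "Baseline Blood Glucose (mg/dL)": (136.6, 45.19, 40.0, 400.0),
    "Baseline HbA1c (%)": (7.42, 1.11, 4.0, 15.0),
    "Creatinine (mg/dL)": (1.99, 1.52, 0.2, 12.0),
    "Urea Level (mg/dL)": (49.44, 30.65, 5.0, 250.0),
    "Total cholesterol (mg/dL)": (144.82, 33.78, 50.0, 400.0),
    "LDL cholesterol (mg/dL)": (67.17, 32.11, 10.0, 300.0),
    "HDL cholesterol (mg/dL)": (46.86, 10.83, 10.0, 150.0),
    "Triglycerides (mg/dL)": (203.71, 247.43, 20.0, 2000.0),
    "White blood cell count (10^3/uL)": (7.29, 1.83, 1.0, 30.0),
    "Red blood cell count (10^3/uL)": (25.26, 37.27, 1.0, 300.0),
    "Haematocrit (%)": (39.76, 8.86, 15.0, 65.0),
    "Plt (x 1000/uL)": (206.31, 80.53, 20.0, 1000.0),
    "SGOT (IU/L)": (35.42, 32.22, 5.0, 400.0),
    "SGPT (IU/L)": (25.99, 14.12, 5.0, 400.0),
    "K (mmol/L)": (4.57, 0.48, 2.0, 8.0),
    "Na (mmol/L)": (125.52, 42.24, 100.0, 160.0),
}

FEMALE_FRACTION = 0.55  # Gender coded 1 = female, 0 = male

# Nested availability sets of baseline variables (set k extends set k-1).
VARIABLE_SETS: list[list[str]] = [
    ["Age (years)", "Gender"],
    ["Age (years)", "Gender", "Baseline HbA1c (%)"],
    ["Age (years)", "Gender", "Baseline HbA1c (%)", "Weight (kg)", "Height (m)"],
    ["Age (years)", "Gender", "Baseline HbA1c (%)", "Weight (kg)", "Height (m)",
     "HDL cholesterol (mg/dL)", "Total cholesterol (mg/dL)"],
    ["Age (years)", "Gender", "Baseline HbA1c (%)", "Weight (kg)", "Height (m)",
     "HDL cholesterol (mg/dL)", "Total cholesterol (mg/dL)",
     "Baseline Blood Glucose (mg/dL)", "Urea Level (mg/dL)"],
    ["Age (years)", "Gender", "Baseline HbA1c (%)", "Weight (kg)", "Height (m)",
     "HDL cholesterol (mg/dL)", "Total cholesterol (mg/dL)",
     "Baseline Blood Glucose (mg/dL)", "Urea Level (mg/dL)",
     "K (mmol/L)", "Haematocrit (%)", "LDL cholesterol (mg/dL)"],
    ["Age (years)", "Gender", "Baseline HbA1c (%)", "Weight (kg)", "Height (m)",
     "HDL cholesterol (mg/dL)", "Total cholesterol (mg/dL)",
     "Baseline Blood Glucose (mg/dL)", "Urea Level (mg/dL)",
     "K (mmol/L)", "Haematocrit (%)", "LDL cholesterol (mg/dL)",
     "SGOT (IU/L)", "White blood cell count (10^3/uL)"],
]

# Availability counts per sensor population at the reference cohort sizes
# (15 sensor-1 / 25 sensor-2 patients); used to scale nested attrition.
ATTRITION_COUNTS = {
    "sensor1": [15, 8, 6, 5, 5, 3, 2],
    "sensor2": [25, 17, 13, 9, 7, 5, 4],
}

HBA1C_MEAN = TABLE1_VARIABLES["Baseline HbA1c (%)"][0]
GLUCOSE_FLOOR = 40.0
GLUCOSE_CEIL = 400.0
MEAL_TAU_MIN = 60.0
MEAL_HOURS = (8.0, 13.0, 20.0)
MEAL_JITTER_MIN = 45.0
AR1_COEFF_5MIN = 0.9
DEFAULT_START = np.datetime64("2023-03-01T00:00:00")


def eag_from_hba1c(hba1c: float | np.ndarray) -> float | np.ndarray:
    """ADAG estimated average glucose (mg/dL) from HbA1c (%)."""
    return 28.7 * np.asarray(hba1c) - 46.7


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_patients: int = 40
    n_sensor1: int = 15
    duration_days: tuple[int, int] = (8, 28)
    missing_fraction: float = 0.05
    baseline_effect_scale: float = 1.0
    attrition: bool = True
    seed: int = 0
    start: np.datetime64 = DEFAULT_START

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.n_sensor1 <= self.n_patients:
            raise ValueError("n_sensor1 must lie in [0, n_patients]")
        lo, hi = self.duration_days
        if lo < 1 or hi < lo:
            raise ValueError("duration_days must be a nonempty range with min >= 1")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.baseline_effect_scale < 0:
            raise ValueError("baseline_effect_scale must be nonnegative")


@dataclass
class PatientProfile:
    """Latent dynamics parameters for one synthetic patient."""

    patient_id: str
    baseline: dict[str, float]
    basal: float                    # mg/dL, in [70, 300]
    circadian_amplitude: float      # mg/dL
    circadian_phase: float          # rad
    meal_amplitudes: tuple[float, float, float]  # mg/dL
    ar_coeff: float                 # AR(1) coefficient at 5-min steps, [0, 1)
    innovation_sd: float            # mg/dL at 5-min steps, > 0

    def __post_init__(self) -> None:
        if not 70.0 <= self.basal <= 300.0:
            raise ValueError("basal level must lie in [70, 300] mg/dL")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("AR coefficient must lie in [0, 1)")
        if self.innovation_sd < 0:
            raise ValueError("innovation SD must be nonnegative")


from functools import lru_cache


@lru_cache(maxsize=None)
def _compensated_loc(mean: float, sd: float, low: float, high: float) -> float:
    """Location parameter whose truncated-normal mean equals ``mean``.

    Asymmetric truncation shifts the realised mean (e.g. a lower bound 1.6 SD
    below the mean pulls it up several percent); solve for the loc that undoes
    the shift so cohort summary statistics are reproduced.
    """
    from scipy.optimize import brentq

    def realised_mean(loc: float) -> float:
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    return float(brentq(lambda loc: realised_mean(loc) - mean,
                        mean - 3 * sd, mean + 3 * sd, xtol=1e-10))


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    low: float, high: float, size=None):
    loc = _compensated_loc(mean, sd, low, high)
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def simulate_baseline_record(rng: np.random.Generator,
                             effect_scale: float = 1.0) -> dict[str, float]:
    """Draw one baseline health record.

    Each quantitative variable is a truncated normal at its published cohort
    mean +/- SD; Gender is Bernoulli(0.55) for female (coded 1).
    ``effect_scale`` only modulates glucose *dynamics* downstream, never the
    record's own distribution.
    """
    record = {"Gender": float(rng.random() < FEMALE_FRACTION)}
    for name, (mean, sd, low, high) in TABLE1_VARIABLES.items():
        record[name] = float(_truncnorm_draw(rng, mean, sd, low, high))
    return record


def make_profile(patient_id: str, baseline: dict[str, float],
                 effect_scale: float, rng: np.random.Generator) -> PatientProfile:
    """Draw latent dynamics parameters; basal level is anchored to HbA1c.

    With effect_scale = 0 the basal level collapses to the cohort-mean eAG so
    traces carry no baseline signal; with scale 1 the full ADAG slope applies.
    """
    hba1c = baseline["Baseline HbA1c (%)"]
    basal = float(eag_from_hba1c(HBA1C_MEAN)
                  + effect_scale * 28.7 * (hba1c - HBA1C_MEAN))
    basal = float(np.clip(basal, 70.0, 300.0))
    return PatientProfile(
        patient_id=patient_id,
        baseline=baseline,
        basal=basal,
        circadian_amplitude=float(rng.uniform(8.0, 25.0)),
        circadian_phase=float(rng.uniform(-np.pi, np.pi)),
        meal_amplitudes=tuple(rng.uniform(30.0, 70.0, size=3)),
        ar_coeff=AR1_COEFF_5MIN,
        innovation_sd=float(rng.uniform(2.0, 8.0)),
    )


def _meal_kernel(u_min: np.ndarray) -> np.ndarray:
    """Gamma-like rise/decay response, unit peak at u = tau (60 min)."""
    out = np.zeros_like(u_min, dtype=float)
    pos = u_min >= 0
    x = u_min[pos] / MEAL_TAU_MIN
    out[pos] = x * np.exp(1.0 - x)
    return out


def simulate_glucose_trace(profile: PatientProfile, duration_days: int,
                           sampling_interval: int, rng: np.random.Generator,
                           sensor: str = "sensor2",
                           start: np.datetime64 = DEFAULT_START) -> CGMSeries:
    """Simulate a CGM trace on a uniform grid of ``sampling_interval`` minutes.

    The AR(1) noise keeps its 5-min-step autocorrelation (0.9) and stationary
    variance regardless of the native grid, so sensors with different sampling
    rates see the same underlying process.
    """
    if sampling_interval not in (1, 5, 15):
        raise ValueError(f"sampling_interval must be 1, 5 or 15 min, got {sampling_interval}")
    if duration_days < 1:
        raise ValueError("duration_days must be >= 1")

    n = duration_days * 24 * 60 // sampling_interval
    t_min = np.arange(n, dtype=float) * sampling_interval  # minutes since start
    hours = t_min / 60.0

    g = np.full(n, profile.basal)
    g += profile.circadian_amplitude * np.sin(2 * np.pi * hours / 24.0
                                              + profile.circadian_phase)
    for day in range(duration_days):
        for amp, hour in zip(profile.meal_amplitudes, MEAL_HOURS):
            jitter = rng.uniform(-MEAL_JITTER_MIN, MEAL_JITTER_MIN)
            meal_t = day * 24 * 60 + hour * 60 + jitter
            g += amp * _meal_kernel(t_min - meal_t)

    # AR(1) on the native grid, rescaled to keep the 5-min-step coefficient
    # and stationary variance.
    rho = profile.ar_coeff ** (sampling_interval / 5.0)
    sd_stat = profile.innovation_sd / np.sqrt(1.0 - profile.ar_coeff ** 2)
    innov_sd = sd_stat * np.sqrt(1.0 - rho ** 2)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd_stat)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        eps[i] = rho * eps[i - 1] + shocks[i - 1]
    g += eps

    g = np.clip(g, GLUCOSE_FLOOR, GLUCOSE_CEIL)
    ts = start + (np.arange(n) * sampling_interval).astype("timedelta64[m]")
    return CGMSeries(patient_id=profile.patient_id,
                     timestamps=ts.astype("datetime64[s]"),
                     glucose=g, sensor=sensor, native_interval=sampling_interval)


def inject_missingness(series: CGMSeries, missing_fraction: float,
                       rng: np.random.Generator,
                       mean_gap_samples: float = 6.0) -> CGMSeries:
    """Blank out contiguous dropout-like gaps until the missing fraction is hit.

    Gap lengths are geometric with the given mean; the realised fraction lands
    within +/-2 percentage points of the target (exact up to rounding, since
    the last gap is trimmed). Timestamps are untouched.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must lie in [0, 1)")
    g = series.glucose.copy()
    n = g.size
    target = int(round(missing_fraction * n))
    if target == 0:
        return dataclasses.replace(series, glucose=g)
    missing = np.isnan(g)
    p = 1.0 / mean_gap_samples
    while missing.sum() < target:
        start = int(rng.integers(0, n))
        length = int(rng.geometric(p))
        length = min(length, target - int(missing.sum()) , n - start)
        if length <= 0:
            continue
        missing[start:start + length] = True
    g[missing] = np.nan
    return dataclasses.replace(series, glucose=g)


def _attrition_levels(n: int, sensor: str, rng: np.random.Generator) -> np.ndarray:
    """Assign each patient the highest variable set fully available to them,
    scaling the reference nested availability counts to the population size."""
    counts = ATTRITION_COUNTS[sensor]
    ref_n = counts[0]
    scaled = [max(0, int(round(c * n / ref_n))) for c in counts]
    scaled[0] = n
    # levels[i] = highest set index available; count with level >= k is scaled[k]
    levels = np.zeros(n, dtype=int)
    for k in range(1, len(scaled)):
        scaled[k] = min(scaled[k], scaled[k - 1])
        idx = rng.permutation(np.flatnonzero(levels == k - 1))[: scaled[k]]
        # keep nesting: only promote patients already at level k-1
        levels[idx] = k
    return levels


def simulate_cohort(config: SyntheticCohortConfig
                    ) -> tuple[list[CGMSeries], pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns (series list, baseline table, ground-truth latent table). The first
    ``n_sensor1`` patients carry the 1-min native sensor ("sensor1"), the rest
    the 15-min sensor ("sensor2"). Identical config (incl. seed) reproduces the
    cohort bit-identically.
    """
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    patient_seeds = ss.spawn(config.n_patients)

    records, truths, series_list = [], [], []
    lo, hi = config.duration_days
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        sensor = "sensor1" if i < config.n_sensor1 else "sensor2"
        interval = 1 if sensor == "sensor1" else 15
        rng = np.random.default_rng(patient_seeds[i])
        baseline = simulate_baseline_record(rng, config.baseline_effect_scale)
        profile = make_profile(pid, baseline, config.baseline_effect_scale, rng)
        duration = int(rng.integers(lo, hi + 1))
        trace = simulate_glucose_trace(profile, duration, interval, rng,
                                       sensor=sensor, start=config.start)
        trace = inject_missingness(trace, config.missing_fraction, rng)
        series_list.append(trace)
        records.append({"patient_id": pid, "sensor": sensor, **baseline})
        truths.append({
            "patient_id": pid, "sensor": sensor, "duration_days": duration,
            "basal": profile.basal,
            "circadian_amplitude": profile.circadian_amplitude,
            "circadian_phase": profile.circadian_phase,
            "meal_amp_breakfast": profile.meal_amplitudes[0],
            "meal_amp_lunch": profile.meal_amplitudes[1],
            "meal_amp_dinner": profile.meal_amplitudes[2],
            "ar_coeff": profile.ar_coeff,
            "innovation_sd": profile.innovation_sd,
        })

    baseline_df = pd.DataFrame(records).set_index("patient_id")
    truth_df = pd.DataFrame(truths).set_index("patient_id")

    if config.attrition:
        for sensor in ("sensor1", "sensor2"):
            mask = baseline_df["sensor"] == sensor
            n = int(mask.sum())
            if n == 0:
                continue
            levels = _attrition_levels(n, sensor, master)
            full = VARIABLE_SETS[-1]
            for row, level in zip(baseline_df.index[mask], levels):
                drop = [v for v in full if v not in VARIABLE_SETS[level]]
                baseline_df.loc[row, drop] = np.nan

    return series_list, baseline_df, truth_df


def write_cohort(series_list: Sequence[CGMSeries], baseline_df: pd.DataFrame,
                 truth_df: pd.DataFrame, outdir) -> dict[str, str]:
    """Write cgm.csv / baseline.csv / truth.csv under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "patient_id": s.patient_id,
            "timestamp": pd.DatetimeIndex(s.timestamps).strftime("%Y-%m-%dT%H:%M:%S"),
            "glucose_mgdl": s.glucose,
            "sensor": s.sensor,
        }))
    cgm_path = outdir / "cgm.csv"
    pd.concat(frames, ignore_index=True).to_csv(cgm_path, index=False)
    baseline_path = outdir / "baseline.csv"
    baseline_df.to_csv(baseline_path)
    truth_path = outdir / "truth.csv"
    truth_df.to_csv(truth_path)
    return {"cgm": str(cgm_path), "baseline": str(baseline_path),
            "truth": str(truth_path)}
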