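"""Clinical evaluation: Parkes consensus error grid (type 2) and AGP summary.

The Parkes grid partitions the (reference, predicted) plane into zones A-E of
increasing clinical risk; the type-2 zone polygons ship as a versioned vertex
CSV (see the data file header for provenance) and classification is
point-in-polygon with boundary ties resolved toward the more accurate zone.
AGP statistics follow the standard ambulatory-glucose-profile conventions:
cumulative time-in-range bands (<54, <70, 70-180, >180, >250 mg/dL), mean
glucose, the glucose management indicator GMI(%) = 3.31 + 0.02392 * mean
(ADAG-derived), and %CV glucose variability.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import shapely
from shapely.geometry import Polygon

ZONES = ("A", "B", "C", "D", "E")
GRID_MAX = 550.0
VERY_LOW = 54.0
LOW = 70.0
HIGH = 180.0
VERY_HIGH = 250.0


def _vertex_rows():
    path = resources.files("cgmcast.data") / "parkes_vertices_t2.csv"
    with path.open("r", encoding="utf-8") as fh:
        rows = [r for r in csv.DictReader(
            (line for line in fh if not line.startswith("#")))]
    return rows


@lru_cache(maxsize=1)
def parkes_polygons_t2() -> dict[str, list[Polygon]]:
    """Zone -> list of closed polygons (a zone may have parts above and
    below the identity diagonal)."""
    parts: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for row in _vertex_rows():
        parts.setdefault((row["zone"], row["segment"]), []).append(
            (float(row["x"]), float(row["y"])))
    out: dict[str, list[Polygon]] = {z: [] for z in ZONES}
    for (zone, _seg), pts in parts.items():
        poly = Polygon(pts)
        if not poly.is_valid:
            raise ValueError(f"invalid zone polygon {zone}")
        out[zone].append(poly)
    return out


def parkes_zone(reference: float, predicted: float) -> str:
    """Classify one (reference, predicted) pair into a zone A-E.

    Out-of-range values are clamped to [0, 550] with a warning; points on a
    shared boundary get the more accurate (earlier) zone.
    """
    return parkes_zones(np.asarray([reference]), np.asarray([predicted]))[0]


def parkes_zones(reference: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Vectorised zone classification; returns an array of zone labels."""
    x = np.asarray(reference, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if (x < 0).any() or (x > GRID_MAX).any() or (y < 0).any() or (y > GRID_MAX).any():
        warnings.warn("glucose outside [0, 550] mg/dL clamped for grid analysis")
        x = np.clip(x, 0.0, GRID_MAX)
        y = np.clip(y, 0.0, GRID_MAX)
    labels = np.full(x.shape, "", dtype="<U1")
    unassigned = np.ones(x.shape, dtype=bool)
    for zone in ZONES:  # A first: boundary ties go to the better zone
        for poly in parkes_polygons_t2()[zone]:
            if not unassigned.any():
                break
            hit = shapely.intersects_xy(poly, x[unassigned], y[unassigned])
            idx = np.flatnonzero(unassigned)[hit]
            labels[idx] = zone
            unassigned[idx] = False
    if unassigned.any():  # numerically on a seam: nudge inward
        for i in np.flatnonzero(unassigned):
            labels[i] = parkes_zone(min(x[i] + 1e-9, GRID_MAX),
                                    min(y[i] + 1e-9, GRID_MAX))
    return labels


def zone_distribution(reference, predicted) -> dict[str, float]:
    """Percentage of prediction pairs per zone (sums to 100)."""
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("empty pair list")
    labels = parkes_zones(reference, np.asarray(predicted, dtype=float))
    return {z: float(100.0 * np.mean(labels == z)) for z in ZONES}


@dataclass(frozen=True)
class AGPReport:
    percent_very_low: float    # < 54 mg/dL
    percent_low: float         # < 70 mg/dL (cumulative, includes very low)
    percent_target: float      # 70-180 mg/dL
    percent_high: float        # > 180 mg/dL (cumulative, includes very high)
    percent_very_high: float   # > 250 mg/dL
    mean_glucose: float        # mg/dL
    gmi: float                 # %
    cv_percent: float          # 100 * SD / mean

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _observed_values(series) -> np.ndarray:
    """Observed (non-imputed) samples from a CGMSeries or array-like."""
    if hasattr(series, "glucose"):
        g = np.asarray(series.glucose, dtype=float)
        if getattr(series, "interpolated", None) is not None:
            g = g[~series.interpolated]
    else:
        g = np.asarray(series, dtype=float)
    return g[~np.isnan(g)]


def time_in_ranges(series) -> dict[str, float]:
    """Cumulative time-in-range percentages over observed samples."""
    g = _observed_values(series)
    if g.size == 0:
        raise ValueError("empty series")
    return {
        "percent_very_low": float(100.0 * np.mean(g < VERY_LOW)),
        "percent_low": float(100.0 * np.mean(g < LOW)),
        "percent_target": float(100.0 * np.mean((g >= LOW) & (g <= HIGH))),
        "percent_high": float(100.0 * np.mean(g > HIGH)),
        "percent_very_high": float(100.0 * np.mean(g > VERY_HIGH)),
    }


def gmi(mean_glucose: float) -> float:
    """Glucose management indicator (%) from mean glucose (mg/dL)."""
    if mean_glucose <= 0:
        raise ValueError("mean glucose must be positive")
    return 3.31 + 0.02392 * mean_glucose


def mean_glucose(series) -> float:
    g = _observed_values(series)
    if g.size == 0:
        raise ValueError("empty series")
    return float(np.mean(g))


def glucose_cv(series) -> float:
    """%CV = 100 * sample SD / mean over observed samples."""
    g = _observed_values(series)
    if g.size < 2:
        raise ValueError("need at least 2 observed samples")
    sd = float(np.std(g, ddof=1))
    return 100.0 * sd / float(np.mean(g))


def agp_report(series) -> AGPReport:
    """Bundle the full ambulatory-glucose-profile summary for one series."""
    ranges = time_in_ranges(series)
    mg = mean_glucose(series)
    return AGPReport(**ranges, mean_glucose=mg, gmi=gmi(mg),
                     cv_percent=glucose_cv(series))


def plot_parkes_scatter(reference, predicted, ax=None, title=None):
    """Scatter of predictions over the zone polygons (matplotlib Axes)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    shades = {"A": "#e8f5e9", "B": "#fffde7", "C": "#ffe0b2",
              "D": "#ffccbc", "E": "#ffcdd2"}
    for zone in ZONES:
        for poly in parkes_polygons_t2()[zone]:
            xs, ys = poly.exterior.xy
            ax.fill(xs, ys, color=shades[zone], zorder=0)
            cx, cy = poly.representative_point().coords[0]
            ax.annotate(zone, (cx, cy), fontsize=9, color="gray")
    ax.scatter(reference, predicted, s=4, alpha=0.5, zorder=2)
    ax.plot([0, GRID_MAX], [0, GRID_MAX], "k--", lw=0.5)
    ax.set_xlim(0, GRID_MAX)
    ax.set_ylim(0, GRID_MAX)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    if title:
        ax.set_title(title)
    return ax
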