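import numpy as np
import pytest

from cgmcast.preprocess import CGMSeries


def make_series(glucose, interval_min=5, patient_id="P001", sensor="sensor2",
                start="2023-03-01T00:00:00", interpolated=None, gaps=None):
    """Build a CGMSeries on a uniform grid from a plain value list."""
    glucose = np.asarray(glucose, dtype=float)
    ts = (np.datetime64(start) +
          (np.arange(glucose.size) * interval_min).astype("timedelta64[m]"))
    return CGMSeries(patient_id=patient_id, timestamps=ts.astype("datetime64[s]"),
                     glucose=glucose, sensor=sensor, native_interval=interval_min,
                     interpolated=interpolated, gaps=gaps or [])


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def small_cohort():
    """4 patients x 3 days, both sensors, light missingness."""
    from cgmcast.synth import SyntheticCohortConfig, simulate_cohort

    config = SyntheticCohortConfig(n_patients=4, n_sensor1=2,
                                   duration_days=(3, 3),
                                   missing_fraction=0.05, seed=11)
    return simulate_cohort(config)
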