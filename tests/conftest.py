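import numpy as np
import pandas as pd
import pytest

from lactload import MeasurementSeries, ObservationWindow


@pytest.fixture
def rng():
    return np.random.default_rng(20220325)


def random_series(rng, n_max=20, window=None, patient_id="r"):
    """Random irregular lactate series: n ~ U{1..n_max}, times ~ U[window],
    values ~ LogNormal."""
    window = window or ObservationWindow()
    n = int(rng.integers(1, n_max + 1))
    t = np.sort(rng.uniform(window.start, window.end, n))
    t = np.unique(t)
    v = rng.lognormal(np.log(2.0), 0.5, t.size)
    return MeasurementSeries(patient_id, t, v)


def quadrature_load(series, window, step=1e-4):
    """Independent oracle: dense-grid trapezoid integration of the
    boundary-extended piecewise-linear interpolant."""
    t = series.times
    v = series.values
    if t[0] > window.start:
        t = np.concatenate([[window.start], t])
        v = np.concatenate([[v[0]], v])
    if t[-1] < window.end:
        t = np.concatenate([t, [window.end]])
        v = np.concatenate([v, [v[-1]]])
    grid = np.linspace(window.start, window.end,
                       int(round(window.duration / step)) + 1)
    grid = np.union1d(grid, t)  # kinks of the interpolant must be on the grid
    return float(np.trapezoid(np.interp(grid, t, v), grid))


@pytest.fixture
def five_patient_cohort():
    """One patient failing each exclusion criterion plus one eligible."""
    patients = pd.DataFrame({
        "patient_id": ["minor", "repeat", "single", "short", "ok"],
        "age_years": [17.0, 50.0, 60.0, 70.0, 55.0],
        "first_icu_stay": [1, 0, 1, 1, 1],
        "icu_los_hours": [48.0, 48.0, 48.0, 20.0, 48.0],
        "sepsis": [0, 0, 1, 0, 1],
        "death_28d": [0, 0, 0, 1, 1],
    })
    series_index = {
        "minor": MeasurementSeries("minor", [1, 5], [2.0, 2.5]),
        "repeat": MeasurementSeries("repeat", [2, 9], [3.0, 2.0]),
        "single": MeasurementSeries("single", [4], [2.2]),
        "short": MeasurementSeries("short", [1, 6, 12], [4.0, 3.0, 2.0]),
        "ok": MeasurementSeries("ok", [2, 8, 20], [5.0, 3.0, 2.0]),
    }
    return patients, series_index
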