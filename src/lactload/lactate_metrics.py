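"""Lactate burden statistics from serial measurements.

A patient's lactate burden over an observation window (by default the
first 24 h of the ICU stay) is summarised four ways:

* ``max_lactate`` — highest observed concentration (mmol/L),
* ``mean_lactate`` — unweighted arithmetic mean of the observed values,
* ``lactate_load`` — area under the piecewise-linear lactate-vs-time
  curve (mmol·h/L), with the first observed value carried back to the
  window start and the last observed value carried forward to the window
  end before integration,
* ``normalized_lactate_load`` — lactate load divided by the window
  duration (mmol/L), i.e. the time-weighted average lactate.

The boundary-extension rule makes the load well defined even when the
first or last draw falls strictly inside the window: the value at the
window start is defined equal to the first measurement, and the value at
the window end equal to the last measurement within the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationWindow",
    "MeasurementSeries",
    "BurdenMetrics",
    "NoMeasurementsError",
    "extend_to_window",
    "lactate_load",
    "normalized_lactate_load",
    "summary_metrics",
    "read_measurements_csv",
]

MEASUREMENT_COLUMNS = ("patient_id", "time_hours", "lactate_mmol_l")


class NoMeasurementsError(ValueError):
    """Raised when a burden statistic is requested for a patient with no
    measurement inside the observation window."""


@dataclass(frozen=True)
class ObservationWindow:
    """Half-open-in-spirit observation window in hours since ICU admission."""

    start: float = 0.0
    end: float = 24.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.start) or not np.isfinite(self.end):
            raise ValueError("window bounds must be finite")
        if self.end <= self.start:
            raise ValueError(f"window end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class MeasurementSeries:
    """One patient's timed lactate values.

    ``times`` are hours since ICU admission, strictly increasing;
    ``values`` are lactate concentrations in mmol/L, one per time.
    Use :meth:`from_raw` to build a series from unnormalised data
    (unsorted times, duplicate timestamps, pre-admission draws).
    """

    patient_id: object
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-d and of equal length")
        if t.size == 0:
            raise NoMeasurementsError(f"patient {self.patient_id!r}: empty measurement series")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError(f"patient {self.patient_id!r}: non-finite time or lactate value")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"patient {self.patient_id!r}: times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError(f"patient {self.patient_id!r}: lactate values must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_raw(
        cls,
        patient_id: object,
        times: Iterable[float],
        values: Iterable[float],
        window: ObservationWindow | None = None,
    ) -> "MeasurementSeries":
        """Normalise raw draws into a valid series.

        Draws before the window start (e.g. pre-ICU samples) and after the
        window end are dropped with a logged count; duplicate timestamps are
        averaged so the series describes a function of time; the remainder
        is sorted.
        """
        window = window or ObservationWindow()
        t = np.asarray(list(times), dtype=float)
        v = np.asarray(list(values), dtype=float)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        keep = (t >= window.start) & (t <= window.end)
        n_dropped = int(t.size - keep.sum())
        if n_dropped:
            logger.debug(
                "patient %r: dropped %d measurement(s) outside [%g, %g] h",
                patient_id, n_dropped, window.start, window.end,
            )
        t, v = t[keep], v[keep]
        if t.size == 0:
            raise NoMeasurementsError(
                f"patient {patient_id!r}: no measurements within the observation window"
            )
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        uniq, inverse = np.unique(t, return_inverse=True)
        if uniq.size < t.size:
            v = np.bincount(inverse, weights=v) / np.bincount(inverse)
            t = uniq
        return cls(patient_id, t, v)


@dataclass(frozen=True)
class BurdenMetrics:
    """Per-patient lactate burden summary."""

    max_lactate: float
    mean_lactate: float
    lactate_load: float
    normalized_lactate_load: float
    n_measurements: int

    _FIELDS = ("max_lactate", "mean_lactate", "lactate_load",
               "normalized_lactate_load", "n_measurements")


def extend_to_window(series: MeasurementSeries, window: ObservationWindow) -> MeasurementSeries:
    """Carry the first/last observed values to the window boundaries.

    Adds a point at ``window.start`` holding the first observed value and a
    point at ``window.end`` holding the last observed value; points already
    sitting exactly on a boundary are not duplicated.
    """
    t, v = series.times, series.values
    if t[0] < window.start or t[-1] > window.end:
        raise ValueError("series extends outside the observation window")
    if t[0] > window.start:
        t = np.concatenate([[window.start], t])
        v = np.concatenate([[v[0]], v])
    if t[-1] < window.end:
        t = np.concatenate([t, [window.end]])
        v = np.concatenate([v, [v[-1]]])
    return MeasurementSeries(series.patient_id, t, v)


def lactate_load(series: MeasurementSeries, window: ObservationWindow | None = None) -> float:
    """Trapezoidal area (mmol·h/L) under the boundary-extended lactate curve."""
    window = window or ObservationWindow()
    ext = extend_to_window(series, window)
    return float(np.trapezoid(ext.values, ext.times))


def normalized_lactate_load(
    series: MeasurementSeries, window: ObservationWindow | None = None
) -> float:
    """Time-weighted average lactate (mmol/L): load divided by window duration."""
    window = window or ObservationWindow()
    return lactate_load(series, window) / window.duration


def summary_metrics(
    series: MeasurementSeries, window: ObservationWindow | None = None
) -> BurdenMetrics:
    """All four burden statistics for one patient.

    ``mean_lactate`` is the unweighted mean of the observed values — the
    time-weighting is exactly what distinguishes the normalized load from
    it. ``n_measurements`` counts observed points before boundary extension.
    """
    window = window or ObservationWindow()
    load = lactate_load(series, window)
    return BurdenMetrics(
        max_lactate=float(series.values.max()),
        mean_lactate=float(series.values.mean()),
        lactate_load=load,
        normalized_lactate_load=load / window.duration,
        n_measurements=len(series),
    )


def read_measurements_csv(
    path: str | Path, window: ObservationWindow | None = None
) -> dict[object, MeasurementSeries]:
    """Read a measurement table into per-patient series.

    Expects columns ``patient_id, time_hours, lactate_mmol_l``. Rows outside
    the window are dropped (logged) and duplicate timestamps averaged, per
    :meth:`MeasurementSeries.from_raw`. Patients whose draws all fall outside
    the window are omitted (they count as having no measurement downstream).
    """
    window = window or ObservationWindow()
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; expected {list(MEASUREMENT_COLUMNS)}"
        )
    index: dict[object, MeasurementSeries] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        try:
            index[pid] = MeasurementSeries.from_raw(
                pid, grp["time_hours"].to_numpy(), grp["lactate_mmol_l"].to_numpy(), window
            )
        except NoMeasurementsError:
            logger.debug("patient %r: all measurements outside window; omitted", pid)
    return index


def series_index_from_frame(
    df: pd.DataFrame, window: ObservationWindow | None = None
) -> dict[object, MeasurementSeries]:
    """Like :func:`read_measurements_csv` but from an in-memory DataFrame."""
    window = window or ObservationWindow()
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing column(s) {missing}")
    index: dict[object, MeasurementSeries] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        try:
            index[pid] = MeasurementSeries.from_raw(
                pid, grp["time_hours"].to_numpy(), grp["lactate_mmol_l"].to_numpy(), window
            )
        except NoMeasurementsError:
            pass
    return index
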