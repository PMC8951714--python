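"""Eligibility cascade and cohort stratification.

The analysis cohort is selected by four sequential exclusions, applied in
a fixed order with each patient attributed to the first criterion it
fails:

1. age < 18 years,
2. not the first ICU admission,
3. fewer than two lactate measurements within the observation window
   (zero measurements included),
4. ICU length of stay < 24 h.

Included patients are then split into sepsis and non-sepsis cohorts by a
supplied (adjudicated) sepsis flag, and optionally stratified by how many
lactate measurements they had within the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .lactate_metrics import MeasurementSeries, ObservationWindow

logger = logging.getLogger(__name__)

__all__ = [
    "PATIENT_COLUMNS",
    "FilterReport",
    "apply_exclusions",
    "split_by_sepsis",
    "stratify_by_measurement_count",
    "read_patients_csv",
]

PATIENT_COLUMNS = (
    "patient_id",
    "age_years",
    "first_icu_stay",
    "icu_los_hours",
    "sepsis",
    "death_28d",
)

# (label, predicate on a patient row + measurement count) in cascade order
EXCLUSION_LABELS = (
    "age < 18 years",
    "not first ICU admission",
    "< 2 lactate measurements in window",
    "ICU stay < 24 h",
)


@dataclass(frozen=True)
class FilterReport:
    """Accounting of the exclusion cascade."""

    steps: tuple[tuple[str, int], ...]
    n_screened: int
    n_included: int

    def __post_init__(self) -> None:
        if self.n_screened - sum(n for _, n in self.steps) != self.n_included:
            raise ValueError("filter report inconsistent: screened - excluded != included")

    def to_frame(self) -> pd.DataFrame:
        rows = [("screened", self.n_screened)]
        rows += [(f"excluded: {label}", n) for label, n in self.steps]
        rows.append(("included", self.n_included))
        return pd.DataFrame(rows, columns=["step", "n"])


def apply_exclusions(
    patients: pd.DataFrame,
    series_index: Mapping[object, MeasurementSeries],
    window: ObservationWindow | None = None,
    *,
    min_age: float = 18.0,
    min_measurements: int = 2,
    min_los_hours: float = 24.0,
) -> tuple[list, FilterReport]:
    """Apply the eligibility cascade; return included ids and the report.

    Patients absent from ``series_index`` count as having zero measurements.
    Series for unknown patient ids are ignored with a warning.
    """
    window = window or ObservationWindow()
    known = set(patients["patient_id"])
    unknown = [pid for pid in series_index if pid not in known]
    if unknown:
        logger.warning(
            "%d measurement series for patient ids absent from the patient table; ignored",
            len(unknown),
        )

    n_counts = {
        pid: len(s) for pid, s in series_index.items() if pid in known
    }

    excluded = [0, 0, 0, 0]
    included: list = []
    for row in patients.itertuples(index=False):
        if row.age_years < min_age:
            excluded[0] += 1
        elif not bool(row.first_icu_stay):
            excluded[1] += 1
        elif n_counts.get(row.patient_id, 0) < min_measurements:
            excluded[2] += 1
        elif row.icu_los_hours < min_los_hours:
            excluded[3] += 1
        else:
            included.append(row.patient_id)

    report = FilterReport(
        steps=tuple(zip(EXCLUSION_LABELS, excluded)),
        n_screened=len(patients),
        n_included=len(included),
    )
    logger.info(
        "exclusion cascade: screened %d → included %d (%s)",
        report.n_screened,
        report.n_included,
        ", ".join(f"{lbl}: {n}" for lbl, n in report.steps),
    )
    return included, report


def split_by_sepsis(patients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into (sepsis, non-sepsis), preserving row order."""
    if "sepsis" not in patients.columns:
        raise ValueError("patient table lacks a 'sepsis' column")
    if patients["sepsis"].isna().any():
        raise ValueError("sepsis flag missing for some patients")
    mask = patients["sepsis"].astype(bool)
    return patients[mask], patients[~mask]


def stratify_by_measurement_count(
    cohort: pd.DataFrame,
    series_index: Mapping[object, MeasurementSeries],
    k: int,
    *,
    exact: bool = False,
) -> pd.DataFrame:
    """Patients whose within-window measurement count is ≥ k (or == k).

    Counts are of observed points, before boundary extension.
    """
    if k < 2:
        raise ValueError("measurement-count threshold must be ≥ 2")
    def count(pid: object) -> int:
        s = series_index.get(pid)
        return len(s) if s is not None else 0
    counts = cohort["patient_id"].map(count)
    mask = counts == k if exact else counts >= k
    return cohort[mask]


def read_patients_csv(path: str | Path) -> pd.DataFrame:
    """Read the patient table; booleans encoded as 0/1."""
    df = pd.read_csv(path)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; expected at least {list(PATIENT_COLUMNS)}"
        )
    return df
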