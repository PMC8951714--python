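"""End-to-end analysis: ingest → exclusions → burden metrics → cohort
split → ROC/DeLong → Youden operating characteristics → measurement-count
sensitivity analysis.

Everything here is deterministic given the input tables and settings;
randomness lives only in the synthetic generator. Report numbers are kept
at full precision — rounding belongs to presentation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_filters import (
    FilterReport,
    apply_exclusions,
    read_patients_csv,
    split_by_sepsis,
    stratify_by_measurement_count,
)
from .group_stats import table_one
from .lactate_metrics import (
    MeasurementSeries,
    ObservationWindow,
    read_measurements_csv,
    series_index_from_frame,
    summary_metrics,
)
from .roc_stats import (
    SingleClassError,
    delong_components,
    independent_auc_test,
    delong_paired_test,
    operating_characteristics,
    roc_curve,
    youden_cutoff,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisReport", "run_analysis", "write_report"]

MARKERS = ("normalized_lactate_load", "max_lactate", "mean_lactate")
COHORTS = ("all", "sepsis", "non_sepsis")
COUNT_STRATA = (2, 3, 4, 5)


@dataclass
class AnalysisReport:
    """Bundle of every table the analysis produces."""

    filter_report: FilterReport
    burden: pd.DataFrame            # per-patient markers + outcome + cohort
    performance: pd.DataFrame       # marker × cohort: cutoff, AUC/CI, operating characteristics
    paired_comparisons: pd.DataFrame    # nll vs max / mean within each cohort
    unpaired_comparisons: pd.DataFrame  # sepsis vs non-sepsis per marker
    sensitivity: pd.DataFrame       # AUC of nll by measurement-count stratum × cohort
    table_one: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _burden_frame(patients, series_index, window) -> pd.DataFrame:
    rows = []
    for row in patients.itertuples(index=False):
        m = summary_metrics(series_index[row.patient_id], window)
        rows.append((
            row.patient_id, m.max_lactate, m.mean_lactate, m.lactate_load,
            m.normalized_lactate_load, m.n_measurements,
            bool(row.sepsis), bool(row.death_28d),
        ))
    return pd.DataFrame(rows, columns=[
        "patient_id", "max_lactate", "mean_lactate", "lactate_load",
        "normalized_lactate_load", "n_measurements", "sepsis", "death_28d",
    ])


def _cohort_mask(burden: pd.DataFrame, cohort: str) -> pd.Series:
    if cohort == "all":
        return pd.Series(True, index=burden.index)
    if cohort == "sepsis":
        return burden["sepsis"]
    return ~burden["sepsis"]


def _performance_rows(burden: pd.DataFrame, ci_level: float) -> pd.DataFrame:
    rows = []
    for cohort in COHORTS:
        sub = burden[_cohort_mask(burden, cohort)]
        labels = sub["death_28d"].to_numpy()
        for marker in MARKERS:
            scores = sub[marker].to_numpy()
            base = {"cohort": cohort, "marker": marker, "n": len(sub),
                    "n_deaths": int(labels.sum())}
            try:
                roc = roc_curve(scores, labels, ci_level)
                cut = youden_cutoff(scores, labels)
                op = operating_characteristics(scores, labels, cut, ci_level)
            except SingleClassError:
                logger.warning("cohort %r has a single outcome class; "
                               "inferential cells unavailable", cohort)
                rows.append(base)
                continue
            rows.append({**base,
                "cutoff": cut, "auc": roc.auc,
                "auc_lo": roc.auc_ci[0], "auc_hi": roc.auc_ci[1],
                "sensitivity": op.sensitivity,
                "sensitivity_lo": op.sensitivity_ci[0], "sensitivity_hi": op.sensitivity_ci[1],
                "specificity": op.specificity,
                "specificity_lo": op.specificity_ci[0], "specificity_hi": op.specificity_ci[1],
                "lr_pos": op.lr_pos, "lr_pos_lo": op.lr_pos_ci[0], "lr_pos_hi": op.lr_pos_ci[1],
                "lr_neg": op.lr_neg, "lr_neg_lo": op.lr_neg_ci[0], "lr_neg_hi": op.lr_neg_ci[1],
                "ppv": op.ppv, "ppv_lo": op.ppv_ci[0], "ppv_hi": op.ppv_ci[1],
                "npv": op.npv, "npv_lo": op.npv_ci[0], "npv_hi": op.npv_ci[1],
            })
    return pd.DataFrame(rows)


def _paired_rows(burden: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cohort in COHORTS:
        sub = burden[_cohort_mask(burden, cohort)]
        labels = sub["death_28d"].to_numpy()
        for other in ("max_lactate", "mean_lactate"):
            row = {"cohort": cohort, "marker_a": "normalized_lactate_load",
                   "marker_b": other}
            try:
                cmp_ = delong_paired_test(
                    sub["normalized_lactate_load"].to_numpy(),
                    sub[other].to_numpy(), labels,
                )
                row.update(auc_a=cmp_.auc_a, auc_b=cmp_.auc_b, z=cmp_.z,
                           p_two_sided=cmp_.p_two_sided)
            except SingleClassError:
                logger.warning("paired comparison skipped for single-class cohort %r", cohort)
            rows.append(row)
    return pd.DataFrame(rows)


def _unpaired_rows(burden: pd.DataFrame) -> pd.DataFrame:
    sep = burden[burden["sepsis"]]
    non = burden[~burden["sepsis"]]
    rows = []
    for marker in MARKERS:
        row = {"marker": marker, "cohort_a": "sepsis", "cohort_b": "non_sepsis"}
        try:
            ca = delong_components(
                sep.loc[sep["death_28d"], marker].to_numpy(),
                sep.loc[~sep["death_28d"], marker].to_numpy(),
            )
            cb = delong_components(
                non.loc[non["death_28d"], marker].to_numpy(),
                non.loc[~non["death_28d"], marker].to_numpy(),
            )
            cmp_ = independent_auc_test(ca, cb)
            row.update(auc_a=cmp_.auc_a, auc_b=cmp_.auc_b, z=cmp_.z,
                       p_two_sided=cmp_.p_two_sided)
        except SingleClassError:
            logger.warning("unpaired comparison skipped for marker %r", marker)
        rows.append(row)
    return pd.DataFrame(rows)


def _sensitivity_rows(
    patients: pd.DataFrame, burden: pd.DataFrame, series_index, ci_level: float
) -> pd.DataFrame:
    """AUC of normalized load within nested measurement-count strata."""
    rows = []
    by_id = burden.set_index("patient_id")
    for cohort in ("sepsis", "non_sepsis"):
        mask = patients["sepsis"].astype(bool)
        sub_pat = patients[mask] if cohort == "sepsis" else patients[~mask]
        for k in COUNT_STRATA:
            strat = stratify_by_measurement_count(sub_pat, series_index, k)
            row = {"cohort": cohort, "min_measurements": k, "n": len(strat)}
            if len(strat):
                b = by_id.loc[strat["patient_id"]]
                try:
                    roc = roc_curve(
                        b["normalized_lactate_load"].to_numpy(),
                        b["death_28d"].to_numpy(), ci_level,
                    )
                    comp = delong_components(
                        b.loc[b["death_28d"], "normalized_lactate_load"].to_numpy(),
                        b.loc[~b["death_28d"], "normalized_lactate_load"].to_numpy(),
                    )
                    row.update(auc=roc.auc, auc_lo=roc.auc_ci[0], auc_hi=roc.auc_ci[1],
                               auc_variance=comp.variance(),
                               n_deaths=int(b["death_28d"].sum()))
                except SingleClassError:
                    logger.warning("sensitivity stratum %s ≥%d has one outcome class", cohort, k)
            rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(
    measurements: str | Path | pd.DataFrame,
    patients: str | Path | pd.DataFrame,
    *,
    window: ObservationWindow | None = None,
    ci_level: float = 0.95,
) -> AnalysisReport:
    """Run the full cohort analysis on measurement and patient tables."""
    window = window or ObservationWindow()
    if isinstance(measurements, (str, Path)):
        series_index = read_measurements_csv(measurements, window)
    else:
        series_index = series_index_from_frame(measurements, window)
    if isinstance(patients, (str, Path)):
        patients = read_patients_csv(patients)
    else:
        patients = patients.copy()

    included_ids, filter_report = apply_exclusions(patients, series_index, window)
    included = patients[patients["patient_id"].isin(set(included_ids))]
    burden = _burden_frame(included, series_index, window)

    sep, non = split_by_sepsis(included)
    try:
        t1 = table_one(sep, non, continuous=["age_years", "icu_los_hours"],
                       categorical=["death_28d"])
    except ValueError as exc:
        logger.warning("table-one unavailable (%s); emitting empty table", exc)
        t1 = pd.DataFrame(
            columns=["variable", "summary_a", "summary_b", "test", "p_value"]
        )

    report = AnalysisReport(
        filter_report=filter_report,
        burden=burden,
        performance=_performance_rows(burden, ci_level),
        paired_comparisons=_paired_rows(burden),
        unpaired_comparisons=_unpaired_rows(burden),
        sensitivity=_sensitivity_rows(included, burden, series_index, ci_level),
        table_one=t1,
        metadata={
            "version": __version__,
            "window_start_hours": window.start,
            "window_end_hours": window.end,
            "ci_level": ci_level,
            "n_screened": filter_report.n_screened,
            "n_included": filter_report.n_included,
        },
    )
    return report


def write_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write every report table as CSV plus metadata JSON; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "filter_report": report.filter_report.to_frame(),
        "burden": report.burden,
        "performance": report.performance,
        "paired_comparisons": report.paired_comparisons,
        "unpaired_comparisons": report.unpaired_comparisons,
        "sensitivity": report.sensitivity,
        "table_one": report.table_one,
    }
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    meta = dict(report.metadata)
    meta["tables_sha256"] = {
        name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in paths.items()
    }
    mp = out / "metadata.json"
    mp.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["metadata"] = mp
    return paths
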