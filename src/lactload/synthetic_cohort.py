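"""Synthetic ICU cohort generator.

Emulates the data-generating reality that a time-weighted lactate
statistic summarises, so the full pipeline is testable without access to
a clinical database. Each patient has a latent exponential-decay lactate
trajectory

    Lac(t) = b + (L0 − b) · exp(−k·t)

(initial lactate L0, physiological baseline b, clearance rate k per hour)
from which irregularly timed, noisy measurements are drawn in the first
24 h. Sepsis patients start higher, clear slower, and are sampled more
densely. 28-day death is Bernoulli with logit β0_group + β1 · true
normalized load, so mortality is driven by the true lactate burden and
every observed marker is a noisy surrogate for it.

Measurement times are early-skewed (Beta-distributed over the window)
rather than uniform: lactate is drawn densely during early resuscitation,
which is also what makes time-weighting informative — an unweighted mean
of early-clustered draws over-represents the pre-clearance phase.

The generator also plants deliberately ineligible records (minors, repeat
ICU stays, single-measurement patients, stays shorter than 24 h) at
configurable rates so the exclusion cascade is exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lactate_metrics import MeasurementSeries, ObservationWindow

__all__ = [
    "TrajectoryParams",
    "ExponentialTrajectory",
    "GroupParams",
    "OutcomeCoefficients",
    "SyntheticConfig",
    "simulate_trajectory",
    "true_normalized_load",
    "sample_measurements",
    "simulate_outcome",
    "generate_cohort",
]

MIN_LACTATE = 0.1  # mmol/L floor for observed values


@dataclass(frozen=True)
class TrajectoryParams:
    """Latent kinetic parameters for one patient."""

    L0: float            # initial lactate, mmol/L
    baseline: float      # asymptotic lactate, mmol/L
    k: float             # clearance rate, 1/h
    sigma_meas: float    # measurement noise SD, mmol/L

    def __post_init__(self) -> None:
        if not (self.L0 > 0 and self.baseline > 0):
            raise ValueError("L0 and baseline must be positive")
        if self.k < 0:
            raise ValueError("clearance rate k must be ≥ 0")
        if self.sigma_meas < 0:
            raise ValueError("sigma_meas must be ≥ 0")


class ExponentialTrajectory:
    """Noiseless lactate curve Lac(t) = b + (L0 − b)·exp(−k·t)."""

    def __init__(self, params: TrajectoryParams):
        self.params = params

    def __call__(self, t):
        p = self.params
        return p.baseline + (p.L0 - p.baseline) * np.exp(-p.k * np.asarray(t, dtype=float))


def simulate_trajectory(params: TrajectoryParams) -> ExponentialTrajectory:
    return ExponentialTrajectory(params)


def true_normalized_load(
    trajectory: ExponentialTrajectory, window: ObservationWindow | None = None
) -> float:
    """Exact time average of the noiseless curve over the window.

    For k > 0 this is b + (L0 − b)·(1 − e^{−kT})/(kT) with T the window
    duration (after shifting the window to start at 0); for k = 0 it is L0.
    """
    window = window or ObservationWindow()
    p = trajectory.params
    T = window.duration
    if p.k == 0:
        return float(p.L0)
    # integrate from window.start, not 0, so shifted windows are honoured
    e0 = math.exp(-p.k * window.start)
    e1 = math.exp(-p.k * window.end)
    return float(p.baseline + (p.L0 - p.baseline) * (e0 - e1) / (p.k * T))


def sample_measurements(
    trajectory: ExponentialTrajectory,
    lam: float,
    rng: np.random.Generator,
    window: ObservationWindow | None = None,
    patient_id: object = "synthetic",
    time_skew: tuple[float, float] = (0.7, 2.0),
    min_count: int = 1,
) -> MeasurementSeries:
    """Draw an irregular, noisy measurement series from a trajectory.

    The number of draws is max(min_count, 1 + Poisson(max(λ − 1, 0))) so
    every patient has at least one; times are window.start +
    duration·Beta(time_skew), sorted; values are the curve plus
    N(0, sigma_meas²) noise, floored at 0.1 mmol/L. Deterministic given
    the generator state.
    """
    if lam <= 0:
        raise ValueError("sampling intensity λ must be positive")
    if min_count < 1:
        raise ValueError("min_count must be ≥ 1")
    window = window or ObservationWindow()
    n = max(min_count, 1 + int(rng.poisson(max(lam - 1.0, 0.0))))
    t = np.sort(window.start + window.duration * rng.beta(*time_skew, size=n))
    v = trajectory(t) + rng.normal(0.0, trajectory.params.sigma_meas, size=n)
    v = np.maximum(v, MIN_LACTATE)
    return MeasurementSeries.from_raw(patient_id, t, v, window)


@dataclass(frozen=True)
class OutcomeCoefficients:
    """Logistic model for 28-day death: logit p = β0_group + β1·true_nll."""

    beta0_nonsepsis: float = -3.6
    beta0_sepsis: float = -3.0
    beta1: float = 0.9


def simulate_outcome(
    true_nll: float, sepsis: bool, coeffs: OutcomeCoefficients, rng: np.random.Generator
) -> bool:
    beta0 = coeffs.beta0_sepsis if sepsis else coeffs.beta0_nonsepsis
    p = 1.0 / (1.0 + math.exp(-(beta0 + coeffs.beta1 * true_nll)))
    return bool(rng.random() < p)


@dataclass(frozen=True)
class GroupParams:
    """Lognormal population distributions for one sepsis stratum.

    ``*_meanlog``/``*_sdlog`` parametrise LogNormal draws of the initial
    lactate L0 (mmol/L), clearance k (1/h) and expected measurement count
    λ per 24 h.
    """

    l0_meanlog: float
    l0_sdlog: float
    k_meanlog: float
    k_sdlog: float
    lam_meanlog: float
    lam_sdlog: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; defaults echo the qualitative
    sepsis/non-sepsis contrasts of large ICU cohorts (higher initial
    lactate, slower clearance, denser sampling and higher mortality in
    sepsis) without claiming to match any database numerically."""

    n_patients: int = 20000
    p_sepsis: float = 0.2
    baseline: float = 1.0
    sigma_meas: float = 0.2
    time_skew: tuple[float, float] = (0.7, 2.0)
    nonsepsis: GroupParams = field(default_factory=lambda: GroupParams(
        l0_meanlog=math.log(2.8), l0_sdlog=0.4,
        k_meanlog=math.log(0.12), k_sdlog=1.2,
        lam_meanlog=math.log(2.2), lam_sdlog=0.7,
    ))
    sepsis: GroupParams = field(default_factory=lambda: GroupParams(
        l0_meanlog=math.log(3.6), l0_sdlog=0.5,
        k_meanlog=math.log(0.05), k_sdlog=1.2,
        lam_meanlog=math.log(6.0), lam_sdlog=0.5,
    ))
    outcome: OutcomeCoefficients = field(default_factory=OutcomeCoefficients)
    # eligibility nuisances
    p_minor: float = 0.01           # age drawn U(16, 18) → fails age criterion
    p_repeat_stay: float = 0.10     # not the first ICU admission
    p_short_stay: float = 0.13      # ICU stay drawn U(2, 24) h
    age_mean: float = 65.0
    age_sd: float = 16.0
    los_meanlog: float = math.log(90.0)   # hours, for non-short stays (≥ 24 h)
    los_sdlog: float = 0.9
    min_measurements: int = 1       # raise to 2 to disable single-draw patients
    window_hours: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be ≥ 1")
        for name in ("p_sepsis", "p_minor", "p_repeat_stay", "p_short_stay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma_meas < 0:
            raise ValueError("sigma_meas must be ≥ 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.window_hours <= 0:
            raise ValueError("window_hours must be positive")
        if self.min_measurements < 1:
            raise ValueError("min_measurements must be ≥ 1")

    @property
    def window(self) -> ObservationWindow:
        return ObservationWindow(0.0, self.window_hours)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["time_skew"] = list(self.time_skew)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for grp in ("nonsepsis", "sepsis"):
            if grp in d and isinstance(d[grp], dict):
                d[grp] = GroupParams(**d[grp])
        if "outcome" in d and isinstance(d["outcome"], dict):
            d["outcome"] = OutcomeCoefficients(**d["outcome"])
        if "time_skew" in d:
            d["time_skew"] = tuple(d["time_skew"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patients, measurements) tables in the pipeline's CSV dialects.

    The patient table additionally carries the latent truth columns
    ``true_nll``, ``L0`` and ``k`` for validation; the analysis pipeline
    ignores them. Fully reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    window = config.window

    is_sepsis = rng.random(n) < config.p_sepsis
    g = is_sepsis.astype(int)
    grp = (config.nonsepsis, config.sepsis)
    take = lambda attr: np.where(
        is_sepsis, getattr(grp[1], attr), getattr(grp[0], attr)
    )
    L0 = rng.lognormal(take("l0_meanlog"), take("l0_sdlog"))
    k = rng.lognormal(take("k_meanlog"), take("k_sdlog"))
    lam = rng.lognormal(take("lam_meanlog"), take("lam_sdlog"))

    # eligibility nuisances
    minor = rng.random(n) < config.p_minor
    age = np.where(
        minor,
        rng.uniform(16.0, 18.0, n),
        np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 100.0),
    )
    first_stay = rng.random(n) >= config.p_repeat_stay
    short = rng.random(n) < config.p_short_stay
    los = np.where(
        short,
        rng.uniform(2.0, 24.0, n),
        24.0 + rng.lognormal(config.los_meanlog, config.los_sdlog, n),
    )

    pat_rows = []
    meas_pid: list = []
    meas_t: list = []
    meas_v: list = []
    for i in range(n):
        pid = f"P{i:06d}"
        params = TrajectoryParams(
            L0=float(L0[i]), baseline=config.baseline, k=float(k[i]),
            sigma_meas=config.sigma_meas,
        )
        traj = ExponentialTrajectory(params)
        series = sample_measurements(
            traj, float(lam[i]), rng, window, patient_id=pid,
            time_skew=config.time_skew, min_count=config.min_measurements,
        )
        tnll = true_normalized_load(traj, window)
        dead = simulate_outcome(tnll, bool(is_sepsis[i]), config.outcome, rng)
        pat_rows.append((
            pid, float(age[i]), int(first_stay[i]), float(los[i]),
            int(is_sepsis[i]), int(dead), tnll, float(L0[i]), float(k[i]),
        ))
        meas_pid.extend([pid] * len(series))
        meas_t.append(series.times)
        meas_v.append(series.values)

    patients = pd.DataFrame(pat_rows, columns=[
        "patient_id", "age_years", "first_icu_stay", "icu_los_hours",
        "sepsis", "death_28d", "true_nll", "L0", "k",
    ])
    measurements = pd.DataFrame({
        "patient_id": meas_pid,
        "time_hours": np.concatenate(meas_t),
        "lactate_mmol_l": np.concatenate(meas_v),
    })
    return patients, measurements
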