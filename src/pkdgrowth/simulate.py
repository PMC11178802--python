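"""Synthetic ADPKD cohort generator.

Emulates the structure of a longitudinal imaging cohort: each patient has
a hidden true growth rate and true birth volume, presents for a first scan
in mid-adulthood, and is rescanned roughly every two years over an 8-16
year follow-up.  Two mechanisms make the single-scan MIC estimate miss the
true rate, mirroring real cohorts:

* the true htTKV at birth is log-normally dispersed around 150 mL/m
  (``sigma0``), so the MIC birth assumption is wrong patient by patient —
  males and PKD2 carriers get a multiplicatively shifted birth-volume
  median, which couples covariates to MIC misalignment;
* each measurement carries multiplicative log-normal noise (``noise_cv``).

Every distributional default beyond the cohort's printed medians and
fractions is an invented modelling choice, documented in the field
comments, and overridable per instance or via a YAML mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import List, Tuple

import numpy as np

from .core import ScanObservation, Trajectory
from .errors import InvalidConfigError



@dataclass(frozen=True)
class SimConfig:
    """All distributional knobs of the synthetic cohort generator.

    Rates are annual fractions; volumes mL/m; ages and intervals in years.
    """

    n_patients: int = 36
    seed: int = 0
    # age at first scan: normal, truncated to [18, 70] years
    age_first_mean: float = 42.0
    age_first_sd: float = 12.0
    age_first_bounds: Tuple[float, float] = (18.0, 70.0)
    # follow-up span: uniform in years (cohort inclusion demanded >= 8)
    followup_min: float = 8.0
    followup_max: float = 16.0
    # rescans roughly every 2 years with jitter
    scan_interval_mean: float = 2.0
    scan_interval_sd: float = 0.5
    scan_interval_min: float = 0.25
    # true annual growth rate: log-normal, median 3.6 %/yr
    r_median: float = 0.036
    r_log_sd: float = 0.45
    r_floor: float = -0.01
    # true birth volume: log-normal around 150 mL/m
    httkv0_median: float = 150.0
    sigma0: float = 0.5
    # multiplicative measurement noise (log-sd, approx. a CV at this scale)
    noise_cv: float = 0.03
    # covariate mix and their birth-volume shifts
    male_fraction: float = 0.58
    pkd2_fraction: float = 0.30
    other_genotype_fraction: float = 0.28
    pkd1_truncating_fraction: float = 0.33  # of PKD1 carriers
    pkd2_truncating_fraction: float = 0.64  # of PKD2 carriers
    hypertension_fraction: float = 0.81
    httkv0_shift_male: float = 1.3
    httkv0_shift_pkd2: float = 1.3

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be >= 1")
        for name in (
            "age_first_sd",
            "followup_min",
            "followup_max",
            "scan_interval_mean",
            "scan_interval_min",
            "r_median",
            "httkv0_median",
            "httkv0_shift_male",
            "httkv0_shift_pkd2",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name in ("r_log_sd", "sigma0", "noise_cv", "scan_interval_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        for name in (
            "male_fraction",
            "pkd2_fraction",
            "other_genotype_fraction",
            "pkd1_truncating_fraction",
            "pkd2_truncating_fraction",
            "hypertension_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if self.pkd2_fraction + self.other_genotype_fraction > 1:
            raise InvalidConfigError("genotype fractions exceed 1")
        if self.followup_max < self.followup_min:
            raise InvalidConfigError("followup_max < followup_min")
        if self.scan_interval_min > self.followup_min:
            raise InvalidConfigError(
                "infeasible schedule: minimum scan interval exceeds the follow-up span"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass(frozen=True)
class SimulatedPatient:
    """A trajectory plus its hidden generating truth."""

    trajectory: Trajectory
    r_true: float
    httkv0_true: float


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise InvalidConfigError("truncated-normal bounds are unreachable")


def _scan_ages(rng: np.random.Generator, cfg: SimConfig, age_first: float, followup: float):
    """Scan schedule: first scan at age_first, last at or just past followup end."""
    for _ in range(100):
        times = [0.0]
        while times[-1] < followup:
            step = max(rng.normal(cfg.scan_interval_mean, cfg.scan_interval_sd),
                       cfg.scan_interval_min)
            times.append(times[-1] + step)
        if len(times) >= 4:
            return [age_first + t for t in times]
    raise InvalidConfigError("could not draw a schedule with >= 4 scans")


def _draw_patient(cfg: SimConfig, index: int) -> SimulatedPatient:
    # per-patient substream keyed by (seed, index): patients are independent
    # of cohort size and of each other
    rng = np.random.default_rng([cfg.seed, index])

    sex = "male" if rng.random() < cfg.male_fraction else "female"
    u = rng.random()
    if u < cfg.pkd2_fraction:
        gene = "PKD2"
    elif u < cfg.pkd2_fraction + cfg.other_genotype_fraction:
        gene = "other"
    else:
        gene = "PKD1"
    if gene == "other":
        genotype = "other"
    else:
        trunc_p = (
            cfg.pkd2_truncating_fraction if gene == "PKD2" else cfg.pkd1_truncating_fraction
        )
        suffix = "truncating" if rng.random() < trunc_p else "nontruncating"
        genotype = f"{gene}_{suffix}"
    hypertension = bool(rng.random() < cfg.hypertension_fraction)

    r_true = float(np.exp(rng.normal(np.log(cfg.r_median), cfg.r_log_sd)))
    while r_true <= cfg.r_floor:  # guard; a log-normal draw is already > 0
        r_true = float(np.exp(rng.normal(np.log(cfg.r_median), cfg.r_log_sd)))

    median0 = cfg.httkv0_median
    if sex == "male":
        median0 *= cfg.httkv0_shift_male
    if gene == "PKD2":
        median0 *= cfg.httkv0_shift_pkd2
    httkv0_true = float(np.exp(rng.normal(np.log(median0), cfg.sigma0)))

    age_first = _truncated_normal(
        rng, cfg.age_first_mean, cfg.age_first_sd, *cfg.age_first_bounds
    )
    followup = float(rng.uniform(cfg.followup_min, cfg.followup_max))
    ages = _scan_ages(rng, cfg, age_first, followup)

    obs = []
    for age in ages:
        noise = float(np.exp(rng.normal(0.0, cfg.noise_cv))) if cfg.noise_cv > 0 else 1.0
        httkv = httkv0_true * (1.0 + r_true) ** age * noise
        obs.append(ScanObservation(age_years=age, httkv=httkv))

    traj = Trajectory(
        patient_id=f"sim{index:04d}",
        observations=obs,
        sex=sex,
        genotype=genotype,
        hypertension=hypertension,
    )
    return SimulatedPatient(trajectory=traj, r_true=r_true, httkv0_true=httkv0_true)


def simulate_cohort(config: SimConfig) -> List[SimulatedPatient]:
    """Draw a cohort; deterministic for a fixed ``config.seed``.

    Every patient has at least 4 scans spanning at least ``followup_min``
    years (the cohort's inclusion criteria), with strictly increasing ages.
    """
    return [_draw_patient(config, i) for i in range(config.n_patients)]


def degrade_to_k_scans(patient: SimulatedPatient, k: int) -> SimulatedPatient:
    """Keep only the first ``k`` scans chronologically; truth unchanged."""
    n = patient.trajectory.n_scans
    if k < 1 or k > n:
        raise IndexError(f"k={k} out of range for {n} scans")
    traj = patient.trajectory
    return SimulatedPatient(
        trajectory=Trajectory(
            patient_id=traj.patient_id,
            observations=traj.observations[:k],
            sex=traj.sex,
            genotype=traj.genotype,
            hypertension=traj.hypertension,
        ),
        r_true=patient.r_true,
        httkv0_true=patient.httkv0_true,
    )
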