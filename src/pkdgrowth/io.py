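"""Cohort CSV readers/writers and per-timepoint sequence aggregation.

The canonical trajectory table is long-format CSV with one row per
measurement::

    patient_id, age_years, httkv_ml_per_m [, sequence_id]

Two input dialects are also accepted, never mixed within one file:

* dates instead of ages — columns ``dob`` and ``scan_date`` (ISO dates);
  age is computed as elapsed days / 365.25;
* raw volumes instead of height-adjusted ones — columns ``tkv_ml`` and
  ``height_m``; htTKV = TKV / height.

When several pulse sequences were segmented at one timepoint (multiple
rows sharing patient and age, distinguished by ``sequence_id``), their
volumes are averaged into a single observation and a coefficient-of-
variation QC flag is raised when the sequences disagree too much.

An optional metadata CSV (``patient_id, sex, genotype, hypertension``)
supplies covariates; absent patients default to unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import GENOTYPES, ScanObservation, Trajectory
from .errors import CohortParseError, InvalidInputError

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DEFAULT_CV_THRESHOLD = 0.10

_AGE_COLS = {"age_years"}
_DATE_COLS = {"dob", "scan_date"}
_HTTKV_COLS = {"httkv_ml_per_m"}
_TKV_COLS = {"tkv_ml", "height_m"}


@dataclass(frozen=True)
class SequenceQC:
    """Per-timepoint agreement of volumes measured on different sequences."""

    n_sequences: int
    mean_tkv: float
    sd_tkv: float
    cv: float
    flag: bool


def aggregate_sequence_volumes(
    volumes: Sequence[float], cv_threshold: float = DEFAULT_CV_THRESHOLD
) -> SequenceQC:
    """Average one timepoint's per-sequence volumes with a CV-based QC flag.

    The final volume is the arithmetic mean; the coefficient of variation
    (sample SD / mean, zero for a single sequence) is flagged when it
    exceeds ``cv_threshold``.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise InvalidInputError("need at least one volume")
    if np.any(v <= 0):
        raise InvalidInputError("volumes must be > 0")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    cv = sd / mean
    return SequenceQC(
        n_sequences=int(v.size), mean_tkv=mean, sd_tkv=sd, cv=cv, flag=cv > cv_threshold
    )


def _ages_from_dates(df: pd.DataFrame) -> pd.Series:
    dob = pd.to_datetime(df["dob"], errors="coerce")
    scan = pd.to_datetime(df["scan_date"], errors="coerce")
    bad = dob.isna() | scan.isna()
    if bad.any():
        raise CohortParseError(f"unparseable date at row(s) {list(df.index[bad])}")
    return (scan - dob).dt.days / DAYS_PER_YEAR


def read_cohort(
    trajectory_csv: Union[str, Path],
    metadata_csv: Optional[Union[str, Path]] = None,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> List[Trajectory]:
    """Read a trajectory CSV (plus optional metadata CSV) into Trajectories.

    Rows sharing (patient_id, age) are treated as per-sequence measurements
    of one timepoint and averaged; timepoints whose sequences disagree
    beyond ``cv_threshold`` are kept but logged.
    """
    df = pd.read_csv(trajectory_csv)
    cols = set(df.columns)
    if "patient_id" not in cols:
        raise CohortParseError("missing required column patient_id")

    if _AGE_COLS <= cols and _DATE_COLS & cols:
        raise CohortParseError("age_years and dob/scan_date dialects must not be mixed")
    if _AGE_COLS <= cols:
        age = df["age_years"].astype(float)
    elif _DATE_COLS <= cols:
        age = _ages_from_dates(df)
    else:
        raise CohortParseError("need either age_years or dob + scan_date columns")

    if _HTTKV_COLS & cols and _TKV_COLS & cols:
        raise CohortParseError("httkv_ml_per_m and tkv_ml/height_m dialects must not be mixed")
    if _HTTKV_COLS <= cols:
        httkv = df["httkv_ml_per_m"].astype(float)
    elif _TKV_COLS <= cols:
        height = df["height_m"].astype(float)
        bad = ~(height > 0)
        if bad.any():
            raise CohortParseError(f"nonpositive height at row(s) {list(df.index[bad])}")
        httkv = df["tkv_ml"].astype(float) / height
    else:
        raise CohortParseError("need either httkv_ml_per_m or tkv_ml + height_m columns")

    bad = ~(httkv > 0) | httkv.isna()
    if bad.any():
        raise CohortParseError(f"nonpositive volume at row(s) {list(df.index[bad])}")
    bad = ~(age > 0) | age.isna()
    if bad.any():
        raise CohortParseError(f"nonpositive age at row(s) {list(df.index[bad])}")

    work = pd.DataFrame(
        {"patient_id": df["patient_id"].astype(str), "age": age, "httkv": httkv}
    )
    if "sequence_id" in cols:
        dup = df.duplicated(subset=["patient_id", *(_AGE_COLS & cols or _DATE_COLS),
                                    "sequence_id"], keep=False)
        if dup.any():
            raise CohortParseError(
                f"duplicate (patient, age, sequence) at row(s) {list(df.index[dup])}"
            )

    meta = {}
    if metadata_csv is not None:
        mdf = pd.read_csv(metadata_csv)
        if "patient_id" not in mdf.columns:
            raise CohortParseError("metadata CSV missing patient_id")
        for _, row in mdf.iterrows():
            hyp = row.get("hypertension")
            meta[str(row["patient_id"])] = {
                "sex": str(row.get("sex", "unknown")) or "unknown",
                "genotype": str(row.get("genotype", "other")) or "other",
                "hypertension": None if pd.isna(hyp) else bool(hyp),
            }

    trajectories = []
    for pid, sub in work.groupby("patient_id", sort=True):
        obs = []
        for a, tp in sub.groupby("age", sort=True):
            qc = aggregate_sequence_volumes(tp["httkv"].to_numpy(), cv_threshold)
            if qc.flag:
                logger.warning(
                    "patient %s age %.2f: sequence CV %.3f exceeds %.3f",
                    pid, a, qc.cv, cv_threshold,
                )
            obs.append(ScanObservation(age_years=float(a), httkv=qc.mean_tkv))
        m = meta.get(pid, {})
        genotype = m.get("genotype", "other")
        if genotype not in GENOTYPES:
            genotype = "other"
        sex = m.get("sex", "unknown")
        if sex not in ("male", "female"):
            sex = "unknown"
        trajectories.append(
            Trajectory(
                patient_id=pid,
                observations=obs,
                sex=sex,
                genotype=genotype,
                hypertension=m.get("hypertension"),
            )
        )
    return trajectories


def write_cohort(
    trajectories: Sequence[Trajectory],
    trajectory_csv: Union[str, Path],
    metadata_csv: Optional[Union[str, Path]] = None,
) -> None:
    """Write trajectories (and optionally covariates) in the canonical schema."""
    rows = [
        {"patient_id": t.patient_id, "age_years": o.age_years,
         "httkv_ml_per_m": o.httkv}
        for t in trajectories
        for o in t.observations
    ]
    pd.DataFrame(rows).to_csv(trajectory_csv, index=False)
    if metadata_csv is not None:
        meta = [
            {
                "patient_id": t.patient_id,
                "sex": t.sex,
                "genotype": t.genotype,
                "hypertension": "" if t.hypertension is None else t.hypertension,
            }
            for t in trajectories
        ]
        pd.DataFrame(meta).to_csv(metadata_csv, index=False)


def write_truth(patients, truth_csv: Union[str, Path]) -> None:
    """Write a simulated cohort's hidden truth (patient_id, r_true, httkv0_true)."""
    pd.DataFrame(
        [
            {
                "patient_id": p.trajectory.patient_id,
                "r_true": p.r_true,
                "httkv0_true": p.httkv0_true,
            }
            for p in patients
        ]
    ).to_csv(truth_csv, index=False)
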