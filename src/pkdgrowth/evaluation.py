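"""Incremental prediction-accuracy evaluation of the growth-rate estimators.

The harness replays each patient's clinical history: present the
estimators with the first 2 scans, then 3, and so on up to all ``n``
scans, and score each method's rate against the patient's long-follow-up
reference rate (the two-parameter fit on every scan).  Absolute errors are
kept in percentage points per year — the scale accuracy tables are printed
in — while rates elsewhere in the package stay fractions.

Patients are also sorted into alignment groups by how far the single-scan
MIC estimate from their index (first) scan sits from the reference rate:
ideal (< 0.75 %/yr, within one class band), slight ([0.75, 1.5) %/yr) and
substantial (>= 1.5 %/yr) misalignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import MayoClass, Trajectory, mic_class, mic_rate
from .errors import DegenerateDesignError, InvalidInputError
from .estimators import (
    ESTIMATOR_IDS,
    blend_mic_lsf2,
    fit_ground_truth,
    fit_lsf1,
    fit_lsf2,
    fit_mic_average,
    fit_mic_latest,
)

logger = logging.getLogger(__name__)

#: Alignment thresholds in %/yr; closed lower bounds (one class band = 0.75).
ALIGNMENT_IDEAL_LT = 0.75
ALIGNMENT_SUBSTANTIAL_GE = 1.5

#: Follow-up span bins in years, closed on the left.
SPAN_BIN_EDGES = (0.0, 3.0, 5.0, 7.0, 9.0, 12.0, 15.0, math.inf)
SPAN_BIN_LABELS = ("<3", "3-5", "5-7", "7-9", "9-12", "12-15", "15+")

K_BIN_MAX = 10  # k of 10 and above pool into "10+"


@dataclass(frozen=True)
class AssessmentRow:
    """One (patient, k-scans-available) evaluation record.

    ``rates`` and ``abs_errors`` map estimator id to the fitted annual rate
    (fraction) and its absolute error versus the reference rate (%/yr);
    methods that need more scans than ``k`` provides are ``None``.
    """

    patient_id: str
    k: int
    span_years: float
    ground_truth_rate: float
    rates: Dict[str, Optional[float]]
    abs_errors: Dict[str, Optional[float]]
    sex: str = "unknown"
    genotype: str = "other"


@dataclass(frozen=True)
class AlignmentGroup:
    """Index-scan MIC deviation from the reference rate, in %/yr."""

    label: str  # ideal | slight | substantial
    deviation: float


@dataclass(frozen=True)
class SummaryCell:
    """Mean +- sample SD of absolute error (%/yr) per method, for one group."""

    grouping: str
    group: str
    n: int
    mean_abs_error: Dict[str, float]
    sd_abs_error: Dict[str, float]


@dataclass(frozen=True)
class MicClassTrack:
    """Per-scan Mayo classes and the first scan index at which they change."""

    classes: Tuple[Tuple[int, MayoClass], ...]
    first_change_k: Optional[int]


def _assess_one(traj: Trajectory, k: int, truth_rate: float, fit_space: str) -> AssessmentRow:
    rates: Dict[str, Optional[float]] = dict.fromkeys(ESTIMATOR_IDS)
    rates["mic_latest"] = fit_mic_latest(traj, k).rate_r
    if k >= 2:
        rates["mic_average"] = fit_mic_average(traj, k).rate_r
        rates["lsf1"] = fit_lsf1(traj, k, fit_space=fit_space).rate_r
        rates["lsf2"] = fit_lsf2(traj, k, fit_space=fit_space).rate_r
        rates["blend_mic_lsf2"] = blend_mic_lsf2(traj, k, fit_space=fit_space).rate_r
    errors = {
        m: None if r is None else abs(r - truth_rate) * 100.0 for m, r in rates.items()
    }
    return AssessmentRow(
        patient_id=traj.patient_id,
        k=k,
        span_years=traj.observations[k - 1].age_years - traj.observations[0].age_years,
        ground_truth_rate=truth_rate,
        rates=rates,
        abs_errors=errors,
        sex=traj.sex,
        genotype=traj.genotype,
    )


def incremental_assessments(
    cohort: Sequence[Trajectory],
    include_index_mic: bool = False,
    exclude_terminal_assessment: bool = False,
    fit_space: str = "log",
) -> List[AssessmentRow]:
    """One row per (patient, k) for k = 2..n, scoring all five estimators.

    With ``include_index_mic`` an extra k=1 row per patient carries the
    index-scan MIC alone (the only estimator defined from one scan).  With
    ``exclude_terminal_assessment`` the k = n row — where the two-parameter
    fit coincides with the reference fit — is dropped.  Patients whose
    reference fit is degenerate are excluded with a logged warning.
    """
    rows: List[AssessmentRow] = []
    for traj in cohort:
        if traj.n_scans < 2:
            logger.warning("patient %s: fewer than 2 scans, excluded", traj.patient_id)
            continue
        try:
            truth = fit_ground_truth(traj, fit_space=fit_space).rate_r
        except DegenerateDesignError:
            logger.warning(
                "patient %s: degenerate ground-truth design, excluded", traj.patient_id
            )
            continue
        k_max = traj.n_scans - 1 if exclude_terminal_assessment else traj.n_scans
        if include_index_mic:
            rows.append(_assess_one(traj, 1, truth, fit_space))
        for k in range(2, k_max + 1):
            rows.append(_assess_one(traj, k, truth, fit_space))
    return rows


def assessments_to_frame(rows: Sequence[AssessmentRow]) -> pd.DataFrame:
    """Long-to-wide: one DataFrame row per assessment, error columns per method."""
    records = []
    for r in rows:
        rec = {
            "patient_id": r.patient_id,
            "k": r.k,
            "span_years": r.span_years,
            "sex": r.sex,
            "genotype": r.genotype,
            "ground_truth_rate_pct": r.ground_truth_rate * 100.0,
        }
        for m in ESTIMATOR_IDS:
            rec[f"rate_pct_{m}"] = None if r.rates[m] is None else r.rates[m] * 100.0
            rec[f"abs_error_pct_{m}"] = r.abs_errors[m]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def _genotype_group(genotype: str) -> str:
    if genotype.startswith("PKD1"):
        return "PKD1"
    if genotype.startswith("PKD2"):
        return "PKD2"
    return "Other"


def span_bin(span_years: float) -> str:
    """Bin a follow-up span; bins are closed on the left, open on the right."""
    for lo, hi, label in zip(SPAN_BIN_EDGES, SPAN_BIN_EDGES[1:], SPAN_BIN_LABELS):
        if lo <= span_years < hi:
            return label
    raise InvalidInputError(f"span_years must be >= 0, got {span_years}")


def k_bin(k: int) -> str:
    return f"{K_BIN_MAX}+" if k >= K_BIN_MAX else str(k)


GROUPINGS = ("all", "genotype", "sex", "span_bins", "k_bins")


def summarize(rows: Sequence[AssessmentRow], grouping: str = "all") -> List[SummaryCell]:
    """Mean +- sample SD (%/yr) of each method's absolute error, per group.

    ``grouping`` is one of ``all``, ``genotype`` (PKD1 / PKD2 / Other),
    ``sex``, ``span_bins`` (follow-up years at assessment time) or
    ``k_bins`` (timepoints used, 10 and above pooled).  Means ignore the
    methods undefined at a given k (e.g. everything but MIC at k=1).
    """
    if not rows:
        raise InvalidInputError("rows must be nonempty")
    if grouping not in GROUPINGS:
        raise InvalidInputError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")
    df = assessments_to_frame(rows)
    if grouping == "all":
        df["_group"] = "all"
    elif grouping == "genotype":
        df["_group"] = df["genotype"].map(_genotype_group)
    elif grouping == "sex":
        df["_group"] = df["sex"]
    elif grouping == "span_bins":
        df["_group"] = df["span_years"].map(span_bin)
    else:
        df["_group"] = df["k"].map(k_bin)

    cells = []
    for group, sub in df.groupby("_group", sort=True):
        means, sds = {}, {}
        for m in ESTIMATOR_IDS:
            col = sub[f"abs_error_pct_{m}"].dropna()
            means[m] = float(col.mean()) if len(col) else float("nan")
            sds[m] = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        cells.append(
            SummaryCell(
                grouping=grouping,
                group=str(group),
                n=int(len(sub)),
                mean_abs_error=means,
                sd_abs_error=sds,
            )
        )
    return cells


def summary_to_frame(cells: Sequence[SummaryCell]) -> pd.DataFrame:
    records = []
    for c in cells:
        rec = {"grouping": c.grouping, "group": c.group, "n": c.n}
        for m in ESTIMATOR_IDS:
            rec[f"mean_abs_error_pct_{m}"] = c.mean_abs_error[m]
            rec[f"sd_abs_error_pct_{m}"] = c.sd_abs_error[m]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def alignment_label(deviation_pct: float) -> str:
    """Band a deviation (%/yr): ideal below 0.75, slight in [0.75, 1.5),
    substantial at or above 1.5.  Bounds are closed below and compared
    exactly — they are definitional, one class band wide."""
    if deviation_pct < 0:
        raise InvalidInputError("deviation must be >= 0")
    if deviation_pct < ALIGNMENT_IDEAL_LT:
        return "ideal"
    if deviation_pct < ALIGNMENT_SUBSTANTIAL_GE:
        return "slight"
    return "substantial"


def alignment_group(traj: Trajectory, fit_space: str = "log") -> AlignmentGroup:
    """Classify index-scan MIC deviation from the reference rate.

    Deviation is |r_MIC(index scan) - r_reference| in %/yr, banded by
    :func:`alignment_label`.
    """
    truth = fit_ground_truth(traj, fit_space=fit_space).rate_r
    index = traj.observations[0]
    dev = abs(mic_rate(index.age_years, index.httkv) - truth) * 100.0
    return AlignmentGroup(label=alignment_label(dev), deviation=dev)


def progression_direction(traj: Trajectory, fit_space: str = "log") -> str:
    """Whether the patient progressed faster or slower than the index-scan MIC.

    Ideal-aligned patients are reported ``aligned``; otherwise ``faster``
    when the reference rate exceeds the index-scan MIC rate, ``slower``
    when it falls short.
    """
    grp = alignment_group(traj, fit_space=fit_space)
    if grp.label == "ideal":
        return "aligned"
    truth = fit_ground_truth(traj, fit_space=fit_space).rate_r
    index = traj.observations[0]
    return "faster" if truth > mic_rate(index.age_years, index.httkv) else "slower"


def mic_class_changes(traj: Trajectory) -> MicClassTrack:
    """Per-scan Mayo classes and the first scan whose class differs from scan 1."""
    classes = tuple(
        (k, mic_class(mic_rate(o.age_years, o.httkv)))
        for k, o in enumerate(traj.observations, start=1)
    )
    first = classes[0][1]
    change = next((k for k, c in classes[1:] if c != first), None)
    return MicClassTrack(classes=classes, first_change_k=change)
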