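"""Growth-rate estimators from serial htTKV measurements.

Five estimators of the annual fractional growth rate ``r`` from the first
``k`` scans of a trajectory, all built on the exponential model
``httkv(t) = httkv0 * (1 + r)**t``:

``mic_latest``
    Mayo Imaging Classification formula applied to scan ``k`` alone,
    assuming htTKV at birth is 150 mL/m.
``mic_average``
    Arithmetic mean of the single-scan MIC rates of scans 1..k.
``lsf1``
    One-parameter least squares of log volume on age with the intercept
    pinned at ln 150 (the MIC birth assumption); closed form
    ``b = sum(t_i * (ln v_i - ln 150)) / sum(t_i**2)``, ``r = e**b - 1``.
``lsf2``
    Ordinary two-parameter least squares of log volume on age; both the
    rate and the birth volume are free.
``blend_mic_lsf2``
    The arithmetic mean of the ``mic_latest`` and ``lsf2`` rates.

The long-follow-up reference ("ground truth") rate is ``lsf2`` on all
available scans.  ``recommend_rate`` applies the scan-count rule: with one
or two scans MIC is the best available, with exactly three the MIC/lsf2
blend wins, and from four scans on the two-parameter fit dominates.

Least squares is performed in log-volume space by default (the model is
exactly linear there, and measurement error in volumes is multiplicative);
``fit_space="linear"`` instead minimises squared residuals in volume space
by iterative nonlinear least squares initialised from the log fit.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import least_squares

from .core import MIC_BIRTH_HTTKV, GrowthFit, Trajectory, mic_rate
from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

FIT_SPACES = ("log", "linear")

ESTIMATOR_IDS = ("mic_latest", "mic_average", "lsf1", "lsf2", "blend_mic_lsf2")


def _first_k(traj: Trajectory, k: int, minimum: int = 1):
    if not isinstance(k, (int, np.integer)):
        raise InvalidInputError(f"k must be an integer, got {k!r}")
    if k < 1 or k > traj.n_scans:
        raise IndexError(f"k={k} out of range for {traj.n_scans} scans")
    if k < minimum:
        raise InsufficientDataError(f"method needs at least {minimum} scans, got k={k}")
    obs = traj.observations[:k]
    ages = np.array([o.age_years for o in obs], dtype=float)
    vols = np.array([o.httkv for o in obs], dtype=float)
    return ages, vols


def _check_fit_space(fit_space: str) -> None:
    if fit_space not in FIT_SPACES:
        raise InvalidInputError(f"fit_space must be one of {FIT_SPACES}, got {fit_space!r}")


def _rss_log(ages: np.ndarray, vols: np.ndarray, rate: float, httkv0: float) -> float:
    resid = np.log(vols) - (np.log(httkv0) + ages * np.log1p(rate))
    return float(resid @ resid)


def fit_mic_latest(traj: Trajectory, k: int) -> GrowthFit:
    """MIC rate from scan ``k`` (1-based, chronological) alone."""
    ages, vols = _first_k(traj, k)
    r = mic_rate(ages[-1], vols[-1])
    return GrowthFit(rate_r=r, httkv0=MIC_BIRTH_HTTKV, method="mic_latest", n_points=1)


def fit_mic_average(traj: Trajectory, k: int) -> GrowthFit:
    """Arithmetic mean of the single-scan MIC rates of scans 1..k."""
    ages, vols = _first_k(traj, k, minimum=2)
    rates = (vols / MIC_BIRTH_HTTKV) ** (1.0 / ages) - 1.0
    r = float(rates.mean())
    return GrowthFit(
        rate_r=r,
        httkv0=MIC_BIRTH_HTTKV,
        method="mic_average",
        n_points=k,
        rss_log=_rss_log(ages, vols, r, MIC_BIRTH_HTTKV),
    )


def _linear_refine(ages, vols, r0, httkv0_0, free_intercept):
    """Nonlinear least squares in volume space, started from the log fit."""

    if free_intercept:
        def resid(p):
            return p[1] * np.exp(ages * p[0]) - vols

        x0 = np.array([np.log1p(r0), httkv0_0])
    else:
        def resid(p):
            return MIC_BIRTH_HTTKV * np.exp(ages * p[0]) - vols

        x0 = np.array([np.log1p(r0)])
    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    b = sol.x[0]
    a = sol.x[1] if free_intercept else MIC_BIRTH_HTTKV
    return float(np.expm1(b)), float(a)


def fit_lsf1(traj: Trajectory, k: int, fit_space: str = "log") -> GrowthFit:
    """One-parameter least-squares fit with the intercept pinned at 150 mL/m."""
    _check_fit_space(fit_space)
    ages, vols = _first_k(traj, k, minimum=2)
    y = np.log(vols) - np.log(MIC_BIRTH_HTTKV)
    b = float((ages @ y) / (ages @ ages))
    r = float(np.expm1(b))
    if fit_space == "linear":
        r, _ = _linear_refine(ages, vols, r, MIC_BIRTH_HTTKV, free_intercept=False)
    return GrowthFit(
        rate_r=r,
        httkv0=MIC_BIRTH_HTTKV,
        method="lsf1",
        n_points=k,
        rss_log=_rss_log(ages, vols, r, MIC_BIRTH_HTTKV),
    )


#: Ages coincident to within this many years (~0.03 s) count as one timepoint.
_AGE_DEGENERACY_TOL = 1e-9


def _lsf2_core(ages, vols):
    if np.ptp(ages) < _AGE_DEGENERACY_TOL:
        raise DegenerateDesignError("lsf2 needs at least 2 distinct scan ages")
    # closed-form simple linear regression of ln(v) on t
    y = np.log(vols)
    tbar, ybar = ages.mean(), y.mean()
    dt = ages - tbar
    b = float((dt @ (y - ybar)) / (dt @ dt))
    a = float(ybar - b * tbar)
    return a, b


def fit_lsf2(
    traj: Trajectory, k: int, fit_space: str = "log", method: str = "lsf2"
) -> GrowthFit:
    """Two-parameter least-squares fit; rate and birth volume both free."""
    _check_fit_space(fit_space)
    ages, vols = _first_k(traj, k, minimum=2)
    a, b = _lsf2_core(ages, vols)
    r, httkv0 = float(np.expm1(b)), float(np.exp(a))
    if fit_space == "linear":
        r, httkv0 = _linear_refine(ages, vols, r, httkv0, free_intercept=True)
    return GrowthFit(
        rate_r=r,
        httkv0=httkv0,
        method=method,
        n_points=k,
        rss_log=_rss_log(ages, vols, r, httkv0),
    )


def fit_ground_truth(traj: Trajectory, fit_space: str = "log") -> GrowthFit:
    """Reference rate: the two-parameter fit over every available scan."""
    return fit_lsf2(traj, traj.n_scans, fit_space=fit_space, method="ground_truth")


def blend_mic_lsf2(traj: Trajectory, k: int, fit_space: str = "log") -> GrowthFit:
    """Average of the ``mic_latest`` and ``lsf2`` rates over scans 1..k.

    The blend averages only the rate; its reported intercept is the
    geometric mean of the two component intercepts, which gives the blend a
    well-defined (if heuristic) trajectory for plotting.
    """
    mic = fit_mic_latest(traj, k)
    if k < 2:
        raise InsufficientDataError("blend needs at least 2 scans")
    ls = fit_lsf2(traj, k, fit_space=fit_space)
    ages, vols = _first_k(traj, k)
    r = 0.5 * (mic.rate_r + ls.rate_r)
    httkv0 = float(np.sqrt(mic.httkv0 * ls.httkv0))
    return GrowthFit(
        rate_r=r,
        httkv0=httkv0,
        method="blend_mic_lsf2",
        n_points=k,
        rss_log=_rss_log(ages, vols, r, httkv0),
    )


_ESTIMATORS = {
    "mic_latest": fit_mic_latest,
    "mic_average": fit_mic_average,
    "lsf1": fit_lsf1,
    "lsf2": fit_lsf2,
    "blend_mic_lsf2": blend_mic_lsf2,
}


def fit_method(traj: Trajectory, k: int, method: str, fit_space: str = "log") -> GrowthFit:
    """Dispatch to one of the named estimators."""
    try:
        fn = _ESTIMATORS[method]
    except KeyError:
        raise InvalidInputError(f"unknown method {method!r}; choose from {ESTIMATOR_IDS}")
    if method in ("mic_latest", "mic_average"):
        return fn(traj, k)
    return fn(traj, k, fit_space=fit_space)


def recommend_rate(traj: Trajectory, k: int, fit_space: str = "log") -> GrowthFit:
    """Scan-count-dependent method selection.

    With k <= 2 scans the single-scan MIC on the latest scan is used; with
    exactly 3 the MIC/two-parameter blend; with 4 or more the two-parameter
    fit alone.  If the least-squares design is degenerate (all ages equal)
    the rule falls back to MIC on the latest scan with a logged warning
    rather than failing.
    """
    if k <= 2:
        return fit_mic_latest(traj, k)
    try:
        if k == 3:
            return blend_mic_lsf2(traj, k, fit_space=fit_space)
        return fit_lsf2(traj, k, fit_space=fit_space)
    except DegenerateDesignError:
        logger.warning(
            "patient %s: degenerate design at k=%d, falling back to mic_latest",
            traj.patient_id,
            k,
        )
        fit = fit_mic_latest(traj, k)
        return GrowthFit(
            rate_r=fit.rate_r,
            httkv0=fit.httkv0,
            method=fit.method,
            n_points=fit.n_points,
            rss_log=fit.rss_log,
            warnings=("degenerate_design_fallback",),
        )
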