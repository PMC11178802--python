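"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately avoid the package's closed forms:
least-squares minimisers are located by (refined) grid search, and the
exact tests are checked by exhaustive enumeration in the test modules.
"""

import numpy as np
import pytest

from pkdgrowth import ScanObservation, Trajectory


def make_traj(ages, volumes, patient_id="p1", **kw) -> Trajectory:
    obs = [ScanObservation(age_years=a, httkv=v) for a, v in zip(ages, volumes)]
    return Trajectory(patient_id=patient_id, observations=obs, **kw)


def exact_traj(httkv0, r, ages, **kw) -> Trajectory:
    """Trajectory lying exactly on the growth curve (httkv0, r)."""
    return make_traj(ages, [httkv0 * (1 + r) ** a for a in ages], **kw)


def grid_search_lsf1(ages, vols, lo=-0.1, hi=0.2, step=1e-5):
    """Brute-force minimiser of the pinned-intercept log-space RSS over b."""
    ages = np.asarray(ages, float)
    y = np.log(np.asarray(vols, float)) - np.log(150.0)
    bs = np.arange(np.log1p(lo), np.log1p(hi), step)
    rss = ((y[None, :] - bs[:, None] * ages[None, :]) ** 2).sum(axis=1)
    return float(bs[np.argmin(rss)])


def grid_search_lsf2(ages, vols, rounds=8):
    """Nested-refinement 2-D grid search for the free-intercept log-space fit.

    Starts from a wide (a, b) box and repeatedly zooms a 101x101 grid onto
    the best cell with a generous +-5-cell window (the RSS surface is a
    long correlated valley), ending below 1e-5 spacing in both axes.
    """
    ages = np.asarray(ages, float)
    y = np.log(np.asarray(vols, float))
    a_lo, a_hi = y.min() - 3.0, y.max() + 3.0
    b_lo, b_hi = -0.3, 0.3
    for _ in range(rounds):
        a_grid = np.linspace(a_lo, a_hi, 101)
        b_grid = np.linspace(b_lo, b_hi, 101)
        A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
        rss = ((y[None, None, :] - (A[..., None] + B[..., None] * ages)) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        da, db = a_grid[1] - a_grid[0], b_grid[1] - b_grid[0]
        a_lo, a_hi = a_grid[i] - 5 * da, a_grid[i] + 5 * da
        b_lo, b_hi = b_grid[j] - 5 * db, b_grid[j] + 5 * db
    return float(a_grid[i]), float(b_grid[j])


@pytest.fixture
def two_point_traj():
    """Scans at ages 40 and 45 with htTKV 400 and 500 mL/m."""
    return make_traj([40.0, 45.0], [400.0, 500.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240614)
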