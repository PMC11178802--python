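"""Statistical tests and multiplicity correction used in accuracy comparisons.

Thin, validated wrappers with a uniform :class:`TestResult` return type:

* paired t-test for within-patient error reduction between two methods;
* Mann-Whitney U for group location shifts (exact enumeration for small
  tie-free samples, tie-corrected normal approximation with continuity
  correction otherwise);
* Fisher's exact test for 2x2 contingency tables (two-sided by summing
  hypergeometric probabilities no larger than the observed table's);
* an exact conditional Poisson rate comparison: under equal rates,
  X1 | (X1 + X2) is Binomial(X1 + X2, n1/(n1 + n2)), tested two-sided by
  the minimum-likelihood rule;
* Benjamini-Hochberg step-up adjustment, optionally within families so
  each analysis block is corrected separately.

The numerical cores delegate to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTestError, InvalidInputError

#: Exact Mann-Whitney enumeration is used when n_a * n_b is at most this
#: (and the pooled sample is tie-free); beyond it the normal approximation.
MANN_WHITNEY_EXACT_MAX_PRODUCT = 400


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise InvalidInputError(f"p_value out of [0, 1]: {self.p_value}")


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on the elementwise differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise InvalidInputError("need at least 2 pairs")
    d = x - y
    if np.ptp(d) == 0:
        raise DegenerateTestError("all paired differences identical; t is undefined")
    res = sps.ttest_rel(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="paired_t",
        n=(int(x.size),),
    )


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test of a location shift between two groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    exact = (a.size * b.size <= MANN_WHITNEY_EXACT_MAX_PRODUCT) and not ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        method="mann_whitney_exact" if exact else "mann_whitney_normal",
        n=(int(a.size), int(b.size)),
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table of nonnegative counts.

    The p-value sums the hypergeometric probabilities (margins fixed) of
    every table no more probable than the observed one.  The reported
    statistic is the sample odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InvalidInputError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise InvalidInputError("counts must be nonnegative integers")
    t = t.astype(int)
    if t.sum() < 1:
        raise InvalidInputError("grand total must be >= 1")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        statistic=float(odds),
        p_value=min(float(p), 1.0),
        method="fisher_exact",
        n=(int(t.sum()),),
    )


def poisson_exact_rate_test(x1: int, n1: float, x2: int, n2: float) -> TestResult:
    """Exact conditional test of equal Poisson rates x1/n1 versus x2/n2.

    Conditional on the total, X1 ~ Binomial(x1 + x2, n1/(n1 + n2)) under
    the null; the two-sided p sums binomial outcomes no more likely than
    the observed count (minimum-likelihood rule), capped at 1.
    """
    if x1 < 0 or x2 < 0 or int(x1) != x1 or int(x2) != x2:
        raise InvalidInputError("counts must be nonnegative integers")
    if n1 <= 0 or n2 <= 0:
        raise InvalidInputError("exposures must be > 0")
    if x1 + x2 < 1:
        raise InvalidInputError("x1 + x2 must be >= 1")
    res = sps.binomtest(int(x1), n=int(x1 + x2), p=n1 / (n1 + n2), alternative="two-sided")
    return TestResult(
        statistic=float(x1),
        p_value=min(float(res.pvalue), 1.0),
        method="poisson_exact_conditional",
        n=(int(x1 + x2),),
    )


def benjamini_hochberg(
    p: Sequence[float], family: Optional[Sequence] = None
) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    With ``family`` (one label per p-value) the correction is applied
    within each family separately, so each analysis block — one table,
    one subgroup panel — is its own multiplicity family.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("p must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    if family is None:
        groups = {None: np.arange(p.size)}
    else:
        family = np.asarray(family, dtype=object)
        if family.size != p.size:
            raise InvalidInputError("family must match p in length")
        groups = {f: np.flatnonzero(family == f) for f in dict.fromkeys(family.tolist())}
    for idx in groups.values():
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return [float(v) for v in out]
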