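"""Exception hierarchy for pkdgrowth.

All errors derive from :class:`PkdGrowthError` so callers can catch the
package's failures with one clause; each subclass also derives from the
built-in it most resembles (``ValueError``/``IndexError``) so idiomatic
``except ValueError`` code keeps working.
"""


class PkdGrowthError(Exception):
    """Base class for all pkdgrowth errors."""


class InvalidInputError(PkdGrowthError, ValueError):
    """An argument violates a precondition (nonpositive volume, bad p-value, ...)."""


class InsufficientDataError(PkdGrowthError, ValueError):
    """Too few observations for the requested fit (e.g. k < 2 for a least-squares fit)."""


class DegenerateDesignError(PkdGrowthError, ValueError):
    """The design matrix is rank-deficient (all scan ages identical)."""


class DegenerateTestError(PkdGrowthError, ValueError):
    """A statistical test's sampling distribution collapses (zero-variance differences)."""


class InvalidConfigError(PkdGrowthError, ValueError):
    """A simulation or run configuration is internally inconsistent."""


class CohortParseError(PkdGrowthError, ValueError):
    """A cohort CSV violates the schema; message carries the offending row."""
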