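"""Exponential kidney-growth model and the Mayo Imaging Classification.

Typical ADPKD kidneys grow exponentially: height-adjusted total kidney
volume (htTKV, mL/m) at age ``t`` years follows

    htTKV(t) = htTKV_0 * (1 + r)**t

with ``r`` the annual fractional growth rate.  The Mayo Imaging
Classification (MIC) inverts this model from a single scan under the
assumption that htTKV at birth is 150 mL/m, and bins the implied rate into
classes 1A-1E.  Rates are fractions everywhere in this package (0.036 =
3.6 %/yr); percent appears only at I/O boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import InvalidInputError

#: MIC birth-volume assumption, mL/m.
MIC_BIRTH_HTTKV = 150.0

#: Class-band lower edges as annual fractions: 1B, 1C, 1D, 1E.
MIC_BAND_EDGES = (0.015, 0.03, 0.045, 0.06)


class MayoClass(str, enum.Enum):
    """Mayo Imaging Classification bands for typical (class 1) ADPKD."""

    C1A = "1A"
    C1B = "1B"
    C1C = "1C"
    C1D = "1D"
    C1E = "1E"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ScanObservation:
    """One htTKV measurement at one patient age.

    Parameters
    ----------
    age_years : float
        Decimal years since birth; must be positive.
    httkv : float
        Height-adjusted total kidney volume in mL/m; must be positive.
    """

    age_years: float
    httkv: float

    def __post_init__(self) -> None:
        if not self.age_years > 0:
            raise InvalidInputError(f"age_years must be > 0, got {self.age_years}")
        if not self.httkv > 0:
            raise InvalidInputError(f"httkv must be > 0, got {self.httkv}")


#: Closed vocabulary of genotype groups carried on a trajectory.
GENOTYPES = (
    "PKD1_truncating",
    "PKD1_nontruncating",
    "PKD2_truncating",
    "PKD2_nontruncating",
    "other",
)


@dataclass
class Trajectory:
    """A patient's chronologically ordered scan series plus covariates."""

    patient_id: str
    observations: Sequence[ScanObservation]
    sex: str = "unknown"
    genotype: str = "other"
    hypertension: Optional[bool] = None

    def __post_init__(self) -> None:
        obs = sorted(self.observations, key=lambda o: o.age_years)
        if not obs:
            raise InvalidInputError("a trajectory needs at least one observation")
        ages = [o.age_years for o in obs]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise InvalidInputError(
                f"patient {self.patient_id}: scan ages must be strictly increasing "
                "after same-age aggregation"
            )
        self.observations = tuple(obs)
        if self.sex not in ("male", "female", "unknown"):
            raise InvalidInputError(f"unknown sex {self.sex!r}")
        if self.genotype not in GENOTYPES:
            raise InvalidInputError(f"unknown genotype {self.genotype!r}")

    @property
    def n_scans(self) -> int:
        return len(self.observations)

    @property
    def span_years(self) -> float:
        """Follow-up span, last scan age minus first."""
        return self.observations[-1].age_years - self.observations[0].age_years


@dataclass(frozen=True)
class GrowthFit:
    """An estimated (rate, intercept) pair with its method tag and diagnostics.

    ``rate_r`` is the annual fractional growth rate, ``httkv0`` the model
    intercept at age 0 in mL/m, ``rss_log`` the residual sum of squares in
    log-volume space over the points used.
    """

    rate_r: float
    httkv0: float
    method: str
    n_points: int
    rss_log: float = 0.0
    warnings: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.rate_r > -1:
            raise InvalidInputError(f"rate_r must be > -1, got {self.rate_r}")
        if not self.httkv0 > 0:
            raise InvalidInputError(f"httkv0 must be > 0, got {self.httkv0}")
        if self.n_points < 1:
            raise InvalidInputError("n_points must be >= 1")
        if self.rss_log < 0:
            raise InvalidInputError("rss_log must be >= 0")

    @property
    def mayo_class(self) -> MayoClass:
        return mic_class(self.rate_r)


def predict_httkv(fit: GrowthFit, age: float) -> float:
    """Evaluate the growth curve ``httkv0 * (1 + r)**age`` at ``age`` years."""
    if age < 0:
        raise InvalidInputError(f"age must be >= 0, got {age}")
    return fit.httkv0 * (1.0 + fit.rate_r) ** age


def mic_rate(age: float, httkv: float, httkv0: float = MIC_BIRTH_HTTKV) -> float:
    """Annual fractional growth rate implied by a single scan.

    Inverts the exponential model under the birth-volume assumption:
    ``r = (httkv / httkv0)**(1/age) - 1``.
    """
    if not age > 0:
        raise InvalidInputError(f"age must be > 0, got {age}")
    if not httkv > 0:
        raise InvalidInputError(f"httkv must be > 0, got {httkv}")
    if not httkv0 > 0:
        raise InvalidInputError(f"httkv0 must be > 0, got {httkv0}")
    return (httkv / httkv0) ** (1.0 / age) - 1.0


def mic_class(rate_r: float) -> MayoClass:
    """Map an annual fractional rate to its Mayo class.

    Bands are closed below: 1A for r < 1.5 %/yr, 1B for [1.5, 3), 1C for
    [3, 4.5), 1D for [4.5, 6), 1E for r >= 6 %/yr.  Edges are compared
    exactly — the bands are definitional, not measured.
    """
    if not rate_r > -1:
        raise InvalidInputError(f"rate_r must be > -1, got {rate_r}")
    if rate_r < MIC_BAND_EDGES[0]:
        return MayoClass.C1A
    if rate_r < MIC_BAND_EDGES[1]:
        return MayoClass.C1B
    if rate_r < MIC_BAND_EDGES[2]:
        return MayoClass.C1C
    if rate_r < MIC_BAND_EDGES[3]:
        return MayoClass.C1D
    return MayoClass.C1E
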