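"""Cohort prevalence estimation with Wilson score intervals.

A cohort prevalence here is the proportion of screened subjects carrying the
duplication, pooled over studies by summing raw counts (no heterogeneity
weighting).  Confidence bounds are Wilson score intervals, which invert the
score test

    |p_hat - p| * sqrt(n / (p (1 - p))) = z

and remain well behaved at the extreme counts typical of rare CNVs (zero or
single-digit carriers in cohorts of tens of thousands).  Fractional success
counts are accepted because partially origin-typed carrier sets are
apportioned to maternal/paternal by the observed origin ratio before a
prevalence is computed (:func:`extrapolate_origin_split`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

from scipy import stats

from .cohort_io import CohortClass, Origin, StudyRecord

__all__ = [
    "ProportionEstimate",
    "OriginSplit",
    "OneInN",
    "EmptySelectionError",
    "OriginUnavailableError",
    "wilson_interval",
    "critical_value",
    "pool_prevalence",
    "extrapolate_origin_split",
    "class_origin_ratio",
    "extrapolated_class_prevalence",
    "as_one_in_n",
]


class EmptySelectionError(ValueError):
    """No usable records matched a pooling request."""


class OriginUnavailableError(ValueError):
    """An origin-specific pool was requested but no carriers are origin-typed."""


def critical_value(confidence_level: float) -> float:
    """Normal critical value for a two-sided interval.

    Returns 1.96 exactly at the conventional 95% level (the value used in the
    published tables this package reproduces) and the exact normal quantile
    otherwise.
    """
    if not 0.0 < confidence_level < 1.0:
        raise ValueError("confidence_level must be in (0, 1)")
    if abs(confidence_level - 0.95) < 1e-12:
        return 1.96
    return float(stats.norm.ppf(0.5 + confidence_level / 2.0))


def wilson_interval(
    successes: float,
    trials: int,
    confidence_level: float = 0.95,
    z: float | None = None,
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Parameters
    ----------
    successes:
        Number of successes; fractional values are allowed (they arise from
        origin-ratio extrapolation) and are passed unchanged into the score
        formula.
    trials:
        Number of trials; must be positive.
    confidence_level:
        Two-sided coverage; defaults to 0.95 (z = 1.96).
    z:
        Explicit critical value overriding ``confidence_level``.

    Returns
    -------
    (low, high):
        The Wilson bounds; ``low`` is exactly 0 when ``successes`` is 0 and
        ``high`` exactly 1 when ``successes == trials``.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes must be in [0, trials], got {successes}/{trials}")
    if z is None:
        z = critical_value(confidence_level)
    if z <= 0:
        raise ValueError("z must be positive")

    n = float(trials)
    p = successes / n
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = p + z2 / (2.0 * n)
    half = z * math.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n))
    low = 0.0 if successes == 0 else (centre - half) / denom
    high = 1.0 if successes == trials else (centre + half) / denom
    return max(0.0, low), min(1.0, high)


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its Wilson confidence bounds."""

    numerator: float
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    confidence_level: float = 0.95
    z: float = 1.96

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.point + 1e-15:
            raise ValueError("ci_low must satisfy 0 <= ci_low <= point")
        if not self.point - 1e-15 <= self.ci_high <= 1.0:
            raise ValueError("ci_high must satisfy point <= ci_high <= 1")

    @classmethod
    def from_counts(
        cls,
        numerator: float,
        denominator: int,
        confidence_level: float = 0.95,
    ) -> "ProportionEstimate":
        z = critical_value(confidence_level)
        low, high = wilson_interval(numerator, denominator, z=z)
        return cls(
            numerator=numerator,
            denominator=denominator,
            point=numerator / denominator,
            ci_low=low,
            ci_high=high,
            confidence_level=confidence_level,
            z=z,
        )


@dataclass(frozen=True)
class OriginSplit:
    """A carrier total apportioned to maternal/paternal by an observed ratio."""

    total_carriers_systematic: int
    known_maternal: int
    known_paternal: int
    extrapolated_maternal: float
    extrapolated_paternal: float


class OneInN(NamedTuple):
    """A prevalence re-expressed as '1 in N' denominators.

    Note the bound order inverts: ``low`` (the smaller N) comes from the
    upper prevalence bound and ``high`` from the lower bound.
    """

    point: float
    low: float
    high: float


def _class_records(
    records: Iterable[StudyRecord], cohort_class: CohortClass
) -> list[StudyRecord]:
    return [r for r in records if r.cohort_class is cohort_class]


def pool_prevalence(
    records: Iterable[StudyRecord],
    cohort_class: CohortClass,
    origin: Origin = Origin.ANY,
    confidence_level: float = 0.95,
) -> ProportionEstimate:
    """Pool carrier counts over usable studies of one class.

    The numerator sums carriers of the requested origin and the denominator
    sums ``n_total`` over records flagged ``usable_for_prevalence``.  Carriers
    of unknown origin count only toward ``Origin.ANY``; use
    :func:`extrapolated_class_prevalence` for partially origin-typed classes.
    """
    usable = [
        r for r in _class_records(records, cohort_class) if r.usable_for_prevalence
    ]
    if not usable:
        raise EmptySelectionError(
            f"no records usable for prevalence in class {cohort_class.value}"
        )
    denominator = sum(r.n_total for r in usable)  # type: ignore[misc]
    if origin is not Origin.ANY:
        typed = sum(r.carriers_maternal + r.carriers_paternal for r in usable)
        untyped = sum(r.carriers_unknown for r in usable)
        if typed == 0 and untyped > 0:
            raise OriginUnavailableError(
                f"all {cohort_class.value} carriers are origin-untyped; "
                "origin-specific prevalence is unavailable"
            )
    numerator = sum(r.carriers(origin) for r in usable)
    return ProportionEstimate.from_counts(numerator, denominator, confidence_level)


def extrapolate_origin_split(
    total_carriers: int, known_maternal: int, known_paternal: int
) -> OriginSplit:
    """Apportion a carrier total by the observed maternal:paternal ratio.

    Used when a systematically ascertained carrier set is only partially
    origin-typed: the full total is split in proportion to the typed counts
    (possibly drawn from a larger superset of cohorts), yielding fractional
    extrapolated counts whose sum equals the total exactly.
    """
    known = known_maternal + known_paternal
    if known <= 0:
        raise ZeroDivisionError(
            "origin-ratio extrapolation requires at least one origin-typed carrier "
            "(known_maternal + known_paternal > 0)"
        )
    if min(total_carriers, known_maternal, known_paternal) < 0:
        raise ValueError("counts must be nonnegative")
    maternal = total_carriers * known_maternal / known
    return OriginSplit(
        total_carriers_systematic=total_carriers,
        known_maternal=known_maternal,
        known_paternal=known_paternal,
        extrapolated_maternal=maternal,
        extrapolated_paternal=total_carriers - maternal,
    )


def class_origin_ratio(
    records: Iterable[StudyRecord], cohort_class: CohortClass
) -> tuple[int, int]:
    """Origin-typed (maternal, paternal) carrier totals over *all* records of a
    class, including studies without a reported cohort size."""
    recs = _class_records(records, cohort_class)
    return (
        sum(r.carriers_maternal for r in recs),
        sum(r.carriers_paternal for r in recs),
    )


def extrapolated_class_prevalence(
    records: Iterable[StudyRecord],
    cohort_class: CohortClass,
    origin: Origin,
    confidence_level: float = 0.95,
) -> ProportionEstimate:
    """Origin-specific prevalence with origin-ratio extrapolation.

    The carrier total and denominator come from usable (systematically
    ascertained) studies; the maternal:paternal ratio comes from every
    origin-typed carrier in the class, including ratio-only studies.  When
    all usable carriers are origin-typed this reduces exactly to the raw
    origin-specific pool.
    """
    records = list(records)
    if origin is Origin.ANY:
        return pool_prevalence(records, cohort_class, Origin.ANY, confidence_level)
    total = pool_prevalence(records, cohort_class, Origin.ANY, confidence_level)
    km, kp = class_origin_ratio(records, cohort_class)
    split = extrapolate_origin_split(int(total.numerator), km, kp)
    numerator = (
        split.extrapolated_maternal
        if origin is Origin.MATERNAL
        else split.extrapolated_paternal
    )
    return ProportionEstimate.from_counts(
        numerator, total.denominator, confidence_level
    )


def as_one_in_n(estimate: ProportionEstimate) -> OneInN:
    """Re-express a prevalence as '1 in N' (point, low-N, high-N).

    ``low = 1/ci_high`` and ``high = 1/ci_low``; values are returned
    unrounded (round for display).  A zero point estimate has no reciprocal.
    """
    if estimate.point <= 0:
        raise ZeroDivisionError("'1 in N' is undefined for a zero prevalence")
    high = math.inf if estimate.ci_low == 0 else 1.0 / estimate.ci_low
    return OneInN(1.0 / estimate.point, 1.0 / estimate.ci_high, high)
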