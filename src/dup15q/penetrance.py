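"""Penetrance estimation via a population mixture and Bayes inversion.

The general population is modelled as a three-way mixture of mutually
exclusive strata — healthy controls, schizophrenia (SZ) and the combined
developmental-delay/autism/congenital-anomaly group (DD/ASD/MCA) — with
default weights 0.95 / 0.01 / 0.04.  The general-population carrier
frequency of a duplication of a given parental origin is then the weighted
average of the stratum prevalences

    q = w_c * p_control + w_sz * p_SZ + w_dd * p_DD

and the penetrance for an outcome follows from Bayes' theorem,

    P(outcome | carrier) = p_outcome_cohort * w_outcome / q,

truncated at 1 (a ``capped`` flag records when truncation fired).  Outcomes
are treated as single-ascertainment classes: a carrier with both diagnoses is
assumed counted once, so the two penetrances need not sum below 1 by
construction and the cap is a genuine boundary.

Confidence limits are propagated through the same algebra by combining the
extreme Wilson bounds: the upper penetrance bound divides the upper cohort
bound by the lower population bound, and vice versa.  This is deliberately
conservative rather than a calibrated interval.

Two rounding policies are provided.  ``FULL_PRECISION`` (default) carries
pooled prevalences through unrounded.  ``PRINTED_PRECISION`` first rounds
every stratum prevalence (point and bounds) to two significant figures —
the precision at which such tables are conventionally printed — before the
mixture and ratio steps, which is the arithmetic needed to reproduce a
published table cell-for-cell from its own printed inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._rounding import round_sig
from .cohort_io import CohortClass, Origin, StudyRecord
from .prevalence import (
    ProportionEstimate,
    extrapolated_class_prevalence,
)

__all__ = [
    "MixtureWeights",
    "RoundingMode",
    "RoundingPolicy",
    "PopulationFrequency",
    "PenetranceEstimate",
    "PenetranceTable",
    "CompositionError",
    "DEFAULT_WEIGHTS",
    "SENSITIVITY_WEIGHTS",
    "FULL_PRECISION",
    "PRINTED_PRECISION",
    "population_frequency",
    "penetrance_point",
    "penetrance_bounds",
    "penetrance_table",
    "sensitivity_analysis",
]

OUTCOME_CLASSES = (CohortClass.SZ, CohortClass.DD_ASD_MCA)


class CompositionError(ValueError):
    """The record set lacks a cohort class the pipeline needs."""


@dataclass(frozen=True)
class MixtureWeights:
    """Population composition: control / SZ / DD-ASD-MCA stratum weights."""

    w_control: float = 0.95
    w_sz: float = 0.01
    w_dd: float = 0.04

    def __post_init__(self) -> None:
        for name in ("w_control", "w_sz", "w_dd"):
            w = getattr(self, name)
            if not 0.0 < w < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {w}")
        if abs(self.w_control + self.w_sz + self.w_dd - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")

    def weight(self, outcome: CohortClass) -> float:
        if outcome is CohortClass.SZ:
            return self.w_sz
        if outcome is CohortClass.DD_ASD_MCA:
            return self.w_dd
        return self.w_control


#: Default composition: 95% healthy, 1% SZ, 4% DD/ASD/MCA.
DEFAULT_WEIGHTS = MixtureWeights()
#: Sensitivity preset halving the affected strata (97.5% / 0.5% / 2%),
#: probing whether ascertained cohorts over-represent severe cases.
SENSITIVITY_WEIGHTS = MixtureWeights(0.975, 0.005, 0.02)


class RoundingMode(enum.Enum):
    FULL_PRECISION = "full"
    PRINTED_PRECISION = "printed"


@dataclass(frozen=True)
class RoundingPolicy:
    """Whether stratum prevalences are rounded before mixture/ratio steps."""

    mode: RoundingMode = RoundingMode.FULL_PRECISION
    sig_figs: int = 2

    def prep(self, value: float) -> float:
        if self.mode is RoundingMode.PRINTED_PRECISION:
            return round_sig(value, self.sig_figs)
        return value


FULL_PRECISION = RoundingPolicy(RoundingMode.FULL_PRECISION)
PRINTED_PRECISION = RoundingPolicy(RoundingMode.PRINTED_PRECISION)


@dataclass(frozen=True)
class PopulationFrequency:
    """General-population carrier frequency for one parental origin."""

    origin: Origin
    q_point: float
    q_low: float
    q_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_low <= self.q_point <= self.q_high:
            raise ValueError("population frequency bounds must bracket the point")


@dataclass(frozen=True)
class PenetranceEstimate:
    """P(outcome | carrier, parental origin) with propagated bounds."""

    origin: Origin
    outcome: CohortClass
    point: float
    ci_low: float
    ci_high: float
    capped: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.point + 1e-12:
            raise ValueError("ci_low must satisfy 0 <= ci_low <= point")
        if not self.point - 1e-12 <= self.ci_high <= 1.0:
            raise ValueError("ci_high must satisfy point <= ci_high <= 1")


def population_frequency(
    prev_control: ProportionEstimate,
    prev_sz: ProportionEstimate,
    prev_dd: ProportionEstimate,
    weights: MixtureWeights = DEFAULT_WEIGHTS,
    policy: RoundingPolicy = FULL_PRECISION,
    origin: Origin = Origin.ANY,
) -> PopulationFrequency:
    """Mix stratum prevalences into a general-population carrier frequency.

    Point and bounds are the same weighted sum applied to the stratum points,
    lower bounds and upper bounds respectively (after the policy's optional
    rounding of each input).
    """

    def mix(values: Sequence[float]) -> float:
        c, s, d = (policy.prep(v) for v in values)
        return weights.w_control * c + weights.w_sz * s + weights.w_dd * d

    return PopulationFrequency(
        origin=origin,
        q_point=mix((prev_control.point, prev_sz.point, prev_dd.point)),
        q_low=mix((prev_control.ci_low, prev_sz.ci_low, prev_dd.ci_low)),
        q_high=mix((prev_control.ci_high, prev_sz.ci_high, prev_dd.ci_high)),
    )


def penetrance_point(
    prev_case: float, outcome_weight: float, q: float
) -> tuple[float, bool]:
    """Bayes-inverted penetrance ``prev_case * w / q``, truncated at 1.

    Returns ``(penetrance, capped)``.
    """
    if q <= 0:
        raise ZeroDivisionError("population frequency q must be positive")
    raw = prev_case * outcome_weight / q
    return (1.0, True) if raw > 1.0 else (raw, False)


def penetrance_bounds(
    prev_case: ProportionEstimate,
    outcome_weight: float,
    q: PopulationFrequency,
    policy: RoundingPolicy = FULL_PRECISION,
    outcome: CohortClass = CohortClass.SZ,
) -> PenetranceEstimate:
    """Penetrance with bound-propagated confidence limits.

    The upper limit pairs the cohort's upper bound with the population's
    lower bound; the lower limit pairs the opposites.  The raw upper limit is
    truncated at 1 with the ``capped`` flag set.
    """
    if q.q_low <= 0:
        raise ZeroDivisionError("q_low must be positive for bound propagation")
    point, capped_pt = penetrance_point(
        policy.prep(prev_case.point), outcome_weight, q.q_point
    )
    high, capped_hi = penetrance_point(
        policy.prep(prev_case.ci_high), outcome_weight, q.q_low
    )
    low, _ = penetrance_point(policy.prep(prev_case.ci_low), outcome_weight, q.q_high)
    return PenetranceEstimate(
        origin=q.origin,
        outcome=outcome,
        point=point,
        ci_low=min(low, point),
        ci_high=max(high, point),
        capped=capped_pt or capped_hi,
    )


@dataclass(frozen=True)
class PenetranceTable:
    """Population frequencies and penetrances for both parental origins."""

    frequencies: Mapping[Origin, PopulationFrequency]
    estimates: Mapping[tuple[Origin, CohortClass], PenetranceEstimate]
    weights: MixtureWeights
    policy: RoundingPolicy
    prevalences: Mapping[tuple[Origin, CohortClass], ProportionEstimate]


def penetrance_table(
    records: Iterable[StudyRecord],
    weights: MixtureWeights = DEFAULT_WEIGHTS,
    policy: RoundingPolicy = FULL_PRECISION,
    confidence_level: float = 0.95,
) -> PenetranceTable:
    """Full pipeline: pool, extrapolate origin splits, mix, invert.

    For each parental origin, stratum prevalences are pooled with
    origin-ratio extrapolation where carriers are only partially typed, mixed
    into a population frequency, and inverted into penetrances for the two
    outcome classes.
    """
    records = list(records)
    present = {r.cohort_class for r in records}
    for needed in CohortClass:
        if needed not in present:
            raise CompositionError(f"records lack cohort class {needed.value}")

    frequencies: dict[Origin, PopulationFrequency] = {}
    estimates: dict[tuple[Origin, CohortClass], PenetranceEstimate] = {}
    prevalences: dict[tuple[Origin, CohortClass], ProportionEstimate] = {}
    for origin in (Origin.MATERNAL, Origin.PATERNAL):
        prev = {
            cls: extrapolated_class_prevalence(records, cls, origin, confidence_level)
            for cls in CohortClass
        }
        q = population_frequency(
            prev[CohortClass.CONTROL],
            prev[CohortClass.SZ],
            prev[CohortClass.DD_ASD_MCA],
            weights,
            policy,
            origin,
        )
        frequencies[origin] = q
        for outcome in OUTCOME_CLASSES:
            estimates[(origin, outcome)] = penetrance_bounds(
                prev[outcome], weights.weight(outcome), q, policy, outcome
            )
            prevalences[(origin, outcome)] = prev[outcome]
        prevalences[(origin, CohortClass.CONTROL)] = prev[CohortClass.CONTROL]
    return PenetranceTable(
        frequencies=frequencies,
        estimates=estimates,
        weights=weights,
        policy=policy,
        prevalences=prevalences,
    )


def sensitivity_analysis(
    records: Iterable[StudyRecord],
    presets: Sequence[MixtureWeights],
    policy: RoundingPolicy = FULL_PRECISION,
    confidence_level: float = 0.95,
) -> list[tuple[MixtureWeights, PenetranceTable]]:
    """Recompute the penetrance table under each mixture-weight preset."""
    records = list(records)
    return [
        (w, penetrance_table(records, w, policy, confidence_level)) for w in presets
    ]
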