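"""Selection coefficients and mutation rates under mutation-selection balance.

For a strongly deleterious variant held at equilibrium, the carriers removed
by selection each generation are replaced by new mutations, so the population
frequency obeys q = mu / s.  Two consequences are used here:

* In an unbiased sample of carriers, the proportion that are de novo
  approximates the selection coefficient, s ~= de_novo / (de_novo + inherited),
  because the de novo influx equals the selective outflow s * q * N.
* Given an estimated population frequency q and selection coefficient s, the
  mutation rate follows as mu = q * s.

Frequencies are population rates (carriers per person) and mutation rates are
per newborn, not per gamete: the observed rate in newborns already reflects
any selection acting before birth, which for some CNVs is known to be strong.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .cohort_io import InheritanceTally, Origin
from .penetrance import PopulationFrequency
from .prevalence import wilson_interval

__all__ = [
    "SelectionEstimate",
    "UndefinedEstimateError",
    "selection_coefficient",
    "pool_tallies",
    "mutation_rate",
]


class UndefinedEstimateError(ValueError):
    """The estimator is undefined for the given counts (e.g. zero carriers)."""


@dataclass(frozen=True)
class SelectionEstimate:
    """Selection coefficient and (optionally) the implied mutation rate.

    ``s`` is the de novo fraction among carriers; ``mu`` (per newborn) and
    ``one_in_n_newborns`` are filled in by :func:`mutation_rate`.  ``ci`` is
    an optional Wilson interval on the de novo fraction — an extension beyond
    the published point estimates, off by default.
    """

    origin: Origin
    s: float
    de_novo: int
    inherited: int
    mu: float | None = None
    one_in_n_newborns: float | None = None
    ci: tuple[float, float] | None = None


def selection_coefficient(
    tally: InheritanceTally, with_ci: bool = False, confidence_level: float = 0.95
) -> SelectionEstimate:
    """Approximate s as the de novo fraction de_novo / (de_novo + inherited).

    Raises :class:`UndefinedEstimateError` when the tally is empty (no
    carriers with both parents tested).
    """
    total = tally.total
    if total == 0:
        raise UndefinedEstimateError(
            f"{tally.study_id} ({tally.origin.value}): selection coefficient is "
            "undefined with zero carriers"
        )
    ci = (
        wilson_interval(tally.de_novo, total, confidence_level) if with_ci else None
    )
    return SelectionEstimate(
        origin=tally.origin,
        s=tally.de_novo / total,
        de_novo=tally.de_novo,
        inherited=tally.inherited,
        ci=ci,
    )


def pool_tallies(
    tallies: Iterable[InheritanceTally], origin: Origin
) -> InheritanceTally:
    """Elementwise sum of the tallies of one parental origin."""
    selected = [t for t in tallies if t.origin is origin]
    if not selected:
        raise ValueError(f"no tallies with origin {origin.value}")
    return InheritanceTally(
        study_id="pooled",
        origin=origin,
        de_novo=sum(t.de_novo for t in selected),
        inherited=sum(t.inherited for t in selected),
    )


def mutation_rate(
    q: PopulationFrequency, s_estimate: SelectionEstimate
) -> SelectionEstimate:
    """Derive the per-newborn mutation rate mu = q * s at balance.

    Returns a copy of ``s_estimate`` with ``mu`` and ``one_in_n_newborns``
    (its reciprocal) filled in.
    """
    if s_estimate.s <= 0:
        raise UndefinedEstimateError(
            "mutation-selection balance gives no mutation rate when s = 0"
        )
    if q.q_point <= 0:
        raise UndefinedEstimateError("population frequency q must be positive")
    mu = q.q_point * s_estimate.s
    return replace(s_estimate, mu=mu, one_in_n_newborns=1.0 / mu)
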