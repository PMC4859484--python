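"""Rendering of prevalence / penetrance / selection reports.

Rendered tables mirror the layout of the published summary tables:
percentages at two significant figures with 95% bounds in brackets,
penetrances at one decimal, and a provenance block recording exactly which
inputs, weights and rounding policy produced the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import __version__
from ._rounding import fmt_pct
from .cohort_io import CohortClass, InheritanceTally, Origin, StudyRecord
from .penetrance import (
    MixtureWeights,
    PenetranceTable,
    RoundingPolicy,
    penetrance_table,
)
from .prevalence import as_one_in_n
from .selection_mutation import (
    UndefinedEstimateError,
    mutation_rate,
    pool_tallies,
    selection_coefficient,
)

__all__ = ["ReportBundle", "build_report", "render_text", "render_tsv"]

_ORIGINS = (Origin.MATERNAL, Origin.PATERNAL)


@dataclass(frozen=True)
class ReportBundle:
    """All rendered estimates plus the provenance that produced them."""

    prevalence: pd.DataFrame
    penetrance: pd.DataFrame
    selection: pd.DataFrame | None
    provenance: dict[str, str]


def _pct_cell(point: float, low: float, high: float) -> str:
    return f"{fmt_pct(point)} ({fmt_pct(low)}–{fmt_pct(high)})"


def _pen_val(fraction: float) -> str:
    pct = 100.0 * fraction
    if pct < 0.095:  # sub-0.1% penetrances print at one significant figure
        return f"{pct:.1g}"
    if pct >= 99.95:
        return "100"
    return f"{pct:.1f}"


def _pen_cell(point: float, low: float, high: float) -> str:
    return f"{_pen_val(point)} ({_pen_val(low)}–{_pen_val(high)})"


def build_report(
    records: list[StudyRecord],
    tallies: list[InheritanceTally] | None,
    weights: MixtureWeights,
    policy: RoundingPolicy,
    confidence_level: float = 0.95,
    inputs: str = "",
) -> ReportBundle:
    """Run the full estimation pipeline and assemble renderable tables."""
    table: PenetranceTable = penetrance_table(records, weights, policy, confidence_level)

    prev_rows = []
    for origin in _ORIGINS:
        row: dict[str, str] = {"origin": origin.value.lower()}
        for cls in (CohortClass.CONTROL, CohortClass.SZ, CohortClass.DD_ASD_MCA):
            p = table.prevalences[(origin, cls)]
            row[cls.value] = _pct_cell(p.point, p.ci_low, p.ci_high)
        q = table.frequencies[origin]
        row["general_population"] = _pct_cell(q.q_point, q.q_low, q.q_high)
        prev_rows.append(row)
    prevalence = pd.DataFrame(prev_rows).set_index("origin")

    pen_rows = []
    for origin in _ORIGINS:
        row = {"origin": origin.value.lower()}
        for outcome in (CohortClass.SZ, CohortClass.DD_ASD_MCA):
            e = table.estimates[(origin, outcome)]
            row[f"penetrance_{outcome.value}"] = _pen_cell(e.point, e.ci_low, e.ci_high)
        pen_rows.append(row)
    penetrance = pd.DataFrame(pen_rows).set_index("origin")

    selection = None
    if tallies:
        sel_rows = []
        for origin in _ORIGINS:
            tally = pool_tallies(tallies, origin)
            try:
                s_est = selection_coefficient(tally)
            except UndefinedEstimateError:
                sel_rows.append(
                    {
                        "origin": origin.value.lower(),
                        "de_novo": tally.de_novo,
                        "inherited": tally.inherited,
                        "s": "n/a",
                        "mu_per_newborn": "n/a",
                        "one_in_n_newborns": "n/a",
                    }
                )
                continue
            q = table.frequencies[origin]
            row = {
                "origin": origin.value.lower(),
                "de_novo": tally.de_novo,
                "inherited": tally.inherited,
                "s": f"{s_est.s:.2g}",
            }
            if s_est.s > 0 and q.q_point > 0:
                m = mutation_rate(q, s_est)
                row["mu_per_newborn"] = f"{m.mu:.3g}"
                row["one_in_n_newborns"] = f"{m.one_in_n_newborns:.0f}"
            else:
                row["mu_per_newborn"] = "n/a"
                row["one_in_n_newborns"] = "n/a"
            sel_rows.append(row)
        selection = pd.DataFrame(sel_rows).set_index("origin")

    provenance = {
        "package": f"dup15q {__version__}",
        "inputs": inputs,
        "weights": (
            f"control={weights.w_control} sz={weights.w_sz} dd={weights.w_dd}"
        ),
        "rounding": policy.mode.value,
        "confidence_level": str(confidence_level),
    }
    return ReportBundle(
        prevalence=prevalence,
        penetrance=penetrance,
        selection=selection,
        provenance=provenance,
    )


def render_text(bundle: ReportBundle) -> str:
    """Human-readable aligned-text report."""
    parts = ["# dup15q estimate report"]
    parts += [f"# {k}: {v}" for k, v in bundle.provenance.items()]
    parts.append("")
    parts.append("Cohort prevalence and general-population frequency, % (95% CI)")
    parts.append(bundle.prevalence.to_string())
    parts.append("")
    parts.append("Penetrance, % (95% CI)")
    parts.append(bundle.penetrance.to_string())
    if bundle.selection is not None:
        parts.append("")
        parts.append("Selection and mutation rate (de novo fraction; mu = q*s)")
        parts.append(bundle.selection.to_string())
    parts.append("")
    return "\n".join(parts)


def render_tsv(bundle: ReportBundle) -> str:
    """Machine-readable tab-delimited report (blocks separated by headers)."""
    parts = [f"# {k}: {v}" for k, v in bundle.provenance.items()]
    for name, frame in (
        ("prevalence", bundle.prevalence),
        ("penetrance", bundle.penetrance),
        ("selection", bundle.selection),
    ):
        if frame is None:
            continue
        parts.append(f"# block: {name}")
        parts.append(frame.to_csv(sep="\t").rstrip("\n"))
    return "\n".join(parts) + "\n"
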