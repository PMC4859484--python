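"""Data model and I/O for study-count tables.

The unit of input for every estimator in this package is a table of carrier
counts: one row per (study, cohort class) giving how many screened subjects
carried the duplication, split by parental origin where that was typed.  Two
tab-delimited schemas are supported:

``counts``
    ``study_id, cohort_class, carriers_maternal, carriers_paternal,
    carriers_unknown, n_total, usable_for_prevalence, notes`` — one
    :class:`StudyRecord` per row.  ``n_total`` may be the literal ``NA`` for
    studies that reported carriers without a cohort size; such rows can only
    inform the maternal:paternal origin ratio, never a prevalence, and must
    carry ``usable_for_prevalence = false``.

``inheritance``
    ``study_id, origin, de_novo, inherited`` — one :class:`InheritanceTally`
    per row, counting de novo versus inherited duplications among carriers
    whose parents were both tested.

Files are UTF-8, tab-delimited, with ``#``-prefixed comment lines.  The
package ships the published count tables for the 15q11.2-q13.3 interstitial
duplication (schizophrenia, DD/ASD/MCA and control cohorts) as fixtures,
loadable via :func:`load_table1_counts` and :func:`load_table3_inheritance`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "CohortClass",
    "Origin",
    "StudyRecord",
    "InheritanceTally",
    "SchemaError",
    "ValidationError",
    "read_study_table",
    "write_study_table",
    "load_table1_counts",
    "load_table3_inheritance",
    "COUNTS_COLUMNS",
    "INHERITANCE_COLUMNS",
]


class CohortClass(str, enum.Enum):
    """Ascertainment class of a cohort."""

    SZ = "SZ"
    DD_ASD_MCA = "DD_ASD_MCA"
    CONTROL = "CONTROL"


class Origin(str, enum.Enum):
    """Parental origin of the duplicated segment.

    ``ANY`` is accepted by pooling operations to mean "ignore origin"; it is
    not a valid origin for a single duplication.
    """

    MATERNAL = "MATERNAL"
    PATERNAL = "PATERNAL"
    ANY = "ANY"


class SchemaError(ValueError):
    """A file's header does not match the requested schema."""


class ValidationError(ValueError):
    """A record violates a type invariant; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


def _check_count(value: int, name: str) -> None:
    if not isinstance(value, int) or isinstance(value, bool) or value < 0:
        raise ValidationError(f"{name} must be a nonnegative integer, got {value!r}")


@dataclass(frozen=True)
class StudyRecord:
    """Carrier counts for one study and cohort class.

    ``carriers_unknown`` counts carriers whose parental origin could not be
    typed; ``n_total`` is the number of subjects screened (``None`` when the
    study did not report it, in which case the row is excluded from
    prevalence pooling and only informs the origin ratio).
    """

    study_id: str
    cohort_class: CohortClass
    carriers_maternal: int
    carriers_paternal: int
    carriers_unknown: int
    n_total: int | None
    usable_for_prevalence: bool
    notes: str = ""

    def __post_init__(self) -> None:
        for name in ("carriers_maternal", "carriers_paternal", "carriers_unknown"):
            _check_count(getattr(self, name), name)
        if self.n_total is None:
            if self.usable_for_prevalence:
                raise ValidationError(
                    f"{self.study_id}: usable_for_prevalence requires n_total"
                )
        else:
            if not isinstance(self.n_total, int) or self.n_total <= 0:
                raise ValidationError(
                    f"{self.study_id}: n_total must be a positive integer, "
                    f"got {self.n_total!r}"
                )
            if self.total_carriers > self.n_total:
                raise ValidationError(
                    f"{self.study_id}: carrier sum {self.total_carriers} exceeds "
                    f"n_total {self.n_total}"
                )

    @property
    def total_carriers(self) -> int:
        return self.carriers_maternal + self.carriers_paternal + self.carriers_unknown

    def carriers(self, origin: Origin) -> int:
        """Carrier count for one parental origin (``ANY`` = all carriers)."""
        if origin is Origin.MATERNAL:
            return self.carriers_maternal
        if origin is Origin.PATERNAL:
            return self.carriers_paternal
        return self.total_carriers


@dataclass(frozen=True)
class InheritanceTally:
    """De novo versus inherited carrier counts for one study and origin."""

    study_id: str
    origin: Origin
    de_novo: int
    inherited: int

    def __post_init__(self) -> None:
        if self.origin is Origin.ANY:
            raise ValidationError(
                f"{self.study_id}: inheritance tallies need a definite origin"
            )
        _check_count(self.de_novo, "de_novo")
        _check_count(self.inherited, "inherited")

    @property
    def total(self) -> int:
        return self.de_novo + self.inherited


COUNTS_COLUMNS = [
    "study_id",
    "cohort_class",
    "carriers_maternal",
    "carriers_paternal",
    "carriers_unknown",
    "n_total",
    "usable_for_prevalence",
    "notes",
]
INHERITANCE_COLUMNS = ["study_id", "origin", "de_novo", "inherited"]

_MISSING = "NA"
_SCHEMAS = {"counts": COUNTS_COLUMNS, "inheritance": INHERITANCE_COLUMNS}


def _parse_int(value: str, name: str, row: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} must be an integer, got {value!r}", row=row)


def _parse_bool(value: str, name: str, row: int) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ValidationError(f"{name} must be true/false, got {value!r}", row=row)


def _cell(raw: object) -> str:
    # pandas yields NaN for short rows even with keep_default_na=False
    return "" if raw is None or (isinstance(raw, float)) else str(raw)


def read_study_table(
    path: Union[str, Path], schema: str = "counts"
) -> list[StudyRecord] | list[InheritanceTally]:
    """Read a tab-delimited study table, validating every row.

    Parameters
    ----------
    path:
        File to read.  UTF-8, tab-delimited, ``#`` comments, ``NA`` for a
        missing ``n_total``.
    schema:
        ``"counts"`` (returns :class:`StudyRecord`) or ``"inheritance"``
        (returns :class:`InheritanceTally`).

    Raises
    ------
    SchemaError
        If the header is missing a required column.
    ValidationError
        On the first row violating a type invariant, with its row number
        (1-based over data rows).
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    expected = _SCHEMAS[schema]
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=True,
    )
    missing = [c for c in expected if c not in frame.columns and c != "notes"]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {', '.join(missing)} for schema {schema!r}"
        )

    out: list = []
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        if schema == "counts":
            n_raw = str(rec["n_total"]).strip()
            n_total = None if n_raw in (_MISSING, "") else _parse_int(n_raw, "n_total", i)
            try:
                cohort_class = CohortClass(str(rec["cohort_class"]).strip())
            except ValueError:
                raise ValidationError(
                    f"unknown cohort_class {rec['cohort_class']!r}", row=i
                )
            try:
                out.append(
                    StudyRecord(
                        study_id=str(rec["study_id"]).strip(),
                        cohort_class=cohort_class,
                        carriers_maternal=_parse_int(
                            rec["carriers_maternal"], "carriers_maternal", i
                        ),
                        carriers_paternal=_parse_int(
                            rec["carriers_paternal"], "carriers_paternal", i
                        ),
                        carriers_unknown=_parse_int(
                            rec["carriers_unknown"], "carriers_unknown", i
                        ),
                        n_total=n_total,
                        usable_for_prevalence=_parse_bool(
                            rec["usable_for_prevalence"], "usable_for_prevalence", i
                        ),
                        notes=_cell(rec.get("notes", "")),
                    )
                )
            except ValidationError as err:
                if err.row is None:
                    raise ValidationError(str(err), row=i) from None
                raise
        else:
            try:
                origin = Origin(str(rec["origin"]).strip())
            except ValueError:
                raise ValidationError(f"unknown origin {rec['origin']!r}", row=i)
            try:
                out.append(
                    InheritanceTally(
                        study_id=str(rec["study_id"]).strip(),
                        origin=origin,
                        de_novo=_parse_int(rec["de_novo"], "de_novo", i),
                        inherited=_parse_int(rec["inherited"], "inherited", i),
                    )
                )
            except ValidationError as err:
                if err.row is None:
                    raise ValidationError(str(err), row=i) from None
                raise
    return out


def write_study_table(
    records: Sequence[Union[StudyRecord, InheritanceTally]],
    path: Union[str, Path],
) -> None:
    """Write records to a tab-delimited table (inverse of :func:`read_study_table`).

    The schema is inferred from the record type; ``read(write(x)) == x``
    field-for-field.  An absent ``n_total`` is serialized as ``NA``.
    """
    records = list(records)
    if records and isinstance(records[0], InheritanceTally):
        rows = [
            {
                "study_id": t.study_id,
                "origin": t.origin.value,
                "de_novo": t.de_novo,
                "inherited": t.inherited,
            }
            for t in records
        ]
        columns = INHERITANCE_COLUMNS
    else:
        for r in records:
            for text_field in (r.study_id, r.notes):
                if "\t" in text_field or "\n" in text_field:
                    raise ValidationError(
                        f"{r.study_id!r}: text fields may not contain tabs or newlines"
                    )
        rows = [
            {
                "study_id": r.study_id,
                "cohort_class": r.cohort_class.value,
                "carriers_maternal": r.carriers_maternal,
                "carriers_paternal": r.carriers_paternal,
                "carriers_unknown": r.carriers_unknown,
                "n_total": _MISSING if r.n_total is None else r.n_total,
                "usable_for_prevalence": "true" if r.usable_for_prevalence else "false",
                "notes": r.notes,
            }
            for r in records
        ]
        columns = COUNTS_COLUMNS
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def _fixture(name: str):
    return resources.files("dup15q.data").joinpath(name)


def load_table1_counts() -> list[StudyRecord]:
    """Published per-study carrier counts (SZ, DD/ASD/MCA and control cohorts)."""
    with resources.as_file(_fixture("table1_counts.tsv")) as p:
        return read_study_table(p, schema="counts")


def load_table3_inheritance() -> list[InheritanceTally]:
    """Published de novo / inherited tallies by parental origin."""
    with resources.as_file(_fixture("table3_inheritance.tsv")) as p:
        return read_study_table(p, schema="inheritance")
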