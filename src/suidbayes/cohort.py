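"""Case-level cohort container with CSV round-trip and summary tables.

A cohort is a list of validated :class:`CaseRecord` plus the coding scheme
they were validated against.  The CSV schema is one row per death: a
``case_id`` column, an optional ``diagnosis`` column, then one column per
factor in coding order.  ``unknown`` encodes informational missingness and
``NA`` structural missingness (see :mod:`suidbayes.coding`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .coding import (
    DEFAULT_CODING,
    DIAGNOSES,
    DIAGNOSIS_COLLAPSE,
    NOT_APPLICABLE,
    UNKNOWN,
    FactorDefinition,
)


class CohortError(ValueError):
    """Schema or vocabulary violation in cohort data."""


@dataclass
class CaseRecord:
    case_id: str
    factors: dict[str, str]
    diagnosis: Optional[str] = None

    def value(self, name: str) -> str:
        if name == "diagnosis":
            if self.diagnosis is None:
                raise CohortError(f"case {self.case_id!r}: diagnosis absent")
            return self.diagnosis
        return self.factors[name]


from .coding import DIAGNOSES_BINARY

#: Labels accepted for the standard three-state scheme plus its binary collapse.
STANDARD_DIAGNOSES = DIAGNOSES + ("non_SIDS",)


@dataclass
class Cohort:
    records: list[CaseRecord]
    coding: tuple[FactorDefinition, ...] = DEFAULT_CODING
    diagnosis_levels: tuple[str, ...] = STANDARD_DIAGNOSES

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate case ids: {dupes}")
        for i, rec in enumerate(self.records):
            validate_record(rec, self.coding, row=i,
                            diagnosis_levels=self.diagnosis_levels)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.coding)

    def subset(self, predicate) -> "Cohort":
        return Cohort([r for r in self.records if predicate(r)], self.coding)

    def collapse_diagnosis(self, mapping: dict[str, str] = DIAGNOSIS_COLLAPSE) -> "Cohort":
        """Return a cohort with diagnosis labels collapsed (e.g. to SIDS/non_SIDS)."""
        out = []
        for r in self.records:
            diag = mapping[r.diagnosis] if r.diagnosis is not None else None
            out.append(CaseRecord(r.case_id, dict(r.factors), diag))
        return Cohort(out, self.coding)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"case_id": r.case_id, "diagnosis": r.diagnosis}
            row.update(r.factors)
            rows.append(row)
        cols = ["case_id", "diagnosis", *self.factor_names]
        return pd.DataFrame(rows, columns=cols)


def validate_record(rec: CaseRecord, coding: Sequence[FactorDefinition],
                    row: Optional[int] = None,
                    diagnosis_levels: tuple[str, ...] = STANDARD_DIAGNOSES) -> None:
    where = f"row {row}" if row is not None else f"case {rec.case_id!r}"
    if rec.diagnosis is not None and rec.diagnosis not in diagnosis_levels:
        raise CohortError(f"{where}: unknown diagnosis {rec.diagnosis!r}")
    for fd in coding:
        if fd.name not in rec.factors:
            raise CohortError(f"{where}: missing factor {fd.name!r}")
        val = rec.factors[fd.name]
        if not fd.is_valid_value(val, rec.factors):
            raise CohortError(
                f"{where}: invalid level {val!r} for factor {fd.name!r} "
                f"(expected one of {list(fd.observable_levels)}"
                + (f", or {NOT_APPLICABLE!r} when "
                   f"{fd.applicability.factor}!={fd.applicability.level!r}"
                   if fd.applicability else "") + ")"
            )


def load_cohort(path: Union[str, Path],
                coding: Sequence[FactorDefinition] = DEFAULT_CODING) -> Cohort:
    """Read a cohort CSV, validating every value against the coding scheme."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        header = reader.fieldnames or []
        required = {"case_id", *(f.name for f in coding)}
        missing = required - set(header)
        if missing:
            raise CohortError(f"{path}: missing columns {sorted(missing)}")
        has_diag = "diagnosis" in header
        records = []
        for i, row in enumerate(reader):
            diag = row.get("diagnosis") or None if has_diag else None
            factors = {f.name: row[f.name] for f in coding}
            records.append(CaseRecord(row["case_id"], factors, diag))
    return Cohort(records, tuple(coding))


def write_cohort(cohort: Cohort, path: Union[str, Path],
                 metadata: Optional[dict] = None) -> None:
    """Write a cohort CSV (optionally with ``# key=value`` header comments)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}={v}\n")
        names = ["case_id", "diagnosis", *cohort.factor_names]
        writer = csv.writer(fh)
        writer.writerow(names)
        for r in cohort.records:
            writer.writerow([r.case_id, r.diagnosis or ""] +
                            [r.factors[n] for n in cohort.factor_names])


def summarize_by_group(cohort: Cohort, group: str = "diagnosis") -> pd.DataFrame:
    """Count table: one row per (factor, level), one column per group level.

    Structural not-applicable values are reported under the controlling
    factor's complementary level and appear as ``NA`` rows, so column sums
    over any one factor equal the group sizes.
    """
    if group != "diagnosis" and group not in cohort.factor_names:
        raise CohortError(f"unknown grouping variable {group!r}")
    if group == "diagnosis":
        group_levels = sorted({r.diagnosis for r in cohort.records if r.diagnosis},
                              key=lambda d: (DIAGNOSES + ("non_SIDS",)).index(d)
                              if d in DIAGNOSES + ("non_SIDS",) else 99)
        if any(r.diagnosis is None for r in cohort.records):
            raise CohortError("grouping by diagnosis but some records are unlabeled")
    else:
        fd = next(f for f in cohort.coding if f.name == group)
        group_levels = list(fd.observable_levels)

    rows = []
    for fd in cohort.coding:
        levels = list(fd.observable_levels)
        if fd.applicability is not None:
            levels.append(NOT_APPLICABLE)
        for level in levels:
            counts = {}
            for g in group_levels:
                counts[g] = sum(
                    1 for r in cohort.records
                    if r.value(group) == g and r.factors[fd.name] == level
                )
            rows.append({"factor": fd.name, "level": level,
                         **counts, "total": sum(counts.values())})
    df = pd.DataFrame(rows, columns=["factor", "level", *group_levels, "total"])
    return df


def group_sizes(cohort: Cohort) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for r in cohort.records:
        if r.diagnosis is not None:
            sizes[r.diagnosis] = sizes.get(r.diagnosis, 0) + 1
    return sizes
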