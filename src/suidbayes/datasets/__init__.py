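"""Packaged reference tables and model structures.

These are small plain-text assets: the training-cohort marginal counts,
the eight expert-labelled validation cases, the general-population control
proportions, the regional variability summary (printed means/SDs), and the
editable JSON network structures for diagnostic models 1-3.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from ..cohort import CaseRecord, Cohort, load_cohort
from ..coding import DEFAULT_CODING


def _data_path(name: str) -> Path:
    return Path(resources.files(__package__) / "data" / name)


@dataclass(frozen=True)
class ControlProportion:
    """One general-population reference proportion for a factor level.

    ``stratum`` is an age band (for age-stratified factors) or ``"all"``.
    ``count`` is present where the source publishes counts; ``proportion``
    is always populated (derived from counts when available).
    """

    factor: str
    level: str
    stratum: str
    proportion: float
    count: Optional[int] = None
    source_note: str = ""


def table3_marginals() -> dict:
    """Raw per-group marginal counts of the 64-case training cohort."""
    with _data_path("table3_marginals.json").open(encoding="utf-8") as fh:
        return json.load(fh)


def load_validation_fixture() -> list[CaseRecord]:
    """The eight expert-diagnosed validation cases (6 SIDS, 2 internal)."""
    path = _data_path("table4_cases.csv")
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            factors = {f.name: row[f.name] for f in DEFAULT_CODING}
            records.append(CaseRecord(row["case_id"], factors, row["diagnosis"]))
    # validate against the coding scheme
    Cohort(records, DEFAULT_CODING)
    return records


def load_control_table(path: Optional[Path] = None) -> list[ControlProportion]:
    """General-population control proportions, normalized per (factor, stratum).

    Where counts are published, proportions are recomputed as
    ``count / total`` within the stratum; printed proportions are used only
    for sources that publish no counts.
    """
    path = Path(path) if path is not None else _data_path("table5_controls.csv")
    raw = []
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            raw.append(row)
    totals: dict[tuple[str, str], float] = {}
    have_counts: dict[tuple[str, str], bool] = {}
    for row in raw:
        key = (row["factor"], row["stratum"])
        has = bool(row["count"])
        have_counts[key] = have_counts.get(key, True) and has
        if has:
            totals[key] = totals.get(key, 0.0) + float(row["count"])
    out = []
    for row in raw:
        key = (row["factor"], row["stratum"])
        count = int(row["count"]) if row["count"] else None
        if have_counts[key]:
            prop = count / totals[key]
        else:
            prop = float(row["proportion"])
        out.append(ControlProportion(row["factor"], row["level"], row["stratum"],
                                     prop, count, row["source_note"]))
    _check_normalized(out)
    return out


def _check_normalized(rows: list[ControlProportion]) -> None:
    sums: dict[tuple[str, str], float] = {}
    for r in rows:
        sums[(r.factor, r.stratum)] = sums.get((r.factor, r.stratum), 0.0) + r.proportion
    bad = {k: v for k, v in sums.items() if abs(v - 1.0) > 1e-9}
    if bad:
        raise ValueError(f"control proportions not normalized: {bad}")


def control_lookup(rows: list[ControlProportion]) -> dict:
    """Index control proportions as {(factor, stratum): {level: proportion}}."""
    idx: dict[tuple[str, str], dict[str, float]] = {}
    for r in rows:
        idx.setdefault((r.factor, r.stratum), {})[r.level] = r.proportion
    return idx


def regional_variability_summary() -> pd.DataFrame:
    """Printed per-subcategory mean/SD (rates per 1000 live births) across
    the 47 regions, with the printed CV column for reference."""
    return pd.read_csv(_data_path("table1_variability.csv"))


def model_structure(model_id: int) -> dict:
    """Editable JSON network structure for diagnostic model 1, 2 or 3."""
    if model_id not in (1, 2, 3):
        raise ValueError(f"model_id must be 1, 2 or 3, got {model_id!r}")
    with _data_path(f"model{model_id}.json").open(encoding="utf-8") as fh:
        return json.load(fh)
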