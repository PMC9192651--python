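"""Controlled vocabularies for the SUID case-coding scheme.

Every case record carries 16 categorical risk factors plus a cause-of-death
label.  The coding distinguishes two kinds of missingness:

* ``unknown`` — informational missingness: the factor applies but was not
  ascertained (allowed only where ``allows_unknown`` is set);
* ``NA`` — structural missingness: the factor is undefined for the record
  (e.g. co-sleeping for an infant who did not die during sleep).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

UNKNOWN = "unknown"
NOT_APPLICABLE = "NA"

#: Cause-of-death labels, in declared (tie-break) order.
DIAGNOSES = ("SIDS", "internal", "external")
#: Two-state collapse used by the binary diagnostic models.
DIAGNOSIS_COLLAPSE = {"SIDS": "SIDS", "internal": "non_SIDS", "external": "non_SIDS"}
DIAGNOSES_BINARY = ("SIDS", "non_SIDS")

AGE_BANDS = ("0-2", "3-6", "7-11")


@dataclass(frozen=True)
class Applicability:
    """Predicate restricting a factor to records where a controlling
    factor takes a given level."""

    factor: str
    level: str

    def holds(self, values: dict) -> bool:
        return values.get(self.factor) == self.level


@dataclass(frozen=True)
class FactorDefinition:
    name: str
    levels: tuple[str, ...]
    allows_unknown: bool = False
    applicability: Optional[Applicability] = None

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"factor {self.name!r}: empty level set")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"factor {self.name!r}: duplicate levels")
        if self.allows_unknown and UNKNOWN in self.levels:
            raise ValueError(
                f"factor {self.name!r}: {UNKNOWN!r} duplicated in levels"
            )

    @property
    def observable_levels(self) -> tuple[str, ...]:
        """Levels a record may carry, including ``unknown`` where allowed."""
        return self.levels + ((UNKNOWN,) if self.allows_unknown else ())

    def is_valid_value(self, value: str, other_values: dict) -> bool:
        if self.applicability is not None and not self.applicability.holds(other_values):
            return value == NOT_APPLICABLE
        return value in self.observable_levels

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "levels": list(self.levels),
                   "allows_unknown": self.allows_unknown}
        if self.applicability is not None:
            d["applicability"] = {"factor": self.applicability.factor,
                                  "level": self.applicability.level}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FactorDefinition":
        app = d.get("applicability")
        return cls(
            name=d["name"],
            levels=tuple(d["levels"]),
            allows_unknown=bool(d.get("allows_unknown", False)),
            applicability=Applicability(app["factor"], app["level"]) if app else None,
        )


_SLEEP = Applicability("death_during_sleep", "yes")

#: The 16 risk factors examined for every case, in canonical column order.
DEFAULT_CODING: tuple[FactorDefinition, ...] = (
    FactorDefinition("age_band", AGE_BANDS),
    FactorDefinition("sex", ("male", "female")),
    FactorDefinition("gestational_age", ("<37", ">=37")),
    FactorDefinition("birth_weight", ("<2500", ">=2500")),
    FactorDefinition("death_during_sleep", ("yes", "no")),
    FactorDefinition("co_sleeping", ("yes", "no"), applicability=_SLEEP),
    FactorDefinition("sleep_position", ("supine", "prone", "other"),
                     allows_unknown=True, applicability=_SLEEP),
    FactorDefinition("maternal_age", ("<=19", "20-34", ">=35")),
    FactorDefinition("siblings", ("0", "1", ">=2")),
    FactorDefinition("suid_history", ("yes", "no")),
    FactorDefinition("breastfeeding", ("yes", "no"), allows_unknown=True),
    FactorDefinition("passive_smoking", ("yes", "no"), allows_unknown=True),
    FactorDefinition("alcohol_influence", ("yes", "no")),
    FactorDefinition("vaccination", ("yes", "no"), allows_unknown=True),
    FactorDefinition("maltreatment", ("yes", "no")),
    FactorDefinition("infection_symptoms", ("yes", "no")),
)

FACTOR_NAMES = tuple(f.name for f in DEFAULT_CODING)
CODING_BY_NAME = {f.name: f for f in DEFAULT_CODING}


def coding_to_json(coding: tuple[FactorDefinition, ...] = DEFAULT_CODING) -> str:
    return json.dumps([f.to_dict() for f in coding], indent=2)


def coding_from_json(text: str) -> tuple[FactorDefinition, ...]:
    return tuple(FactorDefinition.from_dict(d) for d in json.loads(text))
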