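"""Synthetic inputs with the statistical structure the analyses assume.

Three generators:

* :func:`generate_replicate_cohort` — a case table whose per-factor marginal
  counts equal the packaged training-cohort specification exactly, for every
  seed; only the arrangement of values across records is random.
* :func:`sample_cohort_from_bn` — ancestral sampling from a Bayesian
  network, used for parameter-recovery testing.
* :func:`generate_regions` — region-level SUID counts from a gamma-Poisson
  (negative-binomial style) surveillance model.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import datasets
from .bayesnet import BayesNet, sample_assignments
from .coding import DEFAULT_CODING, NOT_APPLICABLE, UNKNOWN, FactorDefinition
from .cohort import CaseRecord, Cohort


class SpecError(ValueError):
    """Inconsistent generator specification."""


#: Factors defined only for sleep-related deaths.
_NESTED = ("co_sleeping", "sleep_position")


@dataclass
class MarginalSpec:
    """Exact marginal counts for the replicate cohort.

    ``factor_counts`` maps factor -> count-group -> level -> count, where the
    count groups are ``"SIDS"`` and ``"others"`` (the granularity at which
    the training-cohort marginals are reported).  ``group_sizes`` splits the
    others into internal/external causes.  ``sids_age_stratified`` holds
    age-band joint counts for factors whose case distribution is reported
    per age band (co-sleeping, breastfeeding); these joints are honored
    within the SIDS group.
    """

    group_sizes: dict[str, int]
    factor_counts: dict[str, dict[str, dict[str, int]]]
    sids_age_stratified: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    coding: tuple[FactorDefinition, ...] = DEFAULT_CODING

    @classmethod
    def default(cls) -> "MarginalSpec":
        raw = datasets.table3_marginals()
        return cls(group_sizes=dict(raw["group_sizes"]),
                   factor_counts=raw["factor_counts"],
                   sids_age_stratified=raw.get("sids_age_stratified", {}))

    @property
    def count_group_sizes(self) -> dict[str, int]:
        sizes = dict(self.group_sizes)
        others = sum(v for k, v in sizes.items() if k != "SIDS")
        return {"SIDS": sizes["SIDS"], "others": others}

    def validate(self) -> None:
        sizes = self.count_group_sizes
        sleep = self.factor_counts.get("death_during_sleep", {})
        for fd in self.coding:
            if fd.name not in self.factor_counts:
                raise SpecError(f"factor {fd.name!r}: no counts")
            for grp, n in sizes.items():
                counts = self.factor_counts[fd.name][grp]
                bad = set(counts) - set(fd.observable_levels)
                if bad:
                    raise SpecError(f"factor {fd.name!r}: undeclared levels {sorted(bad)}")
                target = sleep[grp]["yes"] if fd.name in _NESTED else n
                got = sum(counts.values())
                if got != target:
                    raise SpecError(
                        f"factor {fd.name!r}, group {grp!r}: counts sum to {got}, "
                        f"expected {target}")
        age = self.factor_counts["age_band"]["SIDS"]
        for fac, by_band in self.sids_age_stratified.items():
            marg = self.factor_counts[fac]["SIDS"]
            for band, counts in by_band.items():
                if sum(counts.values()) != age[band]:
                    raise SpecError(
                        f"stratified factor {fac!r}, band {band!r}: counts sum to "
                        f"{sum(counts.values())}, expected {age[band]}")
            for level in marg:
                strat = sum(by_band[b].get(level, 0) for b in by_band)
                if strat != marg[level]:
                    raise SpecError(
                        f"stratified factor {fac!r}, level {level!r}: joint sum "
                        f"{strat} != marginal {marg[level]}")


def _permuted_levels(counts: dict[str, int], rng: np.random.Generator) -> list[str]:
    pool = [lvl for lvl, c in counts.items() for _ in range(c)]
    return [pool[i] for i in rng.permutation(len(pool))]


def generate_replicate_cohort(spec: Optional[MarginalSpec] = None,
                              seed: int = 0) -> Cohort:
    """Build a cohort whose marginal summary equals ``spec`` exactly.

    Within each diagnosis group, factor values are assigned by independent
    seeded permutation, honoring the structural nesting (co-sleeping and
    sleep position exist only for sleep-related deaths) and the age-band
    joints declared in ``sids_age_stratified``.  Joint structure beyond
    those printed constraints is deliberately not modelled.
    """
    spec = spec if spec is not None else MarginalSpec.default()
    spec.validate()
    rng = np.random.default_rng(seed)

    records: list[CaseRecord] = []
    case_no = 0
    for grp in ("SIDS", "others"):
        n = spec.count_group_sizes[grp]
        if grp == "SIDS":
            labels = ["SIDS"] * n
        else:
            pool = [d for d, c in spec.group_sizes.items() if d != "SIDS"
                    for _ in range(c)]
            labels = [pool[i] for i in rng.permutation(n)]

        values: dict[str, list[Optional[str]]] = {}
        counts_of = lambda f: spec.factor_counts[f][grp]
        values["age_band"] = _permuted_levels(counts_of("age_band"), rng)
        values["death_during_sleep"] = _permuted_levels(counts_of("death_during_sleep"), rng)
        sleep_idx = [i for i in range(n) if values["death_during_sleep"][i] == "yes"]

        for fd in spec.coding:
            if fd.name in ("age_band", "death_during_sleep"):
                continue
            stratified = grp == "SIDS" and fd.name in spec.sids_age_stratified
            if fd.name in _NESTED:
                col: list[str] = [NOT_APPLICABLE] * n
                if stratified:
                    for band, counts in spec.sids_age_stratified[fd.name].items():
                        idx = [i for i in sleep_idx if values["age_band"][i] == band]
                        if len(idx) != sum(counts.values()):
                            raise SpecError(
                                f"factor {fd.name!r}: band {band!r} joint counts "
                                f"inconsistent with sleep-related records")
                        for i, lvl in zip(idx, _permuted_levels(counts, rng)):
                            col[i] = lvl
                else:
                    for i, lvl in zip(sleep_idx, _permuted_levels(counts_of(fd.name), rng)):
                        col[i] = lvl
                values[fd.name] = col
            elif stratified:
                col = [None] * n
                for band, counts in spec.sids_age_stratified[fd.name].items():
                    idx = [i for i in range(n) if values["age_band"][i] == band]
                    for i, lvl in zip(idx, _permuted_levels(counts, rng)):
                        col[i] = lvl
                values[fd.name] = col
            else:
                values[fd.name] = _permuted_levels(counts_of(fd.name), rng)

        for i in range(n):
            case_no += 1
            factors = {fd.name: values[fd.name][i] for fd in spec.coding}
            records.append(CaseRecord(f"r{case_no:03d}", factors, labels[i]))

    return Cohort(records, spec.coding)


def sample_cohort_from_bn(net: BayesNet, n: int, seed: int = 0,
                          coding: Optional[tuple[FactorDefinition, ...]] = None) -> Cohort:
    """Ancestral-sample ``n`` case records from a Bayesian network.

    Non-diagnosis nodes become factors.  If ``coding`` is not given, a
    coding scheme is synthesized from the node state spaces (the literal
    ``unknown`` state maps onto informational missingness); nodes with a
    structural ``NA`` state then require an explicit ``coding``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    assignments = sample_assignments(net, n, rng)
    factor_nodes = [name for name in net.spec.node_names if name != "diagnosis"]
    if coding is None:
        defs = []
        for name in factor_nodes:
            states = net.spec.states(name)
            if NOT_APPLICABLE in states:
                raise ValueError(
                    f"node {name!r} has a structural {NOT_APPLICABLE!r} state; "
                    "pass an explicit coding")
            allows_unknown = UNKNOWN in states
            levels = tuple(s for s in states if s != UNKNOWN)
            defs.append(FactorDefinition(name, levels, allows_unknown=allows_unknown))
        coding = tuple(defs)
    records = []
    for i, a in enumerate(assignments):
        factors = {name: a[name] for name in factor_nodes}
        records.append(CaseRecord(f"s{i + 1:05d}", factors, a.get("diagnosis")))
    diag_levels = (net.spec.states("diagnosis")
                   if "diagnosis" in net.spec.node_names else ())
    return Cohort(records, coding, diagnosis_levels=diag_levels)


# --- regions ------------------------------------------------------------

@dataclass
class RegionSimSpec:
    """Gamma-Poisson generator for region-level SUID subcategory counts.

    Per subcategory, region rates are gamma-distributed around
    ``mean_rates`` (per 1000 live births) with coefficient of variation
    ``rate_cv``; death counts are Poisson with mean
    ``live_births * rate / 1000``.  A subcategory with ``rate_cv == 0``
    is fully deterministic (expected counts), so downstream rate
    variability is exactly zero.
    """

    n_regions: int = 47
    live_births_range: tuple[int, int] = (30_000, 400_000)
    mean_rates: dict[str, float] = field(default_factory=lambda: {
        "sids": 0.11, "asphyxia": 0.07, "unknown": 0.31})
    rate_cv: dict[str, float] = field(default_factory=lambda: {
        "sids": 0.727, "asphyxia": 0.714, "unknown": 0.322})

    def validate(self) -> None:
        if self.n_regions < 2:
            raise SpecError("n_regions must be >= 2")
        if self.live_births_range[0] <= 0 or self.live_births_range[1] < self.live_births_range[0]:
            raise SpecError("invalid live_births_range")
        for k, v in self.mean_rates.items():
            if v < 0:
                raise SpecError(f"negative mean rate for {k!r}")
            if self.rate_cv.get(k, 0.0) < 0:
                raise SpecError(f"negative rate CV for {k!r}")


def generate_regions(spec: Optional[RegionSimSpec] = None, seed: int = 0) -> pd.DataFrame:
    """Simulate a region table: region id, live births, subcategory deaths."""
    spec = spec if spec is not None else RegionSimSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    lo, hi = spec.live_births_range
    births = rng.integers(lo, hi + 1, size=spec.n_regions)
    deterministic = all(cv == 0.0 for cv in spec.rate_cv.values())
    if deterministic:
        # zero dispersion: identical rates, expected (non-sampled) counts
        births = np.full(spec.n_regions, (lo + hi) // 2)
    data = {"region": [f"region-{i + 1:02d}" for i in range(spec.n_regions)],
            "live_births": births}
    for sub, mean in spec.mean_rates.items():
        cv = spec.rate_cv.get(sub, 0.0)
        if cv == 0.0:
            rates = np.full(spec.n_regions, mean)
            deaths = births * rates / 1000.0
            data[sub] = deaths if deterministic else np.round(deaths).astype(int)
        else:
            shape = 1.0 / cv ** 2
            rates = rng.gamma(shape, mean / shape, size=spec.n_regions)
            data[sub] = rng.poisson(births * rates / 1000.0)
    return pd.DataFrame(data)


def default_control_tables():
    """The packaged general-population control proportions."""
    return datasets.load_control_table()
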