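"""Age-stratified SIDS onset-incidence model.

The model updates a general-population annual SIDS incidence prior (rate
per 1000 live births per year) with an age-band prior ratio and one
case-versus-population likelihood ratio per observed risk-factor level:

    rate(band, x) = prior * [P(band | case) / P(band | population)]
                          * prod_i P(x_i | case) / P(x_i | population)

This rate-space product is the first-order (rare-event) form of the exact
posterior odds update; both forms are implemented and agree to better than
1% relative for rates below a few per 1000.  Factors left unassigned are
neutral and contribute a ratio of exactly 1.

Case proportions come from the SIDS cases of a fitted cohort (records with
``unknown``/``NA`` values are excluded from denominators); population
proportions come from packaged control tables.  Co-sleeping and
breastfeeding are age-stratified because their reference data are published
per age band; the remaining factors use a single stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .coding import AGE_BANDS, NOT_APPLICABLE, UNKNOWN
from .cohort import Cohort
from .datasets import ControlProportion, control_lookup, load_control_table

#: Default annual SIDS incidence in the general population, per 1000 live births.
DEFAULT_PRIOR_RATE = 0.3

_DEFAULT_FACTORS = ("sex", "gestational_age", "birth_weight",
                    "co_sleeping", "breastfeeding", "passive_smoking")


def derive_prior(suid_rate: float, sids_fraction: float, decimals: int = 1) -> float:
    """General-population SIDS rate = total SUID rate x SIDS proportion,
    rounded half-up to the stated precision."""
    if suid_rate <= 0 or sids_fraction <= 0:
        raise ValueError("inputs must be positive")
    return _round_half_up(suid_rate * sids_fraction, decimals)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_rate(x: float) -> float:
    """Display rounding: one decimal for rates >= 0.25, two below."""
    return _round_half_up(x, 1 if x >= 0.25 else 2)


@dataclass
class IncidenceGrid:
    """Age band x risk-group incidence grid with ratio columns.

    Groups: A = no smoking / no co-sleeping, B = no / yes,
    C = yes / no, D = yes / yes.  ``display`` applies the display rounding;
    the ratio columns (D/A and D over the general-population rate) are
    computed from the rounded cells.
    """

    raw: pd.DataFrame
    display: pd.DataFrame


class OnsetIncidenceModel(BaseEstimator):
    """Sklearn-style estimator for annual SIDS incidence by risk profile.

    Parameters
    ----------
    prior_rate : float
        General-population annual SIDS incidence per 1000 live births.
    controls : list of ControlProportion, optional
        Population reference proportions; defaults to the packaged tables.
    factors : sequence of str
        Risk factors whose likelihood ratios the model uses.
    stratified_factors : sequence of str
        Factors whose case/control proportions are age-band-stratified.
    """

    def __init__(self, prior_rate: float = DEFAULT_PRIOR_RATE,
                 controls: Optional[list[ControlProportion]] = None,
                 factors: Sequence[str] = _DEFAULT_FACTORS,
                 stratified_factors: Sequence[str] = ("co_sleeping", "breastfeeding"),
                 age_bands: Sequence[str] = AGE_BANDS):
        self.prior_rate = prior_rate
        self.controls = controls
        self.factors = factors
        self.stratified_factors = stratified_factors
        self.age_bands = age_bands

    # --- fitting -------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "OnsetIncidenceModel":
        """Estimate case proportions from a table of SIDS case records.

        ``X`` needs an ``age_band`` column plus one column per factor;
        ``unknown`` and ``NA`` values are excluded from denominators.
        """
        if self.prior_rate <= 0:
            raise ValueError("prior_rate must be positive")
        controls = self.controls if self.controls is not None else load_control_table()
        self._control_idx_ = control_lookup(controls)

        band_counts = X["age_band"].value_counts()
        n = float(len(X))
        self.case_age_dist_ = {b: band_counts.get(b, 0) / n for b in self.age_bands}
        self.population_age_dist_ = {
            b: self._control_idx_[("age_band", "all")][b] for b in self.age_bands}

        tables: dict[str, dict[str, dict[str, float]]] = {}
        for fac in self.factors:
            tables[fac] = {}
            strata = list(self.age_bands) if fac in self.stratified_factors else ["all"]
            for stratum in strata:
                rows = X if stratum == "all" else X[X["age_band"] == stratum]
                vals = rows[fac][~rows[fac].isin([UNKNOWN, NOT_APPLICABLE])]
                total = len(vals)
                counts = vals.value_counts()
                tables[fac][stratum] = (
                    {lvl: counts.get(lvl, 0) / total for lvl in counts.index}
                    if total else {})
        self.case_tables_ = tables
        return self

    def fit_cohort(self, cohort: Cohort, case_label: str = "SIDS") -> "OnsetIncidenceModel":
        cases = cohort.subset(lambda r: r.diagnosis == case_label)
        if not len(cases):
            raise ValueError(f"cohort has no {case_label!r} cases")
        return self.fit(cases.to_frame())

    # --- components ----------------------------------------------------

    def _stratum(self, factor: str, band: str) -> str:
        return band if factor in self.stratified_factors else "all"

    def age_prior(self, band: str) -> float:
        """Annual incidence per 1000 for an age band, before risk factors."""
        if band not in self.age_bands:
            raise ValueError(f"undeclared age band {band!r}")
        return (self.prior_rate * self.case_age_dist_[band]
                / self.population_age_dist_[band])

    def likelihood_ratio(self, factor: str, level: str, band: str) -> float:
        """Case proportion over population proportion for one factor level."""
        stratum = self._stratum(factor, band)
        case_p = self.case_tables_[factor].get(stratum, {}).get(level)
        if case_p is None:
            raise ValueError(
                f"no case proportion for {factor}={level!r} (stratum {stratum!r})")
        try:
            control_p = self._control_idx_[(factor, stratum)][level]
        except KeyError:
            raise ValueError(
                f"no control proportion for {factor}={level!r} (stratum {stratum!r})")
        if control_p <= 0:
            raise ZeroDivisionError(
                f"control proportion is 0 for {factor}={level!r}; ratio undefined")
        return case_p / control_p

    # --- prediction ----------------------------------------------------

    def predict_incidence(self, band: str, assignment: Mapping[str, str]) -> float:
        """Annual incidence per 1000 for a (partial) risk profile.

        Unassigned factors are neutral; each assigned level multiplies the
        age-band prior by its likelihood ratio.
        """
        rate = self.age_prior(band)
        for factor, level in assignment.items():
            if factor not in self.factors:
                raise ValueError(f"undeclared factor {factor!r}")
            rate *= self.likelihood_ratio(factor, level, band)
        return rate

    def posterior_exact(self, band: str, assignment: Mapping[str, str]) -> float:
        """Exact posterior-odds form of the same update, as a rate per 1000.

        Converts the age-band rate to a probability, applies Bayes' rule with
        the factor likelihood ratios on the odds scale, and converts back.
        """
        p0 = self.age_prior(band) / 1000.0
        odds = p0 / (1.0 - p0)
        for factor, level in assignment.items():
            odds *= self.likelihood_ratio(factor, level, band)
        return 1000.0 * odds / (1.0 + odds)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Vectorized :meth:`predict_incidence` over rows of a DataFrame.

        Missing/NaN factor cells are neutral.
        """
        out = np.empty(len(X))
        for i, (_, row) in enumerate(X.iterrows()):
            assignment = {f: row[f] for f in self.factors
                          if f in X.columns and pd.notna(row[f])}
            out[i] = self.predict_incidence(row["age_band"], assignment)
        return out

    def incidence_grid(self, extra_assignment: Optional[Mapping[str, str]] = None) -> IncidenceGrid:
        """3 x 4 grid of incidence by (passive smoking, co-sleeping) status.

        ``extra_assignment`` fixes additional factor levels (e.g. a
        high-risk subgroup) and must not touch smoking or co-sleeping.
        """
        extra = dict(extra_assignment or {})
        if {"passive_smoking", "co_sleeping"} & set(extra):
            raise ValueError("extra_assignment must not set smoking/co-sleeping")
        groups = {"A": ("no", "no"), "B": ("no", "yes"),
                  "C": ("yes", "no"), "D": ("yes", "yes")}
        raw_rows, disp_rows = [], []
        for band in self.age_bands:
            raw = {}
            for g, (smoke, cosleep) in groups.items():
                raw[g] = self.predict_incidence(
                    band, {"passive_smoking": smoke, "co_sleeping": cosleep, **extra})
            disp = {g: round_rate(v) for g, v in raw.items()}
            disp["D_over_A"] = _round_half_up(disp["D"] / disp["A"], 1)
            disp["D_over_general"] = _round_half_up(disp["D"] / self.prior_rate, 1)
            raw_rows.append({"age_band": band, **raw})
            disp_rows.append({"age_band": band, **disp})
        return IncidenceGrid(
            raw=pd.DataFrame(raw_rows).set_index("age_band"),
            display=pd.DataFrame(disp_rows).set_index("age_band"),
        )


def fit_default_model(cohort: Cohort, prior_rate: float = DEFAULT_PRIOR_RATE,
                      controls: Optional[list[ControlProportion]] = None) -> OnsetIncidenceModel:
    """Convenience wrapper: fit the standard onset model on a labelled cohort."""
    return OnsetIncidenceModel(prior_rate=prior_rate, controls=controls).fit_cohort(cohort)
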