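"""Onset-incidence model: priors, likelihood ratios, grid reproduction."""

import numpy as np
import pandas as pd
import pytest

from suidbayes.onset import OnsetIncidenceModel, derive_prior, round_rate


class TestPriorDerivation:
    @pytest.mark.parametrize("suid, frac, expected", [
        (0.49, 0.64, 0.3),
        (1.0, 1.0, 1.0),
        (0.49, 0.5, 0.2),
    ])
    def test_prior_is_rounded_product(self, suid, frac, expected):
        assert derive_prior(suid, frac) == expected

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            derive_prior(0.0, 0.64)


class TestAgePrior:
    def test_youngest_band(self, onset_model):
        assert onset_model.age_prior("0-2") == pytest.approx(0.3 * (13 / 41) / (3 / 12))

    def test_oldest_band(self, onset_model):
        assert onset_model.age_prior("7-11") == pytest.approx(0.3 * (4 / 41) / (5 / 12))

    def test_marginal_incidence_is_conserved(self, onset_model):
        total = sum(onset_model.population_age_dist_[b] * onset_model.age_prior(b)
                    for b in onset_model.age_bands)
        assert total == pytest.approx(onset_model.prior_rate)

    def test_undeclared_band_rejected(self, onset_model):
        with pytest.raises(ValueError, match="band"):
            onset_model.age_prior("12-24")


class TestLikelihoodRatios:
    def test_passive_smoking_excludes_unknowns(self, onset_model):
        # 21 exposed of 30 known SIDS cases vs 33.1% population prevalence
        assert onset_model.likelihood_ratio("passive_smoking", "yes", "0-2") == \
            pytest.approx((21 / 30) / 0.331)

    def test_co_sleeping_age_stratified(self, onset_model):
        assert onset_model.likelihood_ratio("co_sleeping", "yes", "0-2") == \
            pytest.approx((12 / 13) / (43 / 141))

    def test_equal_proportions_give_unit_ratio(self, replicate_cohort):
        from suidbayes.datasets import ControlProportion

        model = OnsetIncidenceModel(controls=_controls_matching_cases())
        model.fit_cohort(replicate_cohort)
        assert model.likelihood_ratio("sex", "male", "0-2") == pytest.approx(1.0)

    def test_zero_control_proportion_is_an_error(self, replicate_cohort):
        from suidbayes.datasets import load_control_table

        controls = [c for c in load_control_table()]
        bad = [type(c)(c.factor, c.level, c.stratum,
                       0.0 if (c.factor, c.level) == ("sex", "male") else c.proportion,
                       c.count, c.source_note) for c in controls]
        model = OnsetIncidenceModel(controls=bad)
        model.fit_cohort(replicate_cohort)
        with pytest.raises(ZeroDivisionError):
            model.likelihood_ratio("sex", "male", "0-2")


def _controls_matching_cases():
    """Controls whose sex proportions equal the case proportions (22/41)."""
    from suidbayes.datasets import ControlProportion, load_control_table

    out = []
    for c in load_control_table():
        if c.factor == "sex":
            p = 22 / 41 if c.level == "male" else 19 / 41
            out.append(ControlProportion("sex", c.level, "all", p))
        else:
            out.append(c)
    return out


class TestPrediction:
    def test_high_risk_youngest_band(self, onset_model):
        rate = onset_model.predict_incidence(
            "0-2", {"passive_smoking": "yes", "co_sleeping": "yes"})
        assert round_rate(rate) == 2.4

    def test_low_risk_youngest_band(self, onset_model):
        rate = onset_model.predict_incidence(
            "0-2", {"passive_smoking": "no", "co_sleeping": "no"})
        assert round_rate(rate) == 0.02

    def test_empty_assignment_returns_age_prior(self, onset_model):
        for band in onset_model.age_bands:
            assert onset_model.predict_incidence(band, {}) == \
                pytest.approx(onset_model.age_prior(band))

    def test_update_is_exactly_multiplicative(self, onset_model):
        base = onset_model.predict_incidence("3-6", {"passive_smoking": "yes"})
        extended = onset_model.predict_incidence(
            "3-6", {"passive_smoking": "yes", "breastfeeding": "no"})
        lr = onset_model.likelihood_ratio("breastfeeding", "no", "3-6")
        assert extended == pytest.approx(base * lr, rel=1e-12)

    def test_vectorized_predict_matches_scalar(self, onset_model):
        X = pd.DataFrame([
            {"age_band": "0-2", "passive_smoking": "yes", "co_sleeping": "yes"},
            {"age_band": "3-6", "passive_smoking": None, "co_sleeping": "no"},
        ])
        got = onset_model.predict(X)
        assert got[0] == pytest.approx(onset_model.predict_incidence(
            "0-2", {"passive_smoking": "yes", "co_sleeping": "yes"}))
        assert got[1] == pytest.approx(onset_model.predict_incidence(
            "3-6", {"co_sleeping": "no"}))

    def test_rare_event_form_tracks_exact_posterior(self, onset_model):
        for band in onset_model.age_bands:
            for smoke in ("yes", "no"):
                for cosleep in ("yes", "no"):
                    a = {"passive_smoking": smoke, "co_sleeping": cosleep}
                    lr_form = onset_model.predict_incidence(band, a)
                    exact = onset_model.posterior_exact(band, a)
                    if lr_form < 5.0:  # rates below 5 per 1000
                        assert abs(lr_form - exact) / exact < 0.01


class TestGrid:
    def test_ratio_columns_from_rounded_cells(self, onset_model):
        disp = onset_model.incidence_grid().display
        assert disp.loc["0-2", "D_over_A"] == 120.0
        assert disp.loc["0-2", "D_over_general"] == 8.0
        assert disp.loc["3-6", "D_over_general"] == 5.0
        assert disp.loc["7-11", "D_over_general"] == 0.7

    def test_risk_ordering_when_both_ratios_exceed_one(self, onset_model):
        raw = onset_model.incidence_grid().raw
        for band in ("0-2", "3-6", "7-11"):
            row = raw.loc[band]
            assert row["D"] >= row[["A", "B", "C"]].max()

    def test_high_risk_subgroup_dominates_default(self, onset_model):
        base = onset_model.incidence_grid().raw
        sub = onset_model.incidence_grid(
            {"sex": "male", "birth_weight": "<2500", "breastfeeding": "no"}).raw
        for band in ("0-2", "3-6"):
            assert (sub.loc[band] >= base.loc[band]).all()

    def test_smoking_and_cosleeping_cannot_be_fixed_extra(self, onset_model):
        with pytest.raises(ValueError, match="extra_assignment"):
            onset_model.incidence_grid({"passive_smoking": "yes"})


class TestRounding:
    @pytest.mark.parametrize("x, expected", [
        (0.018884, 0.02), (0.51646, 0.5), (2.43556, 2.4),
        (0.147351, 0.15), (0.2471, 0.25), (0.25, 0.3),
    ])
    def test_display_rule(self, x, expected):
        assert round_rate(x) == expected
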