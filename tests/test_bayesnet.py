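"""Discrete BN engine: validation, estimation, exact inference, sampling."""

import itertools

import numpy as np
import pytest

from suidbayes.bayesnet import (
    NEUTRAL,
    BayesNet,
    Cpt,
    ImpossibleEvidenceError,
    NetworkError,
    NetworkSpec,
    estimate_cpts,
    posterior_enumeration,
    posterior_ve,
    sample_assignments,
    validate_network,
)
from suidbayes.synthetic import sample_cohort_from_bn

from _oracles import random_evidence, random_network


def _binary(name):
    return (name, ("yes", "no"))


class TestValidation:
    def test_valid_chain(self):
        spec = NetworkSpec((_binary("A"), _binary("B"), _binary("C")),
                           (("A", "B"), ("B", "C")))
        assert validate_network(spec) == []

    def test_cycle_reported(self):
        spec = NetworkSpec((_binary("A"), _binary("B")), (("A", "B"), ("B", "A")))
        assert any("cycle" in p for p in validate_network(spec))

    def test_undeclared_node_reported(self):
        spec = NetworkSpec((_binary("A"),), (("A", "ghost"),))
        assert any("ghost" in p for p in validate_network(spec))

    def test_cpt_row_must_normalize(self):
        with pytest.raises(NetworkError, match="sum to 1"):
            Cpt("A", (), ("yes", "no"), (), np.array([0.7, 0.7]))


def _disease_sleep_net():
    """Two-state outcome with a deterministic sleep-related-death CPT."""
    spec = NetworkSpec((("D", ("SIDS", "other")), _binary("S")), (("D", "S"),))
    cpts = {
        "D": Cpt("D", (), ("SIDS", "other"), (), np.array([41 / 64, 23 / 64])),
        "S": Cpt("S", ("D",), ("yes", "no"), (("SIDS", "other"),),
                 np.array([[1.0, 0.0], [13 / 23, 10 / 23]])),
    }
    return BayesNet(spec, cpts)


class TestJointAndEnumeration:
    def test_single_node_joint(self):
        spec = NetworkSpec((("D", ("SIDS", "other")),), ())
        net = BayesNet(spec, {"D": Cpt("D", (), ("SIDS", "other"), (),
                                       np.array([0.64, 0.36]))})
        assert net.joint_probability({"D": "SIDS"}) == pytest.approx(0.64)

    def test_joint_sums_to_one(self, rng):
        net = random_network(rng, max_nodes=5)
        total = sum(net.joint_probability(dict(zip(net.spec.node_names, combo)))
                    for combo in itertools.product(
                        *(net.spec.states(n) for n in net.spec.node_names)))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_independent_fair_coins(self):
        spec = NetworkSpec((_binary("A"), _binary("B")), ())
        half = np.array([0.5, 0.5])
        net = BayesNet(spec, {"A": Cpt("A", (), ("yes", "no"), (), half),
                              "B": Cpt("B", (), ("yes", "no"), (), half)})
        assert net.joint_probability({"A": "yes", "B": "no"}) == pytest.approx(0.25)

    def test_posterior_after_sleep_evidence(self):
        post = posterior_enumeration(_disease_sleep_net(), "D", {"S": "yes"})
        assert post["SIDS"] == pytest.approx(0.7592592592592593)

    def test_no_evidence_returns_prior(self):
        post = posterior_enumeration(_disease_sleep_net(), "D", {})
        assert post["SIDS"] == pytest.approx(41 / 64)

    def test_neutral_marker_is_marginalized(self):
        net = _disease_sleep_net()
        assert (posterior_enumeration(net, "D", {"S": NEUTRAL})
                == posterior_enumeration(net, "D", {}))

    def test_impossible_evidence_raises(self):
        spec = NetworkSpec((_binary("A"), _binary("B")), (("A", "B"),))
        net = BayesNet(spec, {
            "A": Cpt("A", (), ("yes", "no"), (), np.array([1.0, 0.0])),
            "B": Cpt("B", ("A",), ("yes", "no"), (("yes", "no"),),
                     np.array([[1.0, 0.0], [0.5, 0.5]]))})
        with pytest.raises(ImpossibleEvidenceError):
            posterior_enumeration(net, "A", {"B": "no"})
        with pytest.raises(ImpossibleEvidenceError):
            posterior_ve(net, "A", {"B": "no"})


class TestVariableElimination:
    def test_matches_enumeration_on_random_networks(self, rng):
        # reduced sweep; the full 200-network battery runs in the acceptance suite
        for _ in range(50):
            net = random_network(rng)
            query, evidence = random_evidence(net, rng)
            try:
                expected = posterior_enumeration(net, query, evidence)
            except ImpossibleEvidenceError:
                with pytest.raises(ImpossibleEvidenceError):
                    posterior_ve(net, query, evidence)
                continue
            got = posterior_ve(net, query, evidence)
            for state, p in expected.items():
                assert abs(got[state] - p) < 1e-9

    def test_chain_closed_form(self):
        # A -> B -> C with evidence on C: two-step Bayes inversion
        pa, pba, pcb = 0.3, ((0.8, 0.2), (0.4, 0.6)), ((0.9, 0.1), (0.25, 0.75))
        spec = NetworkSpec((_binary("A"), _binary("B"), _binary("C")),
                           (("A", "B"), ("B", "C")))
        net = BayesNet(spec, {
            "A": Cpt("A", (), ("yes", "no"), (), np.array([pa, 1 - pa])),
            "B": Cpt("B", ("A",), ("yes", "no"), (("yes", "no"),), np.array(pba)),
            "C": Cpt("C", ("B",), ("yes", "no"), (("yes", "no"),), np.array(pcb)),
        })
        p_b_yes = pa * pba[0][0] + (1 - pa) * pba[1][0]
        num = p_b_yes * pcb[0][0]
        den = num + (1 - p_b_yes) * pcb[1][0]
        expected_b = num / den
        got = posterior_ve(net, "B", {"C": "yes"})
        assert got["yes"] == pytest.approx(expected_b, abs=1e-12)

    def test_posterior_normalizes(self, rng):
        for _ in range(20):
            net = random_network(rng)
            query, evidence = random_evidence(net, rng)
            try:
                post = posterior_ve(net, query, evidence)
            except ImpossibleEvidenceError:
                continue
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_node_declaration_order(self):
        net = _disease_sleep_net()
        flipped_spec = NetworkSpec(tuple(reversed(net.spec.nodes)), net.spec.edges)
        flipped = BayesNet(flipped_spec, net.cpts)
        assert (posterior_ve(net, "D", {"S": "yes"})
                == pytest.approx(posterior_ve(flipped, "D", {"S": "yes"})))


class TestEstimation:
    def test_stratified_conditional_proportion(self, replicate_cohort):
        # P(breastfeeding = yes | SIDS, 3-6 months) from 7 yes / 17 no
        spec = NetworkSpec(
            (("diagnosis", ("SIDS", "internal", "external")),
             ("age_band", ("0-2", "3-6", "7-11")),
             ("breastfeeding", ("yes", "no"))),
            (("diagnosis", "breastfeeding"), ("age_band", "breastfeeding")))
        net = estimate_cpts(spec, replicate_cohort, unknown_policy="exclude")
        cpt = net.cpts["breastfeeding"]
        assert cpt.prob("yes", {"diagnosis": "SIDS", "age_band": "3-6"}) == \
            pytest.approx(7 / 24)

    def test_deterministic_sleep_row(self, replicate_cohort):
        spec = NetworkSpec(
            (("diagnosis", ("SIDS", "internal", "external")), _binary("death_during_sleep")),
            (("diagnosis", "death_during_sleep"),))
        net = estimate_cpts(spec, replicate_cohort)
        assert net.cpts["death_during_sleep"].prob(
            "yes", {"diagnosis": "SIDS"}) == pytest.approx(1.0)

    def test_zero_count_rows_fall_back_to_uniform(self):
        spec = NetworkSpec((_binary("A"), ("B", ("x", "y", "z"))), (("A", "B"),))
        net = estimate_cpts_empty(spec)
        assert np.allclose(net.cpts["B"].values, 1 / 3)

    def test_node_without_cohort_variable_rejected(self, replicate_cohort):
        spec = NetworkSpec((_binary("shoe_size"),), ())
        with pytest.raises(NetworkError, match="shoe_size"):
            estimate_cpts(spec, replicate_cohort)

    def test_parameter_recovery_small(self):
        net = random_network(np.random.default_rng(77), max_nodes=4, max_states=3)
        cohort = sample_cohort_from_bn(net, n=10_000, seed=78)
        est = estimate_cpts(net.spec, cohort, unknown_policy="as_state")
        for name, cpt in net.cpts.items():
            rows = cpt.values.reshape(-1, len(cpt.states))
            got = est.cpts[name].values.reshape(-1, len(cpt.states))
            # only rows whose parent configs actually occur can be recovered
            for r_true, r_est in zip(rows, got):
                if not np.allclose(r_est, 1 / len(cpt.states)):
                    assert np.abs(r_true - r_est).max() < 0.02


def estimate_cpts_empty(spec):
    """Estimate from zero records (all rows fall back to uniform)."""
    from suidbayes.cohort import Cohort
    from suidbayes.coding import FactorDefinition

    coding = tuple(FactorDefinition(n, s) for n, s in spec.nodes)
    return estimate_cpts(spec, Cohort([], coding))


class TestMonotonicity:
    def test_favorable_evidence_increases_posterior(self):
        # evidence level with likelihood ratio > 1 must raise the favored state
        for lr_hi, lr_lo in ((0.8, 0.4), (0.6, 0.1), (0.51, 0.5)):
            spec = NetworkSpec((_binary("Q"), _binary("E")), (("Q", "E"),))
            net = BayesNet(spec, {
                "Q": Cpt("Q", (), ("yes", "no"), (), np.array([0.3, 0.7])),
                "E": Cpt("E", ("Q",), ("yes", "no"), (("yes", "no"),),
                         np.array([[lr_hi, 1 - lr_hi], [lr_lo, 1 - lr_lo]]))})
            post = posterior_ve(net, "Q", {"E": "yes"})
            assert post["yes"] > 0.3


class TestSerialization:
    def test_json_round_trip(self, rng):
        net = random_network(rng, max_nodes=5)
        back = BayesNet.from_json(net.to_json())
        assert back.spec == net.spec
        for name in net.spec.node_names:
            assert np.allclose(back.cpts[name].values, net.cpts[name].values)


class TestSampling:
    def test_conditional_frequencies_converge(self):
        spec = NetworkSpec((_binary("A"), _binary("B")), (("A", "B"),))
        net = BayesNet(spec, {
            "A": Cpt("A", (), ("yes", "no"), (), np.array([0.25, 0.75])),
            "B": Cpt("B", ("A",), ("yes", "no"), (("yes", "no"),),
                     np.array([[0.9, 0.1], [0.3, 0.7]]))})
        draws = sample_assignments(net, 10_000, np.random.default_rng(5))
        a_yes = [d for d in draws if d["A"] == "yes"]
        freq = sum(1 for d in a_yes if d["B"] == "yes") / len(a_yes)
        assert abs(freq - 0.9) < 0.02
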