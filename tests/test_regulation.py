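"""Interaction networks, agreement calls, consensus, and activation scores."""

import numpy as np
import pandas as pd
import pytest

from evoprofiler.regulation import (
    InteractionEdge,
    InteractionNetwork,
    build_interaction_network,
    call_agreement,
    category_weight,
    consensus_for_unmeasured,
    mode_for_reaction_role,
    regulator_activation,
)
from evoprofiler.synthetic import generate_regulatory_network, generate_regulon_profiles


def _triple_df(d):
    return pd.DataFrame.from_dict(d, orient="index", columns=["ref", "uko", "eko"])


class TestBuildNetwork:
    def test_empty_records(self):
        net = build_interaction_network([])
        assert net.edges == [] and net.nodes == set()

    def test_duplicate_triple_rejected(self):
        e = ("TyrR", "aroF", "positive", "tf_gene")
        with pytest.raises(ValueError):
            build_interaction_network([e, e])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_interaction_network([("A", "B", "sideways", "tf_gene")])

    def test_effector_tf_gene_chain_loads_as_two_edges(self):
        # metabolite-mediated TF activation: tyrosine -> TyrR -> aroF
        net = build_interaction_network([
            {"regulator": "tyr__L", "entity": "TyrR", "mode": "positive",
             "kind": "metabolite_tf"},
            {"regulator": "TyrR", "entity": "aroF", "mode": "positive",
             "kind": "tf_gene"},
        ])
        assert len(net.edges) == 2
        assert net.n_regulators("aroF") == 1
        assert [e.mode for e in net.edges] == ["positive", "positive"]

    def test_reaction_role_modes(self):
        assert mode_for_reaction_role("reactant") == "positive"
        assert mode_for_reaction_role("product") == "negative"
        with pytest.raises(ValueError):
            mode_for_reaction_role("catalyst")


class TestAgreement:
    def _net(self, mode):
        return InteractionNetwork(
            [InteractionEdge("M", "G", mode, "metabolite_tf")], {"M", "G"})

    def test_positive_mode_positive_r_agrees(self):
        triples = _triple_df({"M": [0, 1, 0], "G": [0, 0.95, 0.02]})
        calls = call_agreement(self._net("positive"), triples)
        assert calls[0].call == "agreement" and calls[0].r > 0.88

    def test_positive_mode_negative_r_disagrees(self):
        triples = _triple_df({"M": [0, 1, 0], "G": [1, 0.05, 0.98]})
        calls = call_agreement(self._net("positive"), triples)
        assert calls[0].call == "disagreement" and calls[0].r < -0.88

    def test_below_threshold_indeterminate(self):
        triples = _triple_df({"M": [0, 1, 0], "G": [0, 0.5, 1.0]})
        calls = call_agreement(self._net("positive"), triples)
        assert calls[0].call == "indeterminate"

    def test_unmeasured_endpoint_skipped(self):
        triples = _triple_df({"M": [0, 1, 0]})
        assert call_agreement(self._net("positive"), triples) == []

    def test_mode_flip_symmetry(self, rng):
        # negating every correlation and every mode leaves calls unchanged
        for _ in range(50):
            m = rng.normal(size=3)
            g = rng.normal(size=3)
            t_fwd = _triple_df({"M": m, "G": g})
            t_neg = _triple_df({"M": m, "G": -g})
            fwd = call_agreement(self._net("positive"), t_fwd)[0]
            rev = call_agreement(self._net("negative"), t_neg)[0]
            assert fwd.call == rev.call


class TestConsensus:
    def test_single_neighbor_unit_weight(self):
        net = InteractionNetwork(
            [InteractionEdge("TF", "G", "positive", "tf_gene")], {"G"})
        out = consensus_for_unmeasured(net, {"G": ("restored+", 1.0)})
        assert out["TF"]["consensus"] == "restored+"
        assert out["TF"]["confidence"] == pytest.approx(1.0)

    def test_two_neighbors_printed_arithmetic(self):
        # 2 votes x 0.9/(2*2) = 0.45
        net = InteractionNetwork(
            [InteractionEdge("TF", "G1", "positive", "tf_gene"),
             InteractionEdge("TF", "G2", "positive", "tf_gene"),
             InteractionEdge("TF2", "G1", "positive", "tf_gene"),
             InteractionEdge("TF2", "G2", "positive", "tf_gene")],
            {"G1", "G2"})
        out = consensus_for_unmeasured(
            net, {"G1": ("restored+", 0.9), "G2": ("restored+", 0.9)}, n_eps=2)
        assert out["TF"]["confidence"] == pytest.approx(0.45)
        assert out["TF"]["consensus"] == "restored+"

    def test_negative_mode_flips_vote(self):
        net = InteractionNetwork(
            [InteractionEdge("TF", "G", "negative", "tf_gene")], {"G"})
        out = consensus_for_unmeasured(net, {"G": ("restored+", 0.95)})
        assert out["TF"]["consensus"] == "restored-"

    def test_equal_weight_tie_yields_no_consensus(self):
        net = InteractionNetwork(
            [InteractionEdge("TF", "G1", "positive", "tf_gene"),
             InteractionEdge("TF", "G2", "positive", "tf_gene")],
            {"G1", "G2"})
        out = consensus_for_unmeasured(
            net, {"G1": ("restored+", 0.9), "G2": ("novel-", 0.9)})
        assert out["TF"]["consensus"] is None and out["TF"]["reason"] == "tie"

    def test_no_measured_neighbors(self):
        net = InteractionNetwork(
            [InteractionEdge("TF", "G", "positive", "tf_gene")], set())
        out = consensus_for_unmeasured(net, {})
        assert out["TF"]["reason"] == "no_measured_neighbors"
        assert out["G"]["reason"] == "no_measured_neighbors"


class TestActivation:
    def test_unit_case(self):
        table = pd.DataFrame({"endpoint": [1], "entity": ["G"], "corr": [1.0],
                              "category": ["restored+"]})
        act = regulator_activation("TF", table, n_eps=1, n_regulators={"G": 1})
        assert act.confidence == pytest.approx(1.0)
        assert act.consensus == "restored+"

    def test_printed_weight_formula(self):
        assert category_weight(0.9, 3, 2) == pytest.approx(0.15)
        assert category_weight(-0.9, 3, 2) == pytest.approx(0.15)  # abs value

    def test_printed_confidence_sum(self):
        # 4 entities x 2 endpoints, |corr| 0.8, nEPs 2, nRegulators 1 -> 3.2
        rows = [{"endpoint": e, "entity": f"G{k}", "corr": 0.8, "category": "restored+"}
                for e in (1, 2) for k in range(4)]
        act = regulator_activation("TF", pd.DataFrame(rows), n_eps=2,
                                   n_regulators={f"G{k}": 1 for k in range(4)})
        assert act.confidence == pytest.approx(3.2)

    def test_missing_correlations_excluded_and_counted(self):
        rows = [{"endpoint": 1, "entity": "G0", "corr": 0.5, "category": "novel+"},
                {"endpoint": 1, "entity": "G1", "corr": np.nan, "category": "novel+"}]
        act = regulator_activation("TF", pd.DataFrame(rows), n_eps=1,
                                   n_regulators={"G0": 1, "G1": 1})
        assert act.n_missing == 1
        assert act.confidence == pytest.approx(0.5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            category_weight(0.5, 0, 1)

    def test_confidence_bounded_by_entity_count(self, rng):
        # per-entity sum over endpoints of 1/nEPs is 1; |corr|/nRegulators <= 1
        for _ in range(50):
            n_eps = int(rng.integers(1, 5))
            n_entities = int(rng.integers(1, 8))
            rows = [{"endpoint": e, "entity": f"G{k}",
                     "corr": float(rng.uniform(-1, 1)), "category": "restored+"}
                    for e in range(n_eps) for k in range(n_entities)]
            n_regs = {f"G{k}": int(rng.integers(1, 4)) for k in range(n_entities)}
            act = regulator_activation("TF", pd.DataFrame(rows), n_eps=n_eps,
                                       n_regulators=n_regs)
            assert act.confidence <= n_entities + 1e-12


class TestPlantedDriverRecovery:
    def test_driver_tf_ranks_first(self):
        # the TF whose effector drives its regulon attains maximal confidence
        wins = 0
        n_trials = 200
        for trial in range(n_trials):
            net, _ = generate_regulatory_network(4, 24, 4, seed=3000 + trial)
            tfs = sorted({e.entity for e in net.edges if e.kind == "metabolite_tf"})
            driver = tfs[trial % len(tfs)]
            triples = generate_regulon_profiles(
                net, seed=5000 + trial, noise_sd=0.05, driver_tf=driver)
            eff_of = {e.entity: e.regulator for e in net.edges
                      if e.kind == "metabolite_tf"}
            n_regs = {e.entity: net.n_regulators(e.entity)
                      for e in net.edges if e.kind == "tf_gene"}
            confidences = {}
            for tf in tfs:
                # first-stage mode: entities with a single annotated regulator
                rows = []
                for e in net.targets_of(tf):
                    if (e.entity not in triples.index
                            or eff_of[tf] not in triples.index
                            or n_regs[e.entity] != 1):
                        continue
                    from evoprofiler.regulation import pearson_triple
                    rows.append({"endpoint": 1, "entity": e.entity,
                                 "corr": pearson_triple(triples.loc[eff_of[tf]],
                                                        triples.loc[e.entity]),
                                 "category": ""})
                act = regulator_activation(tf, pd.DataFrame(rows), n_eps=1,
                                           n_regulators=n_regs)
                # per-entity mean: "consistently higher correlation"
                confidences[tf] = act.confidence / max(len(rows), 1)
            wins += max(confidences, key=confidences.get) == driver
        assert wins / n_trials >= 0.95
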