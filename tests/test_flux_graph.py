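"""Flux-weighted bipartite graphs, distances, and path-change calls."""

from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from evoprofiler.flux_graph import (
    build_flux_graph,
    classify_path_change,
    classify_scenario,
    distance_level_correlation,
    metabolite_distance,
)
from evoprofiler.synthetic import (
    FLUX_SCENARIOS,
    PROBE_PAIR,
    FluxState,
    generate_flux_states,
)
from evoprofiler.toy_model import Metabolite, Reaction, ToyMetabolicModel


def chain_model(n_mets=3):
    """Linear chain A -R1-> B -R2-> C ... with no carriers."""
    names = [chr(ord("A") + i) for i in range(n_mets)]
    mets = {m: Metabolite(m, 3, "intermediate") for m in names}
    rxns = {}
    for i in range(n_mets - 1):
        rid = f"R{i+1}"
        rxns[rid] = Reaction(rid, {names[i]: -1, names[i + 1]: 1}, True, "chain")
    return ToyMetabolicModel(mets, rxns), names


def brute_force_shortest(graph, source, target):
    """Oracle: enumerate all simple paths, pick minimum total weight."""
    best = None
    for path in nx.all_simple_paths(graph, source, target):
        w = sum(graph[u][v]["weight"] for u, v in zip(path, path[1:]))
        if best is None or w < best[0] - 1e-12:
            best = (w, path)
    return best


class TestBuildGraph:
    def test_linear_chain_edges_and_weights(self):
        model, names = chain_model(3)
        g = build_flux_graph(model, {"R1": 1.0, "R2": 1.0})
        assert g.number_of_edges() == 4
        assert all(d["weight"] == 1.0 for _, _, d in g.edges(data=True))
        assert set(g.nodes) == {"A", "B", "C", "R1", "R2"}

    def test_negative_flux_reverses_orientation(self):
        model, names = chain_model(2)
        g = build_flux_graph(model, {"R1": -2.0})
        assert g.has_edge("B", "R1") and g.has_edge("R1", "A")
        assert g["B"]["R1"]["weight"] == pytest.approx(0.5)

    def test_negative_flux_on_irreversible_rejected(self, toy_model):
        with pytest.raises(ValueError):
            build_flux_graph(toy_model, {"HEX1": -1.0})

    def test_zero_flux_reactions_absent(self):
        model, _ = chain_model(3)
        g = build_flux_graph(model, {"R1": 1.0, "R2": 0.0})
        assert "R2" not in g

    def test_excluded_metabolite_never_a_node(self):
        model, _ = chain_model(3)
        g = build_flux_graph(model, {"R1": 1.0, "R2": 1.0}, exclusions={"B"})
        assert "B" not in g

    def test_currency_and_carbon_free_excluded_by_default(self, toy_model):
        states, _ = generate_flux_states(toy_model, "baseline", seed=1)
        g = build_flux_graph(toy_model, states["ref"])
        for bad in ("atp", "adp", "nadh", "co2", "pi", "h2o"):
            assert bad not in g

    def test_bipartite_structure(self, toy_model):
        states, _ = generate_flux_states(toy_model, "reroute", seed=2)
        g = build_flux_graph(toy_model, states["eko"])
        for u, v in g.edges:
            assert g.nodes[u]["bipartite"] != g.nodes[v]["bipartite"]

    def test_empty_graph_warns(self):
        model, _ = chain_model(3)
        with pytest.warns(UserWarning):
            build_flux_graph(model, {"R1": 0.0, "R2": 0.0})


class TestDistance:
    def test_one_reaction_apart_distance_zero(self):
        model, _ = chain_model(2)
        g = build_flux_graph(model, {"R1": 1.0})
        res = metabolite_distance(g, "A", "B")
        assert res.distance == 0 and res.reactions == ("R1",)

    def test_two_reactions_apart_distance_one(self):
        model, _ = chain_model(3)
        g = build_flux_graph(model, {"R1": 1.0, "R2": 1.0})
        res = metabolite_distance(g, "A", "C")
        assert res.distance == 1 and res.reactions == ("R1", "R2")

    def test_self_pair_flagged_zero(self):
        model, _ = chain_model(2)
        g = build_flux_graph(model, {"R1": 1.0})
        res = metabolite_distance(g, "A", "A")
        assert res.distance == 0 and res.self_pair

    def test_unreachable_is_no_path_result(self):
        model, _ = chain_model(3)
        g = build_flux_graph(model, {"R1": 1.0, "R2": 1.0})
        res = metabolite_distance(g, "C", "A")  # all flux is forward
        assert not res.reachable and res.distance is None

    def test_unknown_node_raises(self):
        model, _ = chain_model(2)
        g = build_flux_graph(model, {"R1": 1.0})
        with pytest.raises(KeyError):
            metabolite_distance(g, "A", "Z")

    def test_agrees_with_exhaustive_enumeration(self, toy_model, rng):
        # <= 8-metabolite random subgraphs of the toy model, oracle-checked
        states, _ = generate_flux_states(toy_model, "reroute", seed=5)
        for strain in ("ref", "uko", "eko"):
            g = build_flux_graph(toy_model, states[strain])
            mets = sorted(n for n, d in g.nodes(data=True)
                          if d["bipartite"] == "metabolite")[:8]
            for s, t in product(mets, mets):
                if s == t:
                    continue
                mine = metabolite_distance(g, s, t)
                oracle = brute_force_shortest(g, s, t)
                if oracle is None:
                    assert not mine.reachable
                else:
                    assert mine.weighted_length == pytest.approx(oracle[0])
                    assert mine.distance == (len(oracle[1]) - 1) // 2 - 1

    def test_bipartite_parity_makes_distance_integral(self, toy_model):
        states, _ = generate_flux_states(toy_model, "capacity_shift", seed=6)
        g = build_flux_graph(toy_model, states["uko"])
        mets = [n for n, d in g.nodes(data=True) if d["bipartite"] == "metabolite"]
        for s in mets:
            for t in mets:
                if s == t:
                    continue
                res = metabolite_distance(g, s, t)
                if res.reachable:
                    assert len(res.reactions) * 2 == 2 * (res.distance + 1)

    def test_global_flux_scaling_invariance(self, toy_model):
        states, _ = generate_flux_states(toy_model, "reroute", seed=7)
        for strain in ("ref", "uko", "eko"):
            means = states[strain].means()
            g1 = build_flux_graph(toy_model, means)
            g2 = build_flux_graph(toy_model, {k: 17.0 * v for k, v in means.items()})
            for s, t in [PROBE_PAIR, ("f6p", "pyr"), ("6pgc", "pyr")]:
                if s not in g1 or t not in g1:
                    continue
                a = metabolite_distance(g1, s, t)
                b = metabolite_distance(g2, s, t)
                assert a.reactions == b.reactions
                assert a.distance == b.distance


class TestPathChange:
    def _p(self, reactions, distance, source="A", target="B"):
        from evoprofiler.flux_graph import PathResult
        return PathResult(source, target, tuple(reactions), distance, 1.0)

    def test_identical_everywhere_unaffected(self):
        p = self._p(["R1", "R2"], 1)
        assert classify_path_change(p, p, p).call == "unaffected"

    def test_uko_eko_change_is_distribution(self):
        ref = self._p(["R1", "R2"], 1)
        uko = self._p(["R3"], 0)
        eko = self._p(["R4", "R5"], 1)
        assert classify_path_change(ref, uko, eko).call == "changed_distribution"

    def test_ref_uko_change_only_is_capacity(self):
        ref = self._p(["R1", "R2"], 1)
        uko = self._p(["R3"], 0)
        assert classify_path_change(ref, uko, uko).call == "changed_capacity"

    def test_mismatched_pairs_rejected(self):
        a = self._p(["R1"], 0, "A", "B")
        b = self._p(["R1"], 0, "A", "C")
        with pytest.raises(ValueError):
            classify_path_change(a, a, b)

    @pytest.mark.parametrize("scenario", sorted(FLUX_SCENARIOS))
    def test_planted_scenarios_recovered(self, toy_model, scenario):
        for seed in range(10):
            states, truth = generate_flux_states(toy_model, scenario, seed=100 + seed)
            call = classify_scenario(toy_model, states, *PROBE_PAIR)
            assert call.call == truth

    def test_missing_strain_rejected(self, toy_model):
        states, _ = generate_flux_states(toy_model, "baseline", seed=1)
        del states["uko"]
        with pytest.raises(ValueError):
            classify_scenario(toy_model, states, *PROBE_PAIR)


class TestDistanceLevelCorrelation:
    def _pairs(self, distances, levels):
        return pd.DataFrame({
            "category_a": "intermediate", "category_b": "carrier",
            "distance": distances, "level": levels})

    def test_perfect_monotone(self):
        res = distance_level_correlation(self._pairs([1, 2, 3, 4], [10, 20, 30, 40]))
        assert res.iloc[0]["rho"] == pytest.approx(1.0)

    def test_reversed_monotone(self):
        res = distance_level_correlation(self._pairs([1, 2, 3, 4], [40, 30, 20, 10]))
        assert res.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_null_inputs_rarely_significant(self, rng):
        hits = 0
        n_trials = 200
        for _ in range(n_trials):
            res = distance_level_correlation(
                self._pairs(rng.normal(size=12), rng.normal(size=12)))
            hits += res.iloc[0]["p"] < 0.05
        assert hits / n_trials <= 0.10

    def test_constant_ranks_flagged(self):
        res = distance_level_correlation(self._pairs([2, 2, 2, 2], [1, 2, 3, 4]))
        assert res.iloc[0]["flag"] == "constant_ranks"
        assert np.isnan(res.iloc[0]["rho"])

    def test_small_groups_skipped(self):
        res = distance_level_correlation(self._pairs([1, 2, 3], [1, 2, 3]))
        assert res.empty
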