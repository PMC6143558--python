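"""Flux-weighted metabolic graphs and pathway-change classification.

For each strain, the metabolic model and its flux state are turned into a
directed bipartite graph: metabolite nodes connect to the reactions that
consume them and reactions connect to the metabolites they produce, with
every edge weighted by the inverse absolute mean flux of its reaction.
High-flux routes are therefore short, and the minimum-weight path between
two metabolites is the dominant flux-bearing route.  Reversible reactions
carrying negative flux are oriented along the flux sign; zero-flux
reactions are absent; carbon-free species and currency metabolites
(carriers) are excluded so paths cannot shortcut through ATP or NADH pools.

Path length is summarized as distance = (#edges)/2 - 1, the number of
intervening metabolites (bipartite parity makes the edge count even, so
the distance is always an integer).  Comparing the per-strain shortest
paths of a metabolite pair across (ref, uko, eko) yields one of three
calls: ``changed_distribution`` (the route itself changed between uko and
eko), ``changed_capacity`` (the uko route changed from ref but eko kept
it, at whatever magnitude), or ``unaffected``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import FluxState
from .toy_model import ToyMetabolicModel

__all__ = [
    "build_flux_graph",
    "default_exclusions",
    "PathResult",
    "PathChangeCall",
    "metabolite_distance",
    "classify_path_change",
    "classify_scenario",
    "distance_level_correlation",
]

_ZERO_TOL = 1e-12


def default_exclusions(model: ToyMetabolicModel) -> set[str]:
    """Currency metabolites excluded from flux graphs by default.

    The carrier category (ATP/ADP/AMP, NAD(P)(H), CoA, quinone pools, CO2)
    plus every carbon-free species.
    """
    return set(model.metabolites_by_category("carrier")) | model.carbon_free()


def build_flux_graph(
    model: ToyMetabolicModel,
    flux_state: FluxState | Mapping[str, float],
    exclusions: Iterable[str] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> nx.DiGraph:
    """Directed bipartite metabolite-reaction graph with 1/|flux| weights.

    ``exclusions`` extends (not replaces) the default currency list; pass
    an explicit empty set via ``exclusions=()`` together with a model with
    no carriers to disable.  ``alias_map`` renames metabolites on the fly
    (for model-specific substitutions).  Boundary reactions never enter
    the graph.
    """
    means = flux_state.means() if isinstance(flux_state, FluxState) else dict(flux_state)
    excluded = default_exclusions(model) | set(exclusions or ())
    alias = dict(alias_map or {})
    g = nx.DiGraph()
    n_active = 0
    for rid, mean in means.items():
        rxn = model.reactions[rid]
        if rxn.boundary or abs(mean) <= _ZERO_TOL:
            continue
        if mean < 0 and not rxn.reversible:
            raise ValueError(f"irreversible reaction {rid} carries negative flux")
        weight = 1.0 / abs(mean)
        # orient along the flux sign
        subs = rxn.substrates() if mean > 0 else rxn.products()
        prods = rxn.products() if mean > 0 else rxn.substrates()
        subs = [alias.get(m, m) for m in subs if alias.get(m, m) not in excluded]
        prods = [alias.get(m, m) for m in prods if alias.get(m, m) not in excluded]
        if not subs and not prods:
            continue
        g.add_node(rid, bipartite="reaction", flux=mean)
        n_active += 1
        for m in subs:
            g.add_node(m, bipartite="metabolite")
            g.add_edge(m, rid, weight=weight)
        for m in prods:
            g.add_node(m, bipartite="metabolite")
            g.add_edge(rid, m, weight=weight)
    if n_active == 0:
        import warnings
        warnings.warn("all fluxes are zero: flux graph is empty", stacklevel=2)
    return g


@dataclass(frozen=True)
class PathResult:
    """Shortest flux-bearing route between two metabolites in one strain."""

    source: str
    target: str
    reactions: tuple[str, ...] | None  # None when unreachable
    distance: int | None               # (#edges)/2 - 1; None when unreachable
    weighted_length: float | None
    self_pair: bool = False

    @property
    def reachable(self) -> bool:
        return self.reactions is not None


def metabolite_distance(graph: nx.DiGraph, source: str, target: str) -> PathResult:
    """Minimum-total-weight path between two metabolite nodes.

    Uses an A* search with a null (admissible) heuristic, i.e. uniform-cost
    search.  The distance is (#edges)/2 - 1 = the number of intervening
    metabolites; a self-pair reports 0 with a flag; an unreachable target
    is a no-path result rather than an exception.
    """
    for node in (source, target):
        if node not in graph:
            raise KeyError(f"metabolite {node!r} not in graph")
    if source == target:
        return PathResult(source, target, (), 0, 0.0, self_pair=True)
    try:
        nodes = nx.astar_path(graph, source, target, heuristic=None, weight="weight")
    except nx.NetworkXNoPath:
        return PathResult(source, target, None, None, None)
    reactions = tuple(n for n in nodes
                      if graph.nodes[n].get("bipartite") == "reaction")
    n_edges = len(nodes) - 1
    weighted = float(sum(graph[u][v]["weight"] for u, v in zip(nodes, nodes[1:])))
    return PathResult(source, target, reactions, n_edges // 2 - 1, weighted)


@dataclass(frozen=True)
class PathChangeCall:
    source: str
    target: str
    call: str  # changed_distribution | changed_capacity | unaffected
    paths: Mapping[str, PathResult]


def _changed(a: PathResult, b: PathResult, compare_sets: bool = False) -> bool:
    """Route change: different reaction sequence OR different distance."""
    if a.reachable != b.reachable:
        return True
    if not a.reachable:
        return False
    ra = set(a.reactions) if compare_sets else a.reactions
    rb = set(b.reactions) if compare_sets else b.reactions
    return ra != rb or a.distance != b.distance


def classify_path_change(
    ref: PathResult,
    uko: PathResult,
    eko: PathResult,
    compare_sets: bool = False,
) -> PathChangeCall:
    """Classify one metabolite pair's route change across the strain triple.

    A route change between uko and eko is a changed flux distribution; a
    change between ref and uko that eko retains is a changed flux
    capacity; no change anywhere is unaffected.
    """
    if not (ref.source == uko.source == eko.source
            and ref.target == uko.target == eko.target):
        raise ValueError("per-strain paths must describe the same metabolite pair")
    if _changed(uko, eko, compare_sets):
        call = "changed_distribution"
    elif _changed(ref, uko, compare_sets):
        call = "changed_capacity"
    else:
        call = "unaffected"
    return PathChangeCall(ref.source, ref.target, call,
                          {"ref": ref, "uko": uko, "eko": eko})


def classify_scenario(
    model: ToyMetabolicModel,
    states: Mapping[str, FluxState],
    source: str,
    target: str,
    exclusions: Iterable[str] | None = None,
) -> PathChangeCall:
    """Build the three strain graphs and classify one metabolite pair."""
    missing = {"ref", "uko", "eko"} - set(states)
    if missing:
        raise ValueError(f"missing strains: {sorted(missing)}")
    paths = {}
    for strain in ("ref", "uko", "eko"):
        g = build_flux_graph(model, states[strain], exclusions)
        paths[strain] = metabolite_distance(g, source, target)
    return classify_path_change(paths["ref"], paths["uko"], paths["eko"])


def distance_level_correlation(
    pairs: pd.DataFrame,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of graph distance vs metabolite level by category pair.

    ``pairs`` has one row per metabolite pair with columns ``category_a``,
    ``category_b``, ``distance``, and ``level``.  Returns rho and p per
    (category_a, category_b) combination with >= ``min_pairs`` rows;
    constant ranks are flagged as undefined (NaN).
    """
    required = {"category_a", "category_b", "distance", "level"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    rows = []
    for (ca, cb), grp in pairs.groupby(["category_a", "category_b"], sort=True):
        if len(grp) < min_pairs:
            continue
        d = grp["distance"].to_numpy(float)
        lv = grp["level"].to_numpy(float)
        if np.ptp(d) == 0 or np.ptp(lv) == 0:
            rows.append((ca, cb, len(grp), np.nan, np.nan, "constant_ranks"))
            continue
        rho, p = stats.spearmanr(d, lv)
        rows.append((ca, cb, len(grp), float(rho), float(p), ""))
    return pd.DataFrame(
        rows, columns=["category_a", "category_b", "n", "rho", "p", "flag"])
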