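"""Regulatory-network consistency scoring.

A signed Boolean interaction network (TF -> gene, metabolite -> TF,
metabolite -> reaction, gene -> reaction, sRNA -> gene edges, each with a
positive or negative mode) is compared against measured component
trajectory profiles.  For each edge with both endpoints measured, the
Pearson correlation between the two components' (ref, uko, eko) mean
triples is compared to the edge mode: r > 0.88 on a positive edge (or
r < -0.88 on a negative edge) is an agreement; the inverse sign pattern is
a disagreement; |r| <= 0.88 is indeterminate.

Unmeasured nodes receive a consensus trajectory category voted by their
measured neighbors, each vote carrying weight |r| / (nEPs * nRegulators);
regulator activation is scored the same way, summed over endpoints and
regulated entities into a confidence score bounded by the number of
regulated entities.  The category weight and the regulator-activation
weight are the same kernel (:func:`category_weight`) applied at two levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import DEFAULT_THRESHOLD, opposite_template

__all__ = [
    "EDGE_KINDS",
    "InteractionEdge",
    "InteractionNetwork",
    "AgreementCall",
    "RegulatorActivation",
    "build_interaction_network",
    "mode_for_reaction_role",
    "call_agreement",
    "pearson_triple",
    "agreement_summary",
    "consensus_for_unmeasured",
    "category_weight",
    "regulator_activation",
]

EDGE_KINDS = ("tf_gene", "metabolite_tf", "metabolite_reaction", "gene_reaction",
              "srna_gene")
_MODES = ("positive", "negative")

TIE_TOL = 1e-12


@dataclass(frozen=True)
class InteractionEdge:
    regulator: str
    entity: str
    mode: str          # positive | negative
    kind: str          # one of EDGE_KINDS


@dataclass
class InteractionNetwork:
    edges: list[InteractionEdge]
    measured: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        out = set()
        for e in self.edges:
            out.add(e.regulator)
            out.add(e.entity)
        return out

    def regulators_of(self, entity: str, kinds: Iterable[str] | None = None) -> list[InteractionEdge]:
        kinds = set(kinds) if kinds is not None else None
        return [e for e in self.edges
                if e.entity == entity and (kinds is None or e.kind in kinds)]

    def targets_of(self, regulator: str) -> list[InteractionEdge]:
        return [e for e in self.edges if e.regulator == regulator]

    def n_regulators(self, entity: str) -> int:
        return len({e.regulator for e in self.edges if e.entity == entity})

    def to_records(self) -> list[dict]:
        return [vars(e) | {} for e in self.edges]


def mode_for_reaction_role(role: str) -> str:
    """Edge-mode convention for metabolism: reactant->reaction is positive,
    product->reaction negative (activating/stabilizing = positive)."""
    if role == "reactant":
        return "positive"
    if role == "product":
        return "negative"
    raise ValueError(f"unknown reaction role {role!r}")


def build_interaction_network(
    edges: Iterable[InteractionEdge | Mapping | Sequence],
    measured: Iterable[str] = (),
) -> InteractionNetwork:
    """Validate edge records into an :class:`InteractionNetwork`.

    Rejects unknown modes/kinds and duplicate (regulator, entity, kind)
    triples.
    """
    parsed: list[InteractionEdge] = []
    seen: set[tuple[str, str, str]] = set()
    for rec in edges:
        if isinstance(rec, InteractionEdge):
            e = rec
        elif isinstance(rec, Mapping):
            e = InteractionEdge(rec["regulator"], rec["entity"], rec["mode"], rec["kind"])
        else:
            e = InteractionEdge(*rec)
        if e.mode not in _MODES:
            raise ValueError(f"unknown mode {e.mode!r} on edge {e.regulator}->{e.entity}")
        if e.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {e.kind!r}")
        key = (e.regulator, e.entity, e.kind)
        if key in seen:
            raise ValueError(f"duplicate edge {key}")
        seen.add(key)
        parsed.append(e)
    return InteractionNetwork(parsed, set(measured))


@dataclass(frozen=True)
class AgreementCall:
    edge: InteractionEdge
    r: float
    call: str  # agreement | disagreement | indeterminate


def pearson_triple(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)))


def call_agreement(
    network: InteractionNetwork,
    triples: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[AgreementCall]:
    """Score every edge whose two endpoints are both measured.

    ``triples`` holds one (ref, uko, eko) mean triple per measured node
    (index = node id).  Edges with an unmeasured endpoint are skipped;
    degenerate triples yield indeterminate calls (r = NaN).
    """
    calls = []
    for e in network.edges:
        if e.regulator not in triples.index or e.entity not in triples.index:
            continue
        r = pearson_triple(triples.loc[e.regulator], triples.loc[e.entity])
        if np.isnan(r) or abs(r) <= threshold:
            call = "indeterminate"
        elif (r > threshold) == (e.mode == "positive"):
            call = "agreement"
        else:
            call = "disagreement"
        calls.append(AgreementCall(e, r, call))
    return calls


def agreement_summary(calls: Sequence[AgreementCall]) -> dict[str, float]:
    """Percentages of agreement / disagreement / indeterminate calls."""
    n = len(calls)
    out = {"n_edges_called": n}
    for kind in ("agreement", "disagreement", "indeterminate"):
        out[f"{kind}_pct"] = (
            100.0 * sum(c.call == kind for c in calls) / n if n else float("nan"))
    return out


def category_weight(corr: float, n_eps: int, n_regulators: int) -> float:
    """The shared scoring kernel: |corr| / (nEPs * nRegulators)."""
    if n_eps < 1 or n_regulators < 1:
        raise ValueError("nEPs and nRegulators must be >= 1")
    return abs(corr) / (n_eps * n_regulators)


def consensus_for_unmeasured(
    network: InteractionNetwork,
    assignments: Mapping[str, tuple[str, float]],
    n_eps: int = 1,
) -> dict[str, dict]:
    """Vote a consensus trajectory category for each unmeasured node.

    ``assignments`` maps measured node id -> (signed profile name, r) from
    profile classification.  Each measured neighbor of an unmeasured node
    votes its profile — flipped through a negative edge mode — with weight
    |r| / (nEPs * nRegulators(neighbor)).  The consensus is the category
    with the maximal summed weight (its sum is the confidence); exact ties
    yield no consensus.  Nodes with no measured neighbor get no call.
    """
    out: dict[str, dict] = {}
    unmeasured = network.nodes - network.measured
    for node in sorted(unmeasured):
        votes: dict[str, float] = {}
        n_votes = 0
        for e in network.edges:
            if e.regulator == node:
                neighbor = e.entity
            elif e.entity == node:
                neighbor = e.regulator
            else:
                continue
            if neighbor not in assignments:
                continue
            profile, r = assignments[neighbor]
            if profile in ("unassigned", "not_tested") or np.isnan(r):
                continue
            if e.mode == "negative":
                profile = opposite_template(profile).signed_name
            w = category_weight(r, n_eps, network.n_regulators(neighbor) or 1)
            votes[profile] = votes.get(profile, 0.0) + w
            n_votes += 1
        if not votes:
            out[node] = {"consensus": None, "confidence": 0.0, "n_votes": 0,
                         "reason": "no_measured_neighbors"}
            continue
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and abs(ranked[0][1] - ranked[1][1]) <= TIE_TOL:
            out[node] = {"consensus": None, "confidence": ranked[0][1],
                         "n_votes": n_votes, "reason": "tie"}
        else:
            out[node] = {"consensus": ranked[0][0], "confidence": ranked[0][1],
                         "n_votes": n_votes, "reason": ""}
    return out


@dataclass
class RegulatorActivation:
    """Consensus activation category and confidence for one regulator."""

    regulator: str
    lineage: str
    weights: pd.DataFrame       # columns: endpoint, entity, category, weight
    consensus: str | None
    confidence: float           # sum of all weights, bounded by #entities
    n_missing: int = 0


def regulator_activation(
    regulator: str,
    corr_table: pd.DataFrame,
    n_eps: int,
    n_regulators: Mapping[str, int],
    lineage: str = "",
) -> RegulatorActivation:
    """Score one regulator's activation over its regulated entities.

    ``corr_table`` has one row per (endpoint, entity) with columns
    ``endpoint``, ``entity``, ``corr`` (the profile correlation of the
    entity in that endpoint) and ``category`` (the entity's mode-adjusted
    signed profile).  Rows with missing correlations are excluded and
    counted.  weight = |corr| / (nEPs * nRegulators(entity)); confidence is
    the sum of all weights, which cannot exceed the number of entities.
    """
    rows = []
    n_missing = 0
    for rec in corr_table.itertuples(index=False):
        corr = getattr(rec, "corr")
        if corr is None or (isinstance(corr, float) and np.isnan(corr)):
            n_missing += 1
            continue
        w = category_weight(corr, n_eps, n_regulators[rec.entity])
        rows.append((rec.endpoint, rec.entity, getattr(rec, "category", ""), w))
    weights = pd.DataFrame(rows, columns=["endpoint", "entity", "category", "weight"])
    confidence = float(weights["weight"].sum())
    consensus = None
    if not weights.empty:
        by_cat = weights.groupby("category")["weight"].sum().sort_values(ascending=False)
        if len(by_cat) == 1 or by_cat.iloc[0] - by_cat.iloc[1] > TIE_TOL:
            consensus = by_cat.index[0]
    return RegulatorActivation(regulator, lineage, weights, consensus, confidence,
                               n_missing)
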