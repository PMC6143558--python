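#!/usr/bin/env python
"""Score regulatory-network consistency against measured profiles.

Loads the signed network and regulon triples from 01, scores composite
effector -> gene relations (TF activity itself is unmeasured) for
agreement/disagreement at |r| > 0.88, votes consensus activation
categories for the unmeasured TF nodes, and ranks regulators by their
activation confidence score.

Writes agreement, consensus, and activation tables under
<outdir>/06_regulation.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from evoprofiler import regulation as rg
from evoprofiler.profiles import classify_component


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--threshold", type=float, default=0.88)
    args = ap.parse_args()
    datadir = args.outdir / "data"
    outdir = args.outdir / "06_regulation"
    outdir.mkdir(parents=True, exist_ok=True)

    records = json.loads((datadir / "regulatory_network.json").read_text())
    network = rg.build_interaction_network(records)
    triples = pd.read_csv(datadir / "regulon_triples.tsv", sep="\t", index_col=0)
    network.measured = set(triples.index)

    eff_of = {e.entity: (e.regulator, e.mode) for e in network.edges
              if e.kind == "metabolite_tf"}
    composite = []
    for e in network.edges:
        if e.kind != "tf_gene" or e.regulator not in eff_of:
            continue
        eff, eff_mode = eff_of[e.regulator]
        mode = "positive" if eff_mode == e.mode else "negative"
        composite.append(rg.InteractionEdge(eff, e.entity, mode, "metabolite_tf"))
    calls = rg.call_agreement(rg.InteractionNetwork(composite, network.measured),
                              triples, args.threshold)
    summary = rg.agreement_summary(calls)
    pd.DataFrame(
        [(c.edge.regulator, c.edge.entity, c.edge.mode, c.r, c.call) for c in calls],
        columns=["effector", "gene", "mode", "r", "call"],
    ).to_csv(outdir / "agreement.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"{summary['n_edges_called']} effector->gene relations scored: "
          f"{summary['agreement_pct']:.1f}% agree, "
          f"{summary['disagreement_pct']:.1f}% disagree "
          f"(planted dual-regulator conflicts), "
          f"{summary['indeterminate_pct']:.1f}% indeterminate")

    assignments = {
        node: (a.profile, a.r)
        for node in triples.index
        for a in [classify_component(triples.loc[node].to_numpy(), component=node)]}
    consensus = rg.consensus_for_unmeasured(network, assignments)
    cons_df = pd.DataFrame([{"node": n, **v} for n, v in sorted(consensus.items())])
    cons_df.to_csv(outdir / "tf_consensus.tsv", sep="\t", index=False,
                   float_format="%.6g")
    called = cons_df[cons_df["consensus"].notna()]
    print(f"consensus activation voted for {len(called)}/{len(cons_df)} "
          f"unmeasured nodes")

    n_regs = {e.entity: network.n_regulators(e.entity)
              for e in network.edges if e.kind == "tf_gene"}
    activations = []
    for tf, (eff, _mode) in sorted(eff_of.items()):
        rows = [{"endpoint": 1, "entity": e.entity,
                 "corr": rg.pearson_triple(triples.loc[eff], triples.loc[e.entity]),
                 "category": classify_component(
                     triples.loc[e.entity].to_numpy()).profile}
                for e in network.targets_of(tf) if e.entity in triples.index]
        act = rg.regulator_activation(tf, pd.DataFrame(rows), n_eps=1,
                                      n_regulators=n_regs)
        activations.append({"regulator": tf, "consensus": act.consensus,
                            "confidence": act.confidence, "n_targets": len(rows)})
    act_df = pd.DataFrame(activations).sort_values(
        "confidence", ascending=False, ignore_index=True)
    act_df.to_csv(outdir / "regulator_activation.tsv", sep="\t", index=False,
                  float_format="%.6g")
    top = act_df.iloc[0]
    print(f"highest-confidence regulator: {top['regulator']} "
          f"(confidence {top['confidence']:.2f}, consensus {top['consensus']})")
    print(f"wrote tables under {outdir}")


if __name__ == "__main__":
    main()
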