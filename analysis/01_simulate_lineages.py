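#!/usr/bin/env python
"""Generate the synthetic study inputs: three knockout-lineage multi-omics
datasets with planted trajectory profiles, the toy central-carbon model,
per-scenario strain flux states, and a signed regulatory network.

Writes everything under <outdir>/data and prints what was planted, so the
later scripts can be checked against recorded truth.
"""

import argparse
from pathlib import Path

import numpy as np

from evoprofiler import synthetic as syn
from evoprofiler.toy_model import generate_toy_model

LINEAGES = ("pgi", "gnd", "sdhCB")
SCENARIOS = ("reroute", "capacity_shift", "baseline")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    datadir = args.outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=len(LINEAGES) + 2)]

    model = generate_toy_model()
    model.to_json(datadir / "toy_model.json")
    print(f"toy model: {len(model.reactions)} reactions, "
          f"{len(model.metabolites)} metabolites -> {datadir / 'toy_model.json'}")

    for lineage, lseed, scenario in zip(LINEAGES, sub, SCENARIOS):
        cfg = syn.LineageConfig(lineage_id=lineage, n_replicates=6)
        ds = syn.generate_lineage_dataset(cfg, lseed)
        ds.write_tsv(datadir)
        planted = (ds.truth["template"] != "none").mean()
        print(f"{lineage}: {len(ds.metadata)} samples, "
              f"{sum(len(m) for m in ds.matrices.values())} components, "
              f"{100 * planted:.1f}% planted with a profile")

        states, truth = syn.generate_flux_states(model, scenario, lseed)
        for strain, st in states.items():
            st.to_frame().to_csv(datadir / f"{lineage}_flux_{strain}.tsv",
                                 sep="\t", index=False, float_format="%.10g")
        print(f"  flux scenario {scenario!r} planted (truth: {truth})")

    net, net_truth = syn.generate_regulatory_network(5, 40, 5, sub[-2])
    triples = syn.generate_regulon_profiles(net, sub[-2], noise_sd=0.02)
    import json
    (datadir / "regulatory_network.json").write_text(
        json.dumps(net.to_records(), indent=1))
    net_truth.to_csv(datadir / "regulatory_network_truth.tsv", sep="\t", index=False)
    triples.to_csv(datadir / "regulon_triples.tsv", sep="\t",
                   index_label="node", float_format="%.10g")
    print(f"regulatory network: {len(net.edges)} signed edges over "
          f"{len(net.nodes)} nodes; measured triples for {len(triples)} nodes")


if __name__ == "__main__":
    main()
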