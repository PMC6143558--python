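"""End-to-end orchestration: generate -> screen -> classify -> trend ->
flux graph -> regulation -> enrichment, with a machine-readable report.

A run is a pure function of its :class:`RunConfig` (which must carry a
seed): rerunning the same config writes byte-identical outputs.  Every
stage's outputs are persisted as TSV/JSON next to a ``report.json`` that
summarizes per-stage counts against the planted ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import flux_graph as fg
from . import multivariate as mv
from . import omics_stats as om
from . import profiles as pr
from . import regulation as rg
from . import set_analysis as sa
from . import synthetic as syn
from .toy_model import generate_toy_model

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_inputs",
           "screen_dataset", "trend_dataset"]

_SCENARIO_CYCLE = ("reroute", "capacity_shift", "baseline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully serializable settings for one reproducible run."""

    seed: int | None = None
    outdir: str = "results/run"
    lineages: Sequence[str] = ("pgi", "gnd", "sdhCB")
    n_endpoints: int = 3
    # 6 samples per strain = triplicate cultures in analytical duplicate;
    # also the minimal size at which an exact permutation test can undercut
    # the 0.01 flux gate (p floor 2/924 at 6v6 vs 2/20 at 3v3)
    n_replicates: int = 6
    noise_sd: float = 0.05
    n_components: Mapping[str, int] = field(
        default_factory=lambda: {"metabolite": 60, "transcript": 120, "flux": 40})
    profile_threshold: float = pr.DEFAULT_THRESHOLD
    trend_threshold: float = mv.TREND_THRESHOLD
    enrichment_p: float = sa.ENRICHMENT_P
    n_tfs: int = 5
    n_genes: int = 40
    n_effectors: int = 5
    regulon_noise_sd: float = 0.02
    classify_all: bool = False

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("RunConfig.seed is required; refusing an unseeded run")
        for name, value in (("profile_threshold", self.profile_threshold),
                            ("trend_threshold", self.trend_threshold),
                            ("enrichment_p", self.enrichment_p)):
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["lineages"] = list(self.lineages)
        payload["n_components"] = dict(self.n_components)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _sub_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def screen_dataset(
    dataset: syn.LineageDataset,
    seed: int,
    thresholds: om.DifferentialThresholds | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Differential screens over every strain comparison of one lineage.

    Runs ref-vs-uko plus uko-vs-eko and ref-vs-eko per endpoint for each
    datatype; returns the full results table and the per-datatype sets of
    components significant in any comparison.
    """
    tables = []
    significant: dict[str, set[str]] = {}
    for datatype in dataset.datatypes:
        mat = dataset.matrices[datatype]
        sig: set[str] = set()
        comparisons = [("ref_vs_uko", dataset.samples_for("ref"),
                        dataset.samples_for("uko"))]
        for e in dataset.endpoints:
            comparisons.append((f"uko_vs_eko{e}", dataset.samples_for("uko"),
                                dataset.samples_for("eko", e)))
            comparisons.append((f"ref_vs_eko{e}", dataset.samples_for("ref"),
                                dataset.samples_for("eko", e)))
        for name, ga, gb in comparisons:
            res = om.differential_features(mat, ga, gb, datatype,
                                           thresholds=thresholds,
                                           comparison=name, seed=seed)
            res.insert(0, "lineage", dataset.lineage_id)
            tables.append(res)
            sig |= set(res.loc[res["significant"], "component"])
        significant[datatype] = sig
    return pd.concat(tables, ignore_index=True), significant


def trend_dataset(
    dataset: syn.LineageDataset,
    seed: int,
    threshold: float = mv.TREND_THRESHOLD,
) -> pd.DataFrame:
    """PLS-DA per datatype + the axis-1 relative-distance rule per endpoint."""
    rows = []
    for datatype in dataset.datatypes:
        X = dataset.matrices[datatype].T
        labels = [s if s != "eko" else f"eko{e}"
                  for s, e in zip(dataset.metadata["strain"],
                                  dataset.metadata["endpoint"])]
        model = mv.fit_plsda(X, labels, n_components=2, seed=seed)
        for e in dataset.endpoints:
            tr = mv.relative_distance(
                model, dataset.samples_for("ref"), dataset.samples_for("uko"),
                dataset.samples_for("eko", e), dataset.lineage_id, e, threshold)
            rows.append({"lineage": dataset.lineage_id, "datatype": datatype,
                         "endpoint": e, "relative_distance": tr.relative_distance,
                         "matches_trend": tr.matches_trend, "q2": model.q2})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"seed": config.seed, "config": asdict(config), "stages": {}}
    report["config"]["lineages"] = list(config.lineages)
    report["config"]["n_components"] = dict(config.n_components)

    seeds = _sub_seeds(config.seed, 4)
    model = generate_toy_model()

    # ------------------------------------------------------------- simulate
    stage = "simulate"
    try:
        model.to_json(outdir / "toy_model.json")
        lineage_seeds = _sub_seeds(seeds[0], len(config.lineages))
        datasets: dict[str, syn.LineageDataset] = {}
        for lineage, lseed in zip(config.lineages, lineage_seeds):
            cfg = syn.LineageConfig(
                lineage_id=lineage, n_components=dict(config.n_components),
                noise_sd=config.noise_sd, n_endpoints=config.n_endpoints,
                n_replicates=config.n_replicates)
            ds = syn.generate_lineage_dataset(cfg, lseed)
            ds.write_tsv(outdir / "data")
            datasets[lineage] = ds
        report["stages"][stage] = {
            "lineages": list(config.lineages),
            "n_samples": {k: int(len(d.metadata)) for k, d in datasets.items()},
        }
    except Exception as exc:  # noqa: BLE001 - abort with the stage name
        raise PipelineError(stage, str(exc)) from exc

    # --------------------------------------------------------------- screen
    stage = "screen"
    try:
        screen_tables = []
        screens: dict[str, dict[str, set[str]]] = {}
        for lineage, ds in datasets.items():
            table, sig = screen_dataset(ds, config.seed)
            screen_tables.append(table)
            screens[lineage] = sig
        screen_df = pd.concat(screen_tables, ignore_index=True)
        screen_df.to_csv(outdir / "differential.tsv", sep="\t", index=False,
                         float_format="%.6g")
        report["stages"][stage] = {
            lineage: {dt: len(s) for dt, s in by_dt.items()}
            for lineage, by_dt in screens.items()}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------------- classify
    stage = "classify"
    try:
        all_assign = []
        truth_acc = {"match": 0, "total": 0}
        for lineage, ds in datasets.items():
            assign = pr.classify_dataset(
                ds, config.profile_threshold,
                screen=None if config.classify_all else screens[lineage])
            all_assign.append(assign)
            truth = ds.truth.set_index(["component", "datatype", "endpoint"])["template"]
            tested = assign[~assign["profile"].isin(["not_tested"])]
            planted = tested.join(
                truth, on=["component", "datatype", "endpoint"])
            planted = planted[planted["template"] != "none"]
            truth_acc["match"] += int((planted["profile"] == planted["template"]).sum())
            truth_acc["total"] += int(len(planted))
        assignments = pd.concat(all_assign, ignore_index=True)
        assignments.to_csv(outdir / "profile_assignments.tsv", sep="\t", index=False,
                           float_format="%.6g")
        dist = pr.profile_distribution(assignments)
        dist.to_csv(outdir / "profile_distribution.tsv", sep="\t", index=False,
                    float_format="%.6g")
        recovery = (100.0 * truth_acc["match"] / truth_acc["total"]
                    if truth_acc["total"] else float("nan"))
        report["stages"][stage] = {
            "n_assignments": int(len(assignments)),
            "planted_recovery_pct": round(recovery, 3),
            "n_planted_tested": truth_acc["total"],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---------------------------------------------------------------- trend
    stage = "trend"
    try:
        trend_df = pd.concat(
            [trend_dataset(ds, config.seed, config.trend_threshold)
             for ds in datasets.values()], ignore_index=True)
        trend_df.to_csv(outdir / "trend.tsv", sep="\t", index=False, float_format="%.6g")
        report["stages"][stage] = {
            "n_endpoints_tested": int(len(trend_df)),
            "trend_match_pct": round(100.0 * trend_df["matches_trend"].mean(), 3),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------------ fluxgraph
    stage = "fluxgraph"
    try:
        flux_rows = []
        n_correct = 0
        scen_seeds = _sub_seeds(seeds[1], len(config.lineages))
        for i, lineage in enumerate(config.lineages):
            scenario = _SCENARIO_CYCLE[i % len(_SCENARIO_CYCLE)]
            states, truth_label = syn.generate_flux_states(model, scenario, scen_seeds[i])
            for strain, st in states.items():
                st.to_frame().to_csv(outdir / "data" / f"{lineage}_flux_{strain}.tsv",
                                     sep="\t", index=False, float_format="%.10g")
            call = fg.classify_scenario(model, states, *syn.PROBE_PAIR)
            n_correct += int(call.call == truth_label)
            flux_rows.append({
                "lineage": lineage, "scenario": scenario,
                "source": call.source, "target": call.target,
                "call": call.call, "truth": truth_label,
                **{f"{s}_distance": call.paths[s].distance for s in ("ref", "uko", "eko")},
            })
        flux_df = pd.DataFrame(flux_rows)
        flux_df.to_csv(outdir / "flux_calls.tsv", sep="\t", index=False)
        counts = flux_df["call"].value_counts()
        report["stages"][stage] = {
            "call_accuracy_pct": round(100.0 * n_correct / len(flux_df), 3),
            "call_pct": {k: round(100.0 * v / len(flux_df), 3)
                         for k, v in sorted(counts.items())},
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------------- regulate
    stage = "regulate"
    try:
        network, _net_truth = syn.generate_regulatory_network(
            config.n_tfs, config.n_genes, config.n_effectors, seeds[2])
        triples = syn.generate_regulon_profiles(
            network, seeds[2], noise_sd=config.regulon_noise_sd)
        # TF activity is not measured: score composite effector -> gene edges
        # (mode = product of metabolite->TF and TF->gene modes)
        eff_of = {e.entity: (e.regulator, e.mode) for e in network.edges
                  if e.kind == "metabolite_tf"}
        composite = []
        for e in network.edges:
            if e.kind != "tf_gene" or e.regulator not in eff_of:
                continue
            eff, eff_mode = eff_of[e.regulator]
            mode = "positive" if (eff_mode == e.mode) else "negative"
            composite.append(rg.InteractionEdge(eff, e.entity, mode, "metabolite_tf"))
        calls = rg.call_agreement(
            rg.InteractionNetwork(composite, network.measured),
            triples, config.profile_threshold)
        summary = rg.agreement_summary(calls)
        entity_regs = {c.edge.entity: network.n_regulators(c.edge.entity)
                       for c in calls}

        # consensus activation category for the unmeasured TF nodes
        node_assign = {
            node: (a.profile, a.r)
            for node in triples.index
            for a in [pr.classify_component(triples.loc[node].to_numpy(), component=node)]
        }
        consensus = rg.consensus_for_unmeasured(network, node_assign, n_eps=1)
        pd.DataFrame(
            [{"node": n, **v} for n, v in sorted(consensus.items())]
        ).to_csv(outdir / "tf_consensus.tsv", sep="\t", index=False,
                 float_format="%.6g")
        pd.DataFrame(
            [(c.edge.regulator, c.edge.entity, c.edge.mode, c.edge.kind, c.r, c.call,
              entity_regs[c.edge.entity])
             for c in calls],
            columns=["regulator", "entity", "mode", "kind", "r", "call", "n_regulators"],
        ).to_csv(outdir / "agreement.tsv", sep="\t", index=False, float_format="%.6g")

        # per-TF activation confidence from mode-adjusted target correlations
        activations = []
        n_regs = {e.entity: network.n_regulators(e.entity)
                  for e in network.edges if e.kind == "tf_gene"}
        for tf in sorted({e.entity for e in network.edges if e.kind == "metabolite_tf"}):
            rows = []
            for e in network.targets_of(tf):
                if e.entity not in triples.index:
                    continue
                eff = next((x.regulator for x in network.regulators_of(
                    tf, kinds=("metabolite_tf",))), None)
                if eff is None or eff not in triples.index:
                    continue
                r = rg.pearson_triple(triples.loc[eff], triples.loc[e.entity])
                assign = pr.classify_component(triples.loc[e.entity].to_numpy())
                rows.append({"endpoint": 1, "entity": e.entity,
                             "corr": r, "category": assign.profile})
            if not rows:
                continue
            act = rg.regulator_activation(
                tf, pd.DataFrame(rows), n_eps=1, n_regulators=n_regs)
            activations.append({
                "regulator": tf, "consensus": act.consensus,
                "confidence": act.confidence, "n_entities": len(rows)})
        act_df = pd.DataFrame(activations).sort_values(
            "confidence", ascending=False, ignore_index=True)
        act_df.to_csv(outdir / "regulator_activation.tsv", sep="\t", index=False,
                      float_format="%.6g")
        report["stages"][stage] = {
            **{k: (round(v, 3) if isinstance(v, float) else v) for k, v in summary.items()},
            "top_regulator": act_df.iloc[0]["regulator"] if len(act_df) else None,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --------------------------------------------------------------- enrich
    stage = "enrich"
    try:
        enrich_rows = []
        for lineage, ds in datasets.items():
            anno = ds.annotations
            for datatype in ds.datatypes:
                universe = list(ds.matrices[datatype].index)
                selected = sorted(screens[lineage][datatype])
                if not selected:
                    continue
                sets = {
                    name: grp["component"].tolist()
                    for name, grp in anno[anno["datatype"] == datatype].groupby("set_name")}
                for res in sa.hypergeom_enrichment(
                        selected, universe, sets, config.enrichment_p):
                    enrich_rows.append({
                        "lineage": lineage, "datatype": datatype,
                        "set_name": res.set_name, "N": res.universe_size,
                        "K": res.annotated, "n": res.selected, "k": res.overlap,
                        "p": res.p, "enriched": res.enriched})
        enrich_df = pd.DataFrame(enrich_rows)
        enrich_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                         float_format="%.6g")
        n_enriched = int(enrich_df["enriched"].sum()) if len(enrich_df) else 0
        perturbed = enrich_df[enrich_df["enriched"]]["set_name"].str.contains(
            "perturbed").mean() if n_enriched else float("nan")
        report["stages"][stage] = {
            "n_sets_tested": int(len(enrich_df)),
            "n_enriched": n_enriched,
            "enriched_perturbed_fraction": (
                round(float(perturbed), 3) if n_enriched else None),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def validate_inputs(paths: Mapping[str, str | Path]) -> dict:
    """Schema/consistency checks for external TSV/JSON/GMT inputs.

    ``paths`` may contain ``omics`` (TSV matrix), ``meta`` (sample
    metadata TSV), ``model`` (model JSON), ``flux`` (flux-state TSV), and
    ``sets`` (GMT).  Returns {"ok": bool, "errors": [...]}.
    """
    errors: list[str] = []
    omics = meta = model = None
    if "omics" in paths:
        omics = pd.read_csv(paths["omics"], sep="\t", index_col=0)
        if omics.empty:
            errors.append("omics matrix is empty")
    if "meta" in paths:
        meta = pd.read_csv(paths["meta"], sep="\t")
        required = {"sample_id", "strain"}
        missing_cols = required - set(meta.columns)
        if missing_cols:
            errors.append(f"metadata missing columns: {sorted(missing_cols)}")
    if omics is not None and meta is not None and "sample_id" in meta.columns:
        mat_samples = set(omics.columns)
        meta_samples = set(meta["sample_id"])
        for missing in sorted(mat_samples - meta_samples):
            errors.append(f"sample {missing!r} present in omics but absent from metadata")
        for missing in sorted(meta_samples - mat_samples):
            errors.append(f"sample {missing!r} present in metadata but absent from omics")
    if "model" in paths:
        from .toy_model import ToyMetabolicModel
        try:
            model = ToyMetabolicModel.from_json(paths["model"])
        except Exception as exc:  # noqa: BLE001
            errors.append(f"model JSON invalid: {exc}")
    if "flux" in paths:
        flux = pd.read_csv(paths["flux"], sep="\t")
        if "reaction" not in flux.columns:
            errors.append("flux table missing 'reaction' column")
        elif model is not None:
            for rid in flux["reaction"]:
                if rid not in model.reactions:
                    errors.append(f"flux table references unknown reaction {rid!r}")
    if "sets" in paths:
        try:
            sa.read_gmt(paths["sets"])
        except Exception as exc:  # noqa: BLE001
            errors.append(f"GMT invalid: {exc}")
    return {"ok": not errors, "errors": errors}
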