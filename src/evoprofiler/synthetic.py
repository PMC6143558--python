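"""Synthetic multi-omics lineages, flux states, and regulatory networks.

Everything downstream of the wet lab is emulated here with recorded ground
truth: triplet-structured omics matrices (reference strain, unevolved
knockout, evolved knockout endpoints, in replicate) with planted trajectory
templates, strain-specific steady-state flux states on the toy
central-carbon model (baseline / rerouted / capacity-shifted scenarios),
and signed regulator-effector-target networks with planted activation.

All generators are pure functions of (config, seed): the same inputs
regenerate bit-identical outputs.  Seeds are mandatory — there is no
implicit nondeterminism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import TEMPLATES, ProfileTemplate, opposite_template
from .regulation import InteractionEdge, InteractionNetwork, build_interaction_network
from .toy_model import ToyMetabolicModel, generate_toy_model

__all__ = [
    "LineageConfig",
    "LineageDataset",
    "FluxState",
    "DEFAULT_TEMPLATE_MIX",
    "generate_lineage_dataset",
    "generate_flux_states",
    "generate_regulatory_network",
    "generate_regulon_profiles",
    "FLUX_SCENARIOS",
]

_BY_SIGNED = {t.signed_name: t for t in TEMPLATES}

#: Default planted template mixture: restored-dominant among perturbed
#: components, with half of all components left flat ("none"), matching the
#: ~25-30% per-comparison significant fractions seen in knockout lineages.
DEFAULT_TEMPLATE_MIX: dict[str, float] = {
    "restored+": 0.09, "restored-": 0.09,
    "partially_restored+": 0.04, "partially_restored-": 0.04,
    "unrestored+": 0.04, "unrestored-": 0.04,
    "novel+": 0.03, "novel-": 0.03,
    "overcompensation+": 0.025, "overcompensation-": 0.025,
    "reinforced+": 0.025, "reinforced-": 0.025,
    "none": 0.50,
}

_DEFAULT_N_COMPONENTS = {"metabolite": 60, "transcript": 120, "flux": 40}

#: Mixture planting only reverting shapes (eKO moves back toward ref), the
#: condition under which the axis-1 relative-distance trend rule is expected
#: to fire: restored returns fully, partially restored halfway,
#: overcompensation overshoots past the reference.
MODE1_TEMPLATE_MIX: dict[str, float] = {
    "restored+": 0.35, "restored-": 0.35,
    "partially_restored+": 0.10, "partially_restored-": 0.10,
    "overcompensation+": 0.05, "overcompensation-": 0.05,
}

#: Synthetic set annotation scheme: planted components concentrate in the
#: "perturbed" sets, flat components in the "housekeeping" sets.
_N_PERTURBED_SETS = 3
_N_HOUSEKEEPING_SETS = 3
_SET_BIAS = 0.9


@dataclass(frozen=True)
class LineageConfig:
    """Generator settings for one knockout lineage."""

    lineage_id: str = "pgi"
    n_components: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_N_COMPONENTS))
    template_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_MIX))
    noise_sd: float = 0.05          # on the unit-range template scale
    n_endpoints: int = 3
    n_replicates: int = 3
    lognormal_noise: bool = False   # multiplicative noise for concentration-like data
    growth_ref: float = 0.90        # h^-1
    growth_uko: float = 0.35
    growth_eko: float = 0.85
    growth_sd: float = 0.005

    def validate(self) -> None:
        total = sum(self.template_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"template mixture proportions sum to {total}, expected 1")
        unknown = set(self.template_mix) - set(_BY_SIGNED) - {"none"}
        if unknown:
            raise ValueError(f"unknown template names in mixture: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per strain")
        if self.n_endpoints < 1:
            raise ValueError("need >= 1 evolved endpoint")


@dataclass
class LineageDataset:
    """All omics matrices, growth rates, metadata, and truth for one lineage."""

    lineage_id: str
    seed: int
    config: LineageConfig
    matrices: dict[str, pd.DataFrame]       # datatype -> components x samples
    metadata: pd.DataFrame                  # sample_id, strain, endpoint, replicate
    growth: pd.Series                       # per-sample growth rate (h^-1)
    truth: pd.DataFrame                     # component, datatype, endpoint, template
    annotations: pd.DataFrame               # component, datatype, set_name

    @property
    def datatypes(self) -> list[str]:
        return list(self.matrices)

    @property
    def endpoints(self) -> list[int]:
        eps = self.metadata.loc[self.metadata["strain"] == "eko", "endpoint"]
        return sorted(int(e) for e in eps.unique())

    def samples_for(self, strain: str, endpoint: int | None = None) -> list[str]:
        meta = self.metadata
        mask = meta["strain"] == strain
        if strain == "eko":
            if endpoint is None:
                raise ValueError("endpoint required for eko samples")
            mask &= meta["endpoint"] == endpoint
        return meta.loc[mask, "sample_id"].tolist()

    def strain_of(self, sample_id: str) -> str:
        return self.metadata.set_index("sample_id").loc[sample_id, "strain"]

    def triples(self, datatype: str, endpoint: int) -> pd.DataFrame:
        """Per-strain replicate means: components x (ref, uko, eko)."""
        mat = self.matrices[datatype]
        return pd.DataFrame({
            "ref": mat[self.samples_for("ref")].mean(axis=1),
            "uko": mat[self.samples_for("uko")].mean(axis=1),
            "eko": mat[self.samples_for("eko", endpoint)].mean(axis=1),
        })

    def growth_triple(self, endpoint: int) -> tuple[float, float, float]:
        g = self.growth
        return (
            float(g[self.samples_for("ref")].mean()),
            float(g[self.samples_for("uko")].mean()),
            float(g[self.samples_for("eko", endpoint)].mean()),
        )

    def write_tsv(self, outdir: str | Path) -> None:
        import json
        from dataclasses import asdict

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for datatype, mat in self.matrices.items():
            mat.to_csv(outdir / f"{self.lineage_id}_{datatype}.tsv",
                       sep="\t", index_label="component", float_format="%.10g")
        self.metadata.to_csv(outdir / f"{self.lineage_id}_samples.tsv", sep="\t", index=False)
        self.growth.rename("growth_rate").to_csv(
            outdir / f"{self.lineage_id}_growth.tsv", sep="\t", index_label="sample_id",
            float_format="%.10g")
        self.truth.to_csv(outdir / f"{self.lineage_id}_truth.tsv", sep="\t", index=False)
        self.annotations.to_csv(outdir / f"{self.lineage_id}_sets.tsv", sep="\t", index=False)
        payload = asdict(self.config)
        payload["n_components"] = dict(self.config.n_components)
        payload["template_mix"] = dict(self.config.template_mix)
        (outdir / f"{self.lineage_id}_config.json").write_text(
            json.dumps({"seed": self.seed, "config": payload}, indent=1, sort_keys=True))

    @classmethod
    def read_tsv(cls, outdir: str | Path, lineage_id: str) -> "LineageDataset":
        """Load a dataset previously persisted by :meth:`write_tsv`."""
        import json

        outdir = Path(outdir)
        payload = json.loads((outdir / f"{lineage_id}_config.json").read_text())
        config = LineageConfig(**payload["config"])
        matrices = {
            dt: pd.read_csv(outdir / f"{lineage_id}_{dt}.tsv", sep="\t", index_col=0)
            for dt in config.n_components
            if (outdir / f"{lineage_id}_{dt}.tsv").exists()
        }
        metadata = pd.read_csv(outdir / f"{lineage_id}_samples.tsv", sep="\t")
        growth = pd.read_csv(outdir / f"{lineage_id}_growth.tsv", sep="\t",
                             index_col=0)["growth_rate"]
        truth = pd.read_csv(outdir / f"{lineage_id}_truth.tsv", sep="\t")
        annotations = pd.read_csv(outdir / f"{lineage_id}_sets.tsv", sep="\t")
        return cls(lineage_id, payload["seed"], config, matrices, metadata,
                   growth, truth, annotations)


def _unit_encoding(template: ProfileTemplate) -> np.ndarray:
    enc = np.asarray(template.encoding, dtype=float)
    return (enc - enc.min()) / np.ptp(enc)


def generate_lineage_dataset(config: LineageConfig, seed: int) -> LineageDataset:
    """Generate one triplet-structured lineage with planted profile truth.

    Each planted component's strain mean follows an affine transform
    ``a * encoding_unit + b`` (a > 0 per component, encoding scaled to unit
    range) with Gaussian noise of sd ``config.noise_sd`` planted on the
    template scale (so the stated sd means the same signal-to-noise for
    every component; Pearson matching is affine invariant).  Components
    drawn as "none" sit at a flat baseline plus noise.
    """
    if seed is None:
        raise ValueError("a seed is required; implicit nondeterminism is refused")
    config.validate()
    rng = np.random.default_rng(seed)

    # sample frame: ref and uko shared across endpoints, eko per endpoint
    rows = []
    for r in range(1, config.n_replicates + 1):
        rows.append((f"ref_r{r}", "ref", 0, r))
    for r in range(1, config.n_replicates + 1):
        rows.append((f"uko_r{r}", "uko", 0, r))
    for e in range(1, config.n_endpoints + 1):
        for r in range(1, config.n_replicates + 1):
            rows.append((f"eko{e}_r{r}", "eko", e, r))
    metadata = pd.DataFrame(rows, columns=["sample_id", "strain", "endpoint", "replicate"])
    sample_ids = metadata["sample_id"].tolist()
    # per-sample index into the (ref, uko, eko) encoding triple
    strain_slot = np.array([0 if s == "ref" else 1 if s == "uko" else 2
                            for s in metadata["strain"]])

    mix_names = list(config.template_mix)
    mix_probs = np.array([config.template_mix[n] for n in mix_names], dtype=float)
    mix_probs = mix_probs / mix_probs.sum()

    matrices: dict[str, pd.DataFrame] = {}
    truth_rows = []
    anno_rows = []
    endpoints = list(range(1, config.n_endpoints + 1))
    for datatype, n_comp in config.n_components.items():
        comps = [f"{datatype[:3]}_{i:04d}" for i in range(1, n_comp + 1)]
        planted = rng.choice(len(mix_names), size=n_comp, p=mix_probs)
        data = np.empty((n_comp, len(sample_ids)))
        for i, comp in enumerate(comps):
            name = mix_names[planted[i]]
            # amplitude >= 2 over baseline <= 1.5 gives planted components
            # >= 2.3-fold strain changes, clearing the 2-fold screens
            a = rng.uniform(2.0, 6.0)
            b = rng.uniform(0.5, 1.5)
            if name == "none":
                base = np.full(3, 0.5)
            else:
                base = _unit_encoding(_BY_SIGNED[name])
            signal = base[strain_slot]
            noise = rng.normal(0.0, config.noise_sd, size=len(sample_ids)) \
                if config.noise_sd > 0 else np.zeros(len(sample_ids))
            if config.lognormal_noise and datatype == "metabolite":
                data[i] = (a * signal + b) * np.exp(noise)
            else:
                data[i] = a * (signal + noise) + b
            for e in endpoints:
                truth_rows.append((comp, datatype, e, name))
            # planted components concentrate in "perturbed" sets
            if name != "none":
                grp = "perturbed" if rng.random() < _SET_BIAS else "housekeeping"
            else:
                grp = "housekeeping" if rng.random() < _SET_BIAS else "perturbed"
            k = _N_PERTURBED_SETS if grp == "perturbed" else _N_HOUSEKEEPING_SETS
            anno_rows.append((comp, datatype, f"{datatype}_{grp}_{rng.integers(1, k + 1)}"))
        matrices[datatype] = pd.DataFrame(data, index=comps, columns=sample_ids)

    growth_base = np.where(
        metadata["strain"] == "ref", config.growth_ref,
        np.where(metadata["strain"] == "uko", config.growth_uko, config.growth_eko))
    growth = pd.Series(
        growth_base + rng.normal(0.0, config.growth_sd, size=len(sample_ids)),
        index=sample_ids, name="growth_rate")

    truth = pd.DataFrame(truth_rows, columns=["component", "datatype", "endpoint", "template"])
    annotations = pd.DataFrame(anno_rows, columns=["component", "datatype", "set_name"])
    return LineageDataset(config.lineage_id, seed, config, matrices, metadata,
                          growth, truth, annotations)


# ---------------------------------------------------------------------------
# Flux states on the toy model
# ---------------------------------------------------------------------------

@dataclass
class FluxState:
    """Per-strain reaction fluxes with 95% confidence bounds."""

    strain: str
    fluxes: dict[str, tuple[float, float, float]]  # rxn -> (mean, lower, upper)

    def means(self) -> dict[str, float]:
        return {r: v[0] for r, v in self.fluxes.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, m, lo, hi) for r, (m, lo, hi) in self.fluxes.items()],
            columns=["reaction", "mean", "lower", "upper"])

    def validate(self, model: ToyMetabolicModel) -> None:
        for rid, (m, lo, hi) in self.fluxes.items():
            rxn = model.reactions[rid]
            if not (lo <= m <= hi):
                raise ValueError(f"{rid}: bounds {lo} <= {m} <= {hi} violated")
            if not rxn.reversible and not rxn.boundary and m < 0:
                raise ValueError(f"irreversible reaction {rid} has negative mean {m}")


# Balanced steady-state flux vectors (glucose uptake 10) for the three
# pathway usages of the probe pair g6p -> pyr.  Each satisfies S.v = 0.
_EMP_STATE = {
    "EX_glc__D": 10, "HEX1": 10, "PGI": 10, "PFK": 10, "FBA": 10, "TPI": 10,
    "GAPD": 20, "PGK": 20, "PGM": 20, "ENO": 20, "PYK": 20, "DM_pyr": 20,
    "ATPM": 20, "NADH16": 20, "CYTBO3": 20, "EX_o2": 10, "EX_h2o": 20,
}
_ED_STATE = {
    "EX_glc__D": 10, "HEX1": 10, "G6PDH2r": 10, "PGL": 10, "EDD": 10, "EDA": 10,
    "GAPD": 10, "PGK": 10, "PGM": 10, "ENO": 10, "PYK": 10, "DM_pyr": 20,
    "NADTRHD": 10, "NADH16": 20, "CYTBO3": 20, "EX_o2": 10, "ATPM": 10, "EX_h2o": 20,
}
_PPP_STATE = {
    "EX_glc__D": 10, "HEX1": 10, "PGI": -20, "G6PDH2r": 30, "PGL": 30, "GND": 30,
    "RPE": 20, "RPI": -10, "TKT1": 10, "TALA": 10, "TKT2": 10,
    "GAPD": 10, "PGK": 10, "PGM": 10, "ENO": 10, "PYK": 10, "DM_pyr": 10,
    "EX_co2": 30, "NADTRHD": 60, "NADH16": 70, "CYTBO3": 70, "EX_o2": 35,
    "ATPM": 10, "EX_h2o": 40,
}

#: scenario -> (per-strain pathway state, per-strain extra scale, truth label)
FLUX_SCENARIOS: dict[str, dict] = {
    "baseline": {
        "states": {"ref": _EMP_STATE, "uko": _EMP_STATE, "eko": _EMP_STATE},
        "scale": {"ref": 1.0, "uko": 1.0, "eko": 1.0},
        "truth": "unaffected",
    },
    "reroute": {
        "states": {"ref": _EMP_STATE, "uko": _ED_STATE, "eko": _PPP_STATE},
        "scale": {"ref": 1.0, "uko": 1.0, "eko": 1.0},
        "truth": "changed_distribution",
    },
    "capacity_shift": {
        "states": {"ref": _EMP_STATE, "uko": _ED_STATE, "eko": _ED_STATE},
        "scale": {"ref": 1.0, "uko": 1.0, "eko": 2.0},
        "truth": "changed_capacity",
    },
}

#: Probe metabolite pair whose shortest flux-bearing path the scenarios rewire.
PROBE_PAIR = ("g6p", "pyr")


def generate_flux_states(
    model: ToyMetabolicModel,
    scenario: str,
    seed: int,
    ci_width: float = 0.1,
) -> tuple[dict[str, FluxState], str]:
    """Generate (ref, uko, eko) steady-state flux states for one scenario.

    Scenarios: ``baseline`` (identical pathway usage), ``reroute`` (uko and
    eko each carry flux on different paths than ref and each other), and
    ``capacity_shift`` (eko keeps the uko path at scaled magnitude).  A
    seeded global scale factor per strain jitters magnitudes without
    breaking mass balance.  Returns the states plus the ground-truth
    path-change label.
    """
    if scenario not in FLUX_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"expected one of {sorted(FLUX_SCENARIOS)}")
    if seed is None:
        raise ValueError("a seed is required")
    spec = FLUX_SCENARIOS[scenario]
    rng = np.random.default_rng(seed)
    states: dict[str, FluxState] = {}
    for strain in ("ref", "uko", "eko"):
        scale = spec["scale"][strain] * rng.uniform(0.9, 1.1)
        fluxes = {}
        for rid, v in spec["states"][strain].items():
            mean = float(v) * scale
            half = ci_width * abs(mean)
            fluxes[rid] = (mean, mean - half, mean + half)
        state = FluxState(strain, fluxes)
        state.validate(model)
        states[strain] = state
    return states, spec["truth"]


# ---------------------------------------------------------------------------
# Regulatory networks
# ---------------------------------------------------------------------------

def generate_regulatory_network(
    n_tfs: int,
    n_genes: int,
    n_effectors: int,
    seed: int,
    single_regulator_fraction: float = 0.8,
) -> tuple[InteractionNetwork, pd.DataFrame]:
    """Generate a signed regulator network with planted modes.

    Every TF gets >= 1 metabolite effector edge and >= 1 regulated gene
    edge; a ``single_regulator_fraction`` of genes have exactly one
    annotated regulator, the rest get a second TF of random mode.  Returns
    the network plus an edge-truth table.
    """
    if min(n_tfs, n_genes, n_effectors) < 1:
        raise ValueError("counts must all be >= 1")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    tfs = [f"TF_{i:03d}" for i in range(1, n_tfs + 1)]
    genes = [f"G_{i:04d}" for i in range(1, n_genes + 1)]
    effectors = [f"M_{i:03d}" for i in range(1, n_effectors + 1)]

    records = []
    truth_rows = []
    for i, tf in enumerate(tfs):
        eff = effectors[i % n_effectors]
        mode = "positive" if rng.random() < 0.5 else "negative"
        records.append((eff, tf, mode, "metabolite_tf"))
        truth_rows.append((eff, tf, mode, "metabolite_tf"))
    for j, gene in enumerate(genes):
        tf = tfs[j % n_tfs]
        mode = "positive" if rng.random() < 0.5 else "negative"
        records.append((tf, gene, mode, "tf_gene"))
        truth_rows.append((tf, gene, mode, "tf_gene"))
        if n_tfs > 1 and rng.random() > single_regulator_fraction:
            other = tfs[(j + 1 + int(rng.integers(0, n_tfs - 1))) % n_tfs]
            if other != tf:
                mode2 = "positive" if rng.random() < 0.5 else "negative"
                records.append((other, gene, mode2, "tf_gene"))
                truth_rows.append((other, gene, mode2, "tf_gene"))
    network = build_interaction_network(
        [InteractionEdge(*rec) for rec in records],
        measured=set(effectors) | set(genes),
    )
    truth = pd.DataFrame(truth_rows, columns=["regulator", "entity", "mode", "kind"])
    return network, truth


def generate_regulon_profiles(
    network: InteractionNetwork,
    seed: int,
    noise_sd: float = 0.0,
    template: str = "restored+",
    driver_tf: str | None = None,
) -> pd.DataFrame:
    """Materialize (ref, uko, eko) mean triples consistent with the network.

    Each TF's effector is planted with ``template``; regulated genes follow
    the effector through the signed edge chain (metabolite mode x gene
    mode), so a fully positive chain reproduces the template and a negative
    link flips its direction.  If ``driver_tf`` is given, only that TF's
    regulon tracks its effector — all other genes get independent noise
    triples, making the driver the one consistently explained regulator.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    base = _unit_encoding(_BY_SIGNED[template])
    flipped = _unit_encoding(opposite_template(template))

    eff_mode: dict[str, tuple[str, str]] = {}   # tf -> (effector, mode)
    for e in network.edges:
        if e.kind == "metabolite_tf":
            eff_mode[e.entity] = (e.regulator, e.mode)

    triples: dict[str, np.ndarray] = {}

    def noisy(vec: np.ndarray) -> np.ndarray:
        a = rng.uniform(0.5, 2.0)
        b = rng.uniform(2.0, 5.0)
        eps = rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else 0.0
        return a * (vec + eps) + b

    for tf, (eff, _mode) in eff_mode.items():
        if eff not in triples:
            triples[eff] = noisy(base)
    for e in network.edges:
        if e.kind != "tf_gene" or e.entity in triples:
            continue
        tf = e.regulator
        follows = driver_tf is None or tf == driver_tf
        if not follows:
            triples[e.entity] = noisy(rng.uniform(0.0, 1.0, size=3))
            continue
        chain_sign = 1
        if tf in eff_mode and eff_mode[tf][1] == "negative":
            chain_sign *= -1
        if e.mode == "negative":
            chain_sign *= -1
        triples[e.entity] = noisy(base if chain_sign > 0 else flipped)
    return pd.DataFrame.from_dict(triples, orient="index", columns=["ref", "uko", "eko"])
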