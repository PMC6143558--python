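"""A fixed toy central-carbon metabolic model of *E. coli*.

The model is a ~45-reaction textbook-stoichiometry network covering EMP
glycolysis, the Entner-Doudoroff (ED) pathway, the oxidative and
non-oxidative pentose phosphate pathway, the methylglyoxal bypass, a TCA
segment, a small nucleotide-salvage arm, and the carrier-recycling
reactions (transhydrogenase, NADH dehydrogenase, terminal oxidase, ATP
drain) plus exchange boundaries needed to close steady states.  Full
ATP/ADP and NAD(P)(H) stoichiometry is carried so that pathway yields can
be computed exactly: EMP glycolysis nets 2 ATP and 2 NADH per glucose,
the ED route nets 1 ATP, 1 NADH, and 1 NADPH per glucose.

Every metabolite carries a carbon-atom count (used to drop carbon-free
species from flux graphs) and a category tag used downstream:
``intermediate``, ``carrier``, ``biomass_precursor``, or
``nucleotide_salvage``.  All non-boundary reactions are carbon balanced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Metabolite",
    "Reaction",
    "ToyMetabolicModel",
    "generate_toy_model",
    "pathway_yield",
    "EMP_ROUTE",
    "ED_ROUTE",
    "MODEL_VERSION",
]

MODEL_VERSION = "toy-ccm-1.0"


@dataclass(frozen=True)
class Metabolite:
    id: str
    carbons: int
    category: str  # intermediate | carrier | biomass_precursor | nucleotide_salvage


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]  # metabolite id -> signed coefficient
    reversible: bool
    subsystem: str
    genes: tuple[str, ...] = ()
    boundary: bool = False  # exchange/demand: intentionally mass-unbalanced

    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class ToyMetabolicModel:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    version: str = MODEL_VERSION

    def __post_init__(self) -> None:
        for rxn in self.reactions.values():
            for met, coeff in rxn.stoichiometry.items():
                if met not in self.metabolites:
                    raise ValueError(f"reaction {rxn.id} references unknown metabolite {met}")
                if coeff == 0:
                    raise ValueError(f"reaction {rxn.id} has zero coefficient for {met}")
            if not rxn.subsystem:
                raise ValueError(f"reaction {rxn.id} has empty subsystem")

    # -- queries -----------------------------------------------------------
    def metabolites_by_category(self, category: str) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.category == category]

    def carbon_free(self) -> set[str]:
        return {m.id for m in self.metabolites.values() if m.carbons == 0}

    def carbon_balance(self, reaction_id: str) -> int:
        rxn = self.reactions[reaction_id]
        return int(sum(c * self.metabolites[m].carbons for m, c in rxn.stoichiometry.items()))

    def mass_balance_residuals(self, fluxes: Mapping[str, float]) -> dict[str, float]:
        """Per-metabolite net production rate under a flux vector (S.v)."""
        resid: dict[str, float] = {m: 0.0 for m in self.metabolites}
        for rid, v in fluxes.items():
            for met, coeff in self.reactions[rid].stoichiometry.items():
                resid[met] += coeff * v
        return resid

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "metabolites": [
                {"id": m.id, "carbons": m.carbons, "category": m.category}
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": dict(r.stoichiometry),
                    "reversible": r.reversible,
                    "subsystem": r.subsystem,
                    "genes": list(r.genes),
                    "boundary": r.boundary,
                }
                for r in self.reactions.values()
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ToyMetabolicModel":
        mets = {m["id"]: Metabolite(m["id"], int(m["carbons"]), m["category"])
                for m in payload["metabolites"]}
        rxns = {
            r["id"]: Reaction(
                r["id"], {k: float(v) for k, v in r["stoichiometry"].items()},
                bool(r["reversible"]), r["subsystem"], tuple(r.get("genes", ())),
                bool(r.get("boundary", False)),
            )
            for r in payload["reactions"]
        }
        return cls(mets, rxns, payload.get("version", MODEL_VERSION))

    @classmethod
    def from_json(cls, path: str | Path) -> "ToyMetabolicModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _met(id: str, carbons: int, category: str = "intermediate") -> Metabolite:
    return Metabolite(id, carbons, category)


_METABOLITES: tuple[Metabolite, ...] = (
    # glycolysis / ED / PPP intermediates (BiGG-style ids)
    _met("glc__D", 6),
    _met("g6p", 6, "biomass_precursor"),
    _met("f6p", 6, "biomass_precursor"),
    _met("fdp", 6),
    _met("dhap", 3),
    _met("g3p", 3, "biomass_precursor"),
    _met("13dpg", 3),
    _met("3pg", 3, "biomass_precursor"),
    _met("2pg", 3),
    _met("pep", 3, "biomass_precursor"),
    _met("pyr", 3, "biomass_precursor"),
    _met("6pgl", 6),
    _met("6pgc", 6),
    _met("2ddg6p", 6),
    _met("ru5p__D", 5),
    _met("r5p", 5, "biomass_precursor"),
    _met("x5p", 5),
    _met("s7p", 7),
    _met("e4p", 4, "biomass_precursor"),
    # methylglyoxal bypass
    _met("mthgxl", 3),
    _met("lac__D", 3),
    # TCA segment + anaplerosis
    _met("accoa", 23, "biomass_precursor"),
    _met("cit", 6),
    _met("icit", 6),
    _met("akg", 5, "biomass_precursor"),
    _met("succoa", 25),
    _met("succ", 4),
    _met("fum", 4),
    _met("mal__L", 4),
    _met("oaa", 4, "biomass_precursor"),
    # nucleotide salvage arm
    _met("ins", 10, "nucleotide_salvage"),
    _met("hxan", 5, "nucleotide_salvage"),
    _met("r1p", 5, "nucleotide_salvage"),
    # carriers / currency
    _met("atp", 10, "carrier"),
    _met("adp", 10, "carrier"),
    _met("amp", 10, "carrier"),
    _met("nad", 21, "carrier"),
    _met("nadh", 21, "carrier"),
    _met("nadp", 21, "carrier"),
    _met("nadph", 21, "carrier"),
    _met("coa", 21, "carrier"),
    _met("q8", 49, "carrier"),
    _met("q8h2", 49, "carrier"),
    _met("co2", 1, "carrier"),
    _met("o2", 0, "carrier"),
    _met("pi", 0, "carrier"),
    _met("h2o", 0, "carrier"),
)


def _rxn(id, stoich, reversible, subsystem, genes=(), boundary=False) -> Reaction:
    return Reaction(id, stoich, reversible, subsystem, tuple(genes), boundary)


_REACTIONS: tuple[Reaction, ...] = (
    # --- upper EMP glycolysis -------------------------------------------------
    _rxn("HEX1", {"glc__D": -1, "atp": -1, "g6p": 1, "adp": 1}, False,
         "Glycolysis/Gluconeogenesis", ("glk",)),
    _rxn("PGI", {"g6p": -1, "f6p": 1}, True, "Glycolysis/Gluconeogenesis", ("pgi",)),
    _rxn("PFK", {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1}, False,
         "Glycolysis/Gluconeogenesis", ("pfkA", "pfkB")),
    _rxn("FBA", {"fdp": -1, "dhap": 1, "g3p": 1}, True,
         "Glycolysis/Gluconeogenesis", ("fbaA", "fbaB")),
    _rxn("TPI", {"dhap": -1, "g3p": 1}, True, "Glycolysis/Gluconeogenesis", ("tpiA",)),
    # --- lower EMP glycolysis -------------------------------------------------
    _rxn("GAPD", {"g3p": -1, "nad": -1, "pi": -1, "13dpg": 1, "nadh": 1}, True,
         "Glycolysis/Gluconeogenesis", ("gapA",)),
    _rxn("PGK", {"13dpg": -1, "adp": -1, "3pg": 1, "atp": 1}, True,
         "Glycolysis/Gluconeogenesis", ("pgk",)),
    _rxn("PGM", {"3pg": -1, "2pg": 1}, True, "Glycolysis/Gluconeogenesis", ("gpmA", "gpmM")),
    _rxn("ENO", {"2pg": -1, "pep": 1, "h2o": 1}, True,
         "Glycolysis/Gluconeogenesis", ("eno",)),
    _rxn("PYK", {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, False,
         "Glycolysis/Gluconeogenesis", ("pykA", "pykF")),
    # --- oxidative PPP ---------------------------------------------------------
    _rxn("G6PDH2r", {"g6p": -1, "nadp": -1, "6pgl": 1, "nadph": 1}, True,
         "Pentose Phosphate Pathway", ("zwf",)),
    _rxn("PGL", {"6pgl": -1, "h2o": -1, "6pgc": 1}, False,
         "Pentose Phosphate Pathway", ("pgl",)),
    _rxn("GND", {"6pgc": -1, "nadp": -1, "ru5p__D": 1, "co2": 1, "nadph": 1}, False,
         "Pentose Phosphate Pathway", ("gnd",)),
    # --- Entner-Doudoroff ------------------------------------------------------
    _rxn("EDD", {"6pgc": -1, "2ddg6p": 1, "h2o": 1}, False,
         "Entner-Doudoroff Pathway", ("edd",)),
    _rxn("EDA", {"2ddg6p": -1, "pyr": 1, "g3p": 1}, False,
         "Entner-Doudoroff Pathway", ("eda",)),
    # --- non-oxidative PPP -----------------------------------------------------
    _rxn("RPE", {"ru5p__D": -1, "x5p": 1}, True, "Pentose Phosphate Pathway", ("rpe",)),
    _rxn("RPI", {"r5p": -1, "ru5p__D": 1}, True, "Pentose Phosphate Pathway", ("rpiA", "rpiB")),
    _rxn("TKT1", {"r5p": -1, "x5p": -1, "g3p": 1, "s7p": 1}, True,
         "Pentose Phosphate Pathway", ("tktA", "tktB")),
    _rxn("TALA", {"g3p": -1, "s7p": -1, "e4p": 1, "f6p": 1}, True,
         "Pentose Phosphate Pathway", ("talA", "talB")),
    _rxn("TKT2", {"e4p": -1, "x5p": -1, "f6p": 1, "g3p": 1}, True,
         "Pentose Phosphate Pathway", ("tktA", "tktB")),
    # --- methylglyoxal bypass --------------------------------------------------
    _rxn("MGSA", {"dhap": -1, "mthgxl": 1, "pi": 1}, False,
         "Methylglyoxal Metabolism", ("mgsA",)),
    _rxn("MGXDH", {"mthgxl": -1, "h2o": -1, "lac__D": 1}, False,
         "Methylglyoxal Metabolism", ("gloA", "gloB")),
    _rxn("LDH_D", {"lac__D": -1, "nad": -1, "pyr": 1, "nadh": 1}, True,
         "Pyruvate Metabolism", ("ldhA",)),
    # --- TCA segment + anaplerosis --------------------------------------------
    _rxn("PDH", {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1}, False,
         "Citric Acid Cycle", ("aceE", "aceF", "lpd")),
    _rxn("CS", {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1}, False,
         "Citric Acid Cycle", ("gltA",)),
    _rxn("ACONT", {"cit": -1, "icit": 1}, True, "Citric Acid Cycle", ("acnA", "acnB")),
    _rxn("ICDHyr", {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1}, True,
         "Citric Acid Cycle", ("icd",)),
    _rxn("AKGDH", {"akg": -1, "coa": -1, "nad": -1, "succoa": 1, "co2": 1, "nadh": 1}, False,
         "Citric Acid Cycle", ("sucA", "sucB", "lpd")),
    _rxn("SUCOAS", {"succoa": -1, "adp": -1, "pi": -1, "succ": 1, "coa": 1, "atp": 1}, True,
         "Citric Acid Cycle", ("sucC", "sucD")),
    _rxn("SUCDi", {"succ": -1, "q8": -1, "fum": 1, "q8h2": 1}, False,
         "Citric Acid Cycle", ("sdhA", "sdhB", "sdhC", "sdhD")),
    _rxn("FUM", {"fum": -1, "h2o": -1, "mal__L": 1}, True,
         "Citric Acid Cycle", ("fumA", "fumB", "fumC")),
    _rxn("MDH", {"mal__L": -1, "nad": -1, "oaa": 1, "nadh": 1}, True,
         "Citric Acid Cycle", ("mdh",)),
    _rxn("PPC", {"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1}, False,
         "Anaplerotic Reactions", ("ppc",)),
    # --- nucleotide salvage arm ------------------------------------------------
    _rxn("PUNP1", {"ins": -1, "pi": -1, "hxan": 1, "r1p": 1}, True,
         "Nucleotide Salvage Pathway", ("deoD",)),
    _rxn("PPM", {"r1p": -1, "r5p": 1}, True, "Nucleotide Salvage Pathway", ("deoB",)),
    # --- carrier recycling -----------------------------------------------------
    _rxn("NADTRHD", {"nadph": -1, "nad": -1, "nadp": 1, "nadh": 1}, False,
         "Oxidative Phosphorylation", ("udhA", "pntA", "pntB")),
    _rxn("NADH16", {"nadh": -1, "q8": -1, "nad": 1, "q8h2": 1}, False,
         "Oxidative Phosphorylation", ("nuo",)),
    _rxn("CYTBO3", {"q8h2": -1, "o2": -0.5, "q8": 1, "h2o": 1}, False,
         "Oxidative Phosphorylation", ("cyo",)),
    _rxn("ATPM", {"atp": -1, "h2o": -1, "adp": 1, "pi": 1}, False,
         "ATP Maintenance", ()),
    # --- exchange / demand boundaries -----------------------------------------
    _rxn("EX_glc__D", {"glc__D": 1}, False, "Exchange", (), boundary=True),
    _rxn("EX_o2", {"o2": 1}, False, "Exchange", (), boundary=True),
    _rxn("EX_co2", {"co2": -1}, False, "Exchange", (), boundary=True),
    _rxn("EX_h2o", {"h2o": -1}, False, "Exchange", (), boundary=True),
    _rxn("DM_pyr", {"pyr": -1}, False, "Demand", (), boundary=True),
    _rxn("DM_r5p", {"r5p": -1}, False, "Demand", (), boundary=True),
    _rxn("DM_akg", {"akg": -1}, False, "Demand", (), boundary=True),
)


def generate_toy_model() -> ToyMetabolicModel:
    """Return the fixed, versioned toy central-carbon model."""
    return ToyMetabolicModel(
        metabolites={m.id: m for m in _METABOLITES},
        reactions={r.id: r for r in _REACTIONS},
        version=MODEL_VERSION,
    )


#: Glucose -> 2 pyruvate via EMP glycolysis, as (reaction id, multiplicity).
EMP_ROUTE: tuple[tuple[str, int], ...] = (
    ("HEX1", 1), ("PGI", 1), ("PFK", 1), ("FBA", 1), ("TPI", 1),
    ("GAPD", 2), ("PGK", 2), ("PGM", 2), ("ENO", 2), ("PYK", 2),
)

#: Glucose -> 2 pyruvate via the ED pathway.
ED_ROUTE: tuple[tuple[str, int], ...] = (
    ("HEX1", 1), ("G6PDH2r", 1), ("PGL", 1), ("EDD", 1), ("EDA", 1),
    ("GAPD", 1), ("PGK", 1), ("PGM", 1), ("ENO", 1), ("PYK", 1),
)


def pathway_yield(
    model: ToyMetabolicModel,
    reaction_path: Iterable[tuple[str, float | Fraction]],
    target: str,
) -> float:
    """Net stoichiometric yield of ``target`` over a weighted reaction path.

    ``reaction_path`` is an ordered sequence of (reaction id, multiplicity)
    pairs; the yield is the multiplicity-weighted sum of the target's signed
    coefficients.  With routes normalized per glucose this gives e.g. the
    net ATP per glucose of a pathway.
    """
    if target not in model.metabolites:
        raise KeyError(f"unknown metabolite {target!r}")
    total = 0.0
    for rid, mult in reaction_path:
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction {rid!r}")
        if not mult > 0:
            raise ValueError(f"multiplicity for {rid} must be positive, got {mult}")
        total += float(mult) * model.reactions[rid].stoichiometry.get(target, 0.0)
    return total
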