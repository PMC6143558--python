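"""Hypergeometric set enrichment and biomass-correlation analysis.

Enrichment of a selected component list against annotated sets (pathway
subsystems, regulons, GMT gene sets) uses the exact upper-tail
hypergeometric test with the raw p < 1e-3 gate (enrichment only, no
depletion; no multiplicity adjustment by default, a Benjamini-Hochberg
option exists).

The biomass-correlation analysis identifies growth-promoting and
growth-inhibiting components: among biomass-pathway components, those
whose (ref, uko, eko) triple correlates with the growth-rate triple above
0.88 (Pearson) are growth promoting, below -0.88 growth inhibiting, and
the result is reported as a percentage of measured biomass components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .omics_stats import adjust_pvalues

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment",
    "biomass_correlation",
    "GROWTH_ASSOCIATED_PROFILES",
    "read_gmt",
    "write_gmt",
]

ENRICHMENT_P = 1e-3

#: Signed profiles whose shape tracks growth recovery (drop at the knockout,
#: restoration during evolution), used to pre-filter biomass components.
GROWTH_ASSOCIATED_PROFILES = frozenset(
    {"restored-", "novel+", "overcompensation-", "partially_restored-", "reinforced+"}
)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    universe_size: int   # N
    annotated: int       # K
    selected: int        # n
    overlap: int         # k
    p: float             # exact upper-tail hypergeometric
    enriched: bool


def hypergeom_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    p_threshold: float = ENRICHMENT_P,
    bh_adjust: bool = False,
) -> list[EnrichmentResult]:
    """Exact upper-tail hypergeometric enrichment per annotated set.

    p = P[X >= k] with X ~ Hypergeom(N, K, n) where N = |universe|,
    K = |set ∩ universe|, n = |selected|, k = |set ∩ selected|.  Raises if
    ``selected`` is not contained in ``universe``.
    """
    universe = set(universe)
    selected = set(selected)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected ids outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(selected)
    results = []
    for name in sorted(sets):
        members = set(sets[name]) & universe
        K = len(members)
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append((name, N, K, n, k, p))
    pvals = [r[5] for r in results]
    gate = adjust_pvalues(pvals, "bh") if bh_adjust and pvals else pvals
    return [
        EnrichmentResult(name, N, K, n, k, p, bool(g < p_threshold))
        for (name, N, K, n, k, p), g in zip(results, gate)
    ]


def _pearson3(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)))


def biomass_correlation(
    triples: pd.DataFrame,
    biomass_components: Iterable[str],
    growth_triple: Sequence[float],
    assignments: Mapping[str, str] | None = None,
    growth_profiles: frozenset[str] = GROWTH_ASSOCIATED_PROFILES,
    r_threshold: float = 0.88,
) -> dict:
    """Growth-promoting / growth-inhibiting biomass components.

    ``triples`` holds per-component (ref, uko, eko) means; the analysis is
    restricted to ``biomass_components`` and, when profile ``assignments``
    are supplied, to components in the growth-associated profile set.  A
    component is growth promoting when Pearson r between its triple and
    the growth triple exceeds ``r_threshold`` and growth inhibiting below
    ``-r_threshold``.  Percentages are over measured biomass components.
    """
    growth = np.asarray(growth_triple, float)
    if np.ptp(growth) == 0:
        raise ValueError("constant growth vector: correlation undefined")
    measured = [c for c in biomass_components if c in triples.index]
    if not measured:
        raise ValueError("no measured biomass components")
    candidates = measured
    if assignments is not None:
        candidates = [c for c in measured if assignments.get(c) in growth_profiles]
    promoting, inhibiting = [], []
    for comp in candidates:
        r = _pearson3(triples.loc[comp], growth)
        if np.isnan(r):
            continue
        if r > r_threshold:
            promoting.append(comp)
        elif r < -r_threshold:
            inhibiting.append(comp)
    n = len(measured)
    return {
        "growth_promoting": promoting,
        "growth_inhibiting": inhibiting,
        "n_measured": n,
        "promoting_pct": 100.0 * len(promoting) / n,
        "inhibiting_pct": 100.0 * len(inhibiting) / n,
    }


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT set annotations (name <tab> description <tab> ids...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = fields[2:]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "evoprofiler") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(ids)
             for name, ids in sorted(sets.items())]
    Path(path).write_text("\n".join(lines) + "\n")
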