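"""Normalization, imputation, and per-datatype differential feature screens.

Significance criteria per datatype (each configurable via
:class:`DifferentialThresholds`):

* metabolite — two-sample t-test on glog-transformed concentrations,
  Bonferroni-adjusted p < 0.01 and |log2 fold-change| > 1;
* transcript — two-sample t-test on log2 levels, Benjamini-Hochberg
  adjusted p < 0.05 and |log2 fold-change| > 1;
* flux — seeded permutation test on mean difference, p < 0.01 and
  |geometric fold-change| > 0.001, with an excluded-subsystem filter;
* mutation — frequency > 0.1 pass-through (no test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialThresholds",
    "glog_transform",
    "impute_missing",
    "rsd",
    "adjust_pvalues",
    "geometric_fold_change",
    "permutation_pvalue",
    "differential_features",
    "DATATYPES",
]

DATATYPES = ("metabolite", "transcript", "flux", "mutation")

#: Flux subsystems excluded from differential flux analysis.
DEFAULT_EXCLUDED_SUBSYSTEMS = frozenset(
    {"Demand", "Exchange", "Nucleotide Salvage Pathway", "Oxidative Phosphorylation",
     "ATP Maintenance"}
)

_EPS = 1e-9


@dataclass(frozen=True)
class DifferentialThresholds:
    """Significance gates for the per-datatype differential screens."""

    metabolite_p: float = 0.01
    metabolite_log2fc: float = 1.0
    transcript_p: float = 0.05
    transcript_log2fc: float = 1.0
    flux_p: float = 0.01          # printed both as 0.01 and 0.05; 0.01 is the default
    flux_gfc: float = 0.001
    mutation_frequency: float = 0.1
    glog_lambda: float = 1.0
    n_permutations: int = 2000
    literal_fc_band: bool = False  # literal "0.5 < FC < 2.0" reading (unchanged band)
    excluded_subsystems: frozenset[str] = DEFAULT_EXCLUDED_SUBSYSTEMS


def glog_transform(value, lam: float = 1.0):
    """Generalized log transform log((y + sqrt(y^2 + lambda)) / 2).

    Strictly increasing; reduces to log(y) at lambda = 0.  Accepts scalars
    or arrays.  Raises on y <= 0 with lambda = 0 (plain log domain error).
    """
    if lam < 0:
        raise ValueError("glog lambda must be >= 0")
    arr = np.asarray(value, dtype=float)
    if lam == 0 and np.any(arr <= 0):
        raise ValueError("glog with lambda=0 requires strictly positive values")
    out = np.log((arr + np.sqrt(arr * arr + lam)) / 2.0)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def impute_missing(
    matrix: pd.DataFrame,
    lloq: Mapping[str, float] | pd.Series,
    biomass_factor: Mapping[str, float] | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing cells with half the per-component LLOQ.

    The fill value for component c in sample s is ``lloq[c] / 2 /
    biomass_factor[s]`` (biomass factor defaults to 1).  Returns the
    completed matrix and a boolean mask of imputed cells.
    """
    lloq = pd.Series(lloq, dtype=float)
    mask = matrix.isna()
    if not mask.to_numpy().any():
        return matrix.copy(), mask
    missing_rows = matrix.index[mask.any(axis=1)]
    unresolvable = [c for c in missing_rows if c not in lloq.index or not lloq[c] > 0]
    if unresolvable:
        raise ValueError(f"missing values without a positive LLOQ: {unresolvable}")
    if biomass_factor is None:
        bf = pd.Series(1.0, index=matrix.columns)
    else:
        bf = pd.Series(biomass_factor, dtype=float).reindex(matrix.columns)
    fill = pd.DataFrame(
        np.outer(lloq.reindex(matrix.index).to_numpy() / 2.0, 1.0 / bf.to_numpy()),
        index=matrix.index, columns=matrix.columns,
    )
    return matrix.where(~mask, fill), mask


def rsd(values: Sequence[float]) -> float:
    """Percent relative standard deviation, 100 * sd / mean (sample sd)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD requires at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mean


def adjust_pvalues(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: 'bonferroni' or 'bh' (Benjamini-Hochberg)."""
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method=key)[1]


def geometric_fold_change(a: Sequence[float], b: Sequence[float]) -> float:
    """Sign-free log10 ratio of geometric means of absolute flux samples.

    gfc = log10((gm(|b|) + eps) / (gm(|a|) + eps)) with eps = 1e-9 guarding
    zero fluxes; negative values mean the flux magnitude dropped in b.
    """
    ga = float(np.exp(np.mean(np.log(np.abs(np.asarray(a, float)) + _EPS))))
    gb = float(np.exp(np.mean(np.log(np.abs(np.asarray(b, float)) + _EPS))))
    return math.log10((gb + _EPS) / (ga + _EPS))


def _ttest(a: np.ndarray, b: np.ndarray) -> float:
    # Zero-variance groups: deterministic p per the documented convention.
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 1e-300
    import warnings

    with warnings.catch_warnings():
        # near-identical groups trigger scipy's catastrophic-cancellation
        # warning; the p-value is still the right deterministic answer
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
    return float(p) if np.isfinite(p) else 1.0


def permutation_pvalue(
    a: Sequence[float],
    b: Sequence[float],
    n_permutations: int = 2000,
    seed: int | None = 0,
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Uses exhaustive label reassignment when the number of distinct splits is
    small (< n_permutations), otherwise ``n_permutations`` seeded random
    splits with the identity included: p = (1 + #as-extreme) / (1 + B).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = a.size
    observed = abs(a.mean() - b.mean())
    n_splits = math.comb(pooled.size, na)
    if n_splits <= n_permutations:
        # exact test: enumerate every label split, vectorized
        idx = np.array(list(combinations(range(pooled.size), na)))
        sums_a = pooled[idx].sum(axis=1)
        means_a = sums_a / na
        means_b = (pooled.sum() - sums_a) / b.size
        count = int(np.sum(np.abs(means_a - means_b) >= observed - 1e-12))
        return count / n_splits
    if seed is None:
        raise ValueError("permutation test requires an explicit seed")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_permutations)


def _log2fc(mean_a: float, mean_b: float) -> float:
    return math.log2((abs(mean_b) + _EPS) / (abs(mean_a) + _EPS))


def differential_features(
    levels: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    datatype: str,
    thresholds: DifferentialThresholds | None = None,
    comparison: str = "a_vs_b",
    subsystems: Mapping[str, str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Differential screen of one comparison for one datatype.

    ``levels`` is a components x samples frame on the measurement scale;
    ``group_a``/``group_b`` are sample (column) labels.  Returns a frame
    with columns (component, datatype, comparison, p, p_adj, fc_stat,
    significant); ``fc_stat`` is log2 FC for metabolites/transcripts and
    the geometric fold-change for fluxes.
    """
    th = thresholds or DifferentialThresholds()
    if datatype not in DATATYPES:
        raise ValueError(f"unknown datatype {datatype!r}")

    if datatype == "mutation":
        freq = levels[list(group_b)].mean(axis=1)
        return pd.DataFrame({
            "component": levels.index,
            "datatype": datatype,
            "comparison": comparison,
            "p": np.nan,
            "p_adj": np.nan,
            "fc_stat": freq.to_numpy(),
            "significant": (freq > th.mutation_frequency).to_numpy(),
        })

    A = levels[list(group_a)].to_numpy(float)
    B = levels[list(group_b)].to_numpy(float)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("test-based datatypes require >= 2 samples per group")

    pvals = np.empty(len(levels))
    fc = np.empty(len(levels))
    if datatype == "metabolite":
        Ag = glog_transform(A, th.glog_lambda)
        Bg = glog_transform(B, th.glog_lambda)
        for i in range(len(levels)):
            pvals[i] = _ttest(Ag[i], Bg[i])
            fc[i] = _log2fc(A[i].mean(), B[i].mean())
        padj = adjust_pvalues(pvals, "bonferroni")
        if th.literal_fc_band:
            ratio = 2.0 ** fc
            fc_pass = (ratio > 0.5) & (ratio < 2.0)
        else:
            fc_pass = np.abs(fc) > th.metabolite_log2fc
        sig = (padj < th.metabolite_p) & fc_pass
    elif datatype == "transcript":
        Al = np.log2(np.abs(A) + _EPS)
        Bl = np.log2(np.abs(B) + _EPS)
        for i in range(len(levels)):
            pvals[i] = _ttest(Al[i], Bl[i])
            fc[i] = _log2fc(A[i].mean(), B[i].mean())
        padj = adjust_pvalues(pvals, "bh")
        sig = (padj < th.transcript_p) & (np.abs(fc) > th.transcript_log2fc)
    else:  # flux
        for i in range(len(levels)):
            pvals[i] = permutation_pvalue(A[i], B[i], th.n_permutations, seed=seed + i)
            fc[i] = geometric_fold_change(A[i], B[i])
        padj = pvals.copy()  # permutation p used directly, no adjustment
        sig = (pvals < th.flux_p) & (np.abs(fc) > th.flux_gfc)
        if subsystems is not None:
            excluded = np.array(
                [subsystems.get(c) in th.excluded_subsystems for c in levels.index]
            )
            sig = sig & ~excluded

    return pd.DataFrame({
        "component": levels.index,
        "datatype": datatype,
        "comparison": comparison,
        "p": pvals,
        "p_adj": padj,
        "fc_stat": fc,
        "significant": sig,
    })
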