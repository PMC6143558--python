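"""Trajectory profile classification for knockout-evolution triples.

Each system component (a metabolite concentration, transcript level, or
reaction flux) is observed in three states of a knockout lineage: the
pre-evolved reference strain (``ref``), the unevolved knockout (``uko``),
and an evolved knockout endpoint (``eko``).  The qualitative shape of the
ordered (ref, uko, eko) triple is matched against six canonical profiles,
each in a positive and negative direction, by Pearson correlation against
fixed integer encodings.  A component is binned into the best-matching
template when r exceeds a cutoff (default 0.88); because the largest
correlation between two distinct templates is sqrt(3)/2 ~ 0.866, every
noiseless template matches itself uniquely at that cutoff.

Profile semantics:

* ``restored``            — perturbed by the KO, returned to reference level.
* ``partially_restored``  — perturbed, partially returned.
* ``overcompensation``    — returned past the reference level.
* ``reinforced``          — perturbed, then moved further in the same direction.
* ``unrestored``          — perturbed and left at the perturbed level.
* ``novel``               — unchanged by the KO, changed only during evolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileTemplate",
    "ProfileAssignment",
    "TEMPLATES",
    "PROFILE_NAMES",
    "DEFAULT_THRESHOLD",
    "template_set",
    "signed_name",
    "opposite_template",
    "classify_component",
    "classify_dataset",
    "profile_distribution",
]

DEFAULT_THRESHOLD = 0.88

#: Unsigned profile shape names, alphabetical.
PROFILE_NAMES = (
    "novel",
    "overcompensation",
    "partially_restored",
    "reinforced",
    "restored",
    "unrestored",
)


@dataclass(frozen=True)
class ProfileTemplate:
    """One signed canonical profile with its (ref, uko, eko) integer encoding."""

    name: str
    direction: str  # "+" or "-"
    encoding: tuple[int, int, int]

    @property
    def signed_name(self) -> str:
        return self.name + self.direction


# Fixed template set; order is the published encoding order.
TEMPLATES: tuple[ProfileTemplate, ...] = (
    ProfileTemplate("novel", "-", (1, 1, 0)),
    ProfileTemplate("novel", "+", (0, 0, 1)),
    ProfileTemplate("overcompensation", "-", (1, 0, 2)),
    ProfileTemplate("overcompensation", "+", (1, 2, 0)),
    ProfileTemplate("partially_restored", "-", (2, 0, 1)),
    ProfileTemplate("partially_restored", "+", (0, 2, 1)),
    ProfileTemplate("reinforced", "-", (2, 1, 0)),
    ProfileTemplate("reinforced", "+", (0, 1, 2)),
    ProfileTemplate("restored", "-", (1, 0, 1)),
    ProfileTemplate("restored", "+", (0, 1, 0)),
    ProfileTemplate("unrestored", "-", (1, 0, 0)),
    ProfileTemplate("unrestored", "+", (0, 1, 1)),
)

_ENCODINGS = np.array([t.encoding for t in TEMPLATES], dtype=float)
# Row-standardize encodings once: correlation is a dot product of z-scores.
_ENC_CENTERED = _ENCODINGS - _ENCODINGS.mean(axis=1, keepdims=True)
_ENC_UNIT = _ENC_CENTERED / np.linalg.norm(_ENC_CENTERED, axis=1, keepdims=True)

_BY_SIGNED_NAME = {t.signed_name: t for t in TEMPLATES}

TIE_TOL = 1e-12


def template_set() -> tuple[ProfileTemplate, ...]:
    """Return the fixed set of 12 signed templates in stable (published) order."""
    return TEMPLATES


def signed_name(name: str, direction: str) -> str:
    return name + direction


def opposite_template(template: ProfileTemplate | str) -> ProfileTemplate:
    """Return the same shape in the opposite direction (T+ <-> T-)."""
    if isinstance(template, str):
        template = _BY_SIGNED_NAME[template]
    flipped = "-" if template.direction == "+" else "+"
    return _BY_SIGNED_NAME[template.name + flipped]


@dataclass(frozen=True)
class ProfileAssignment:
    """Outcome of matching one component triple against the template set."""

    component: str
    profile: str  # signed name, or "unassigned"
    r: float
    reason: str = ""  # "", "below_threshold", "degenerate", "tie"

    @property
    def assigned(self) -> bool:
        return self.profile != "unassigned"


def _correlations(triple: np.ndarray) -> np.ndarray:
    """Pearson r of a centered, finite triple against all 12 encodings."""
    x = triple - triple.mean()
    norm = np.linalg.norm(x)
    return _ENC_UNIT @ (x / norm)


def classify_component(
    triple: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
    component: str = "",
) -> ProfileAssignment:
    """Match one (ref, uko, eko) triple against the 12 signed templates.

    The maximum-correlation template is assigned iff its r strictly exceeds
    ``threshold``.  Zero-variance triples are unassigned ("degenerate"); two
    templates tied within 1e-12 at the maximum are unassigned ("tie").
    """
    arr = np.asarray(triple, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a (ref, uko, eko) triple, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in triple {arr!r}")
    if np.ptp(arr) == 0.0 or np.linalg.norm(arr - arr.mean()) == 0.0:
        return ProfileAssignment(component, "unassigned", np.nan, "degenerate")

    r = _correlations(arr)
    best = int(np.argmax(r))
    r_best = float(r[best])
    if r_best <= threshold:
        return ProfileAssignment(component, "unassigned", r_best, "below_threshold")
    ties = np.flatnonzero(r >= r_best - TIE_TOL)
    if ties.size > 1:
        return ProfileAssignment(component, "unassigned", r_best, "tie")
    return ProfileAssignment(component, TEMPLATES[best].signed_name, r_best)


def classify_dataset(
    dataset,
    threshold: float = DEFAULT_THRESHOLD,
    screen: dict[str, set[str]] | None = None,
    datatypes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Classify every (component, datatype, endpoint) triple of a lineage dataset.

    Parameters
    ----------
    dataset
        Object exposing ``lineage_id``, ``datatypes``, ``endpoints`` and
        ``triples(datatype, endpoint)`` returning a components x
        (ref, uko, eko) frame of per-strain replicate means
        (:class:`evoprofiler.synthetic.LineageDataset` satisfies this).
    screen
        Optional per-datatype sets of component ids that passed the
        differential significance screen.  Components outside the set are
        reported as ``not_tested`` (the screen-first behavior); ``None``
        classifies everything.

    Returns
    -------
    DataFrame with columns
    (component, datatype, lineage, endpoint, profile, r, reason).
    """
    rows = []
    for datatype in datatypes if datatypes is not None else dataset.datatypes:
        allowed = None if screen is None else screen.get(datatype, set())
        for endpoint in dataset.endpoints:
            triples = dataset.triples(datatype, endpoint)
            for component, triple in zip(triples.index, triples.to_numpy()):
                if allowed is not None and component not in allowed:
                    rows.append(
                        (component, datatype, dataset.lineage_id, endpoint,
                         "not_tested", np.nan, "failed_screen")
                    )
                    continue
                a = classify_component(triple, threshold, component)
                rows.append(
                    (component, datatype, dataset.lineage_id, endpoint,
                     a.profile, a.r, a.reason)
                )
    return pd.DataFrame(
        rows,
        columns=["component", "datatype", "lineage", "endpoint", "profile", "r", "reason"],
    )


def profile_distribution(assignments: pd.DataFrame) -> pd.DataFrame:
    """Percentage of tested components falling in each signed profile.

    Grouped by (lineage, datatype, endpoint).  The denominator is the number
    of tested (classified or unassigned) components, so percentages sum to
    at most 100; ``not_tested`` rows are dropped entirely.
    """
    if assignments.empty:
        raise ValueError("no assignments provided")
    tested = assignments[assignments["profile"] != "not_tested"]
    names = [t.signed_name for t in TEMPLATES]
    out = []
    for (lineage, datatype, endpoint), grp in tested.groupby(
        ["lineage", "datatype", "endpoint"], sort=True
    ):
        n = len(grp)
        counts = grp["profile"].value_counts()
        row = {"lineage": lineage, "datatype": datatype, "endpoint": endpoint, "n_tested": n}
        for name in names:
            row[name] = 100.0 * counts.get(name, 0) / n if n else np.nan
        row["unassigned"] = 100.0 * counts.get("unassigned", 0) / n if n else np.nan
        out.append(row)
    return pd.DataFrame(out)
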