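"""Sample-trend analysis: PCA, PLS-DA, and the relative-distance criterion.

Samples of one lineage (reference, unevolved knockout, evolved endpoints)
are projected into a low-dimensional latent space after univariate scaling
and centering.  The first latent axis ("mode 1") captures the
perturbation-and-recovery direction: the knockout moves away from the
reference along it, and evolved endpoints move back.  An endpoint matches
that trend when its relative distance

    relative_distance = |axis1(uko) - axis1(eko)| / |axis1(ref) - axis1(uko)|

exceeds 0.70.  The second axis ("mode 2") captures diversity among evolved
endpoints and is reported but not thresholded.

PLS-DA is standard NIPALS PLS2 against one-hot class indicators
(scikit-learn's PLSRegression), with cross-validated Q2 reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, LeaveOneOut

__all__ = [
    "LatentModel",
    "TrendResult",
    "fit_pca",
    "fit_plsda",
    "relative_distance",
    "select_loading_features",
    "TREND_THRESHOLD",
]

TREND_THRESHOLD = 0.70


@dataclass
class LatentModel:
    """Fitted latent projection with its scaling record."""

    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    explained_variance: np.ndarray
    center: pd.Series
    scale: pd.Series
    method: str
    labels: list | None = None
    q2: float | None = None
    dropped_features: list[str] = field(default_factory=list)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Reproject new samples using the stored scaling record."""
        Z = (X[self.loadings.index] - self.center) / self.scale
        return Z.to_numpy() @ self.loadings.to_numpy()


def _scale_matrix(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Univariate scaling + centering; zero-variance features are dropped."""
    sd = X.std(ddof=1)
    dropped = sd.index[sd == 0].tolist()
    kept = sd.index[sd > 0]
    X = X[kept]
    center = X.mean()
    Z = (X - center) / sd[kept]
    return Z, center, sd[kept], dropped


def _orient_sign(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return scores, loadings


def fit_pca(X: pd.DataFrame, n_components: int = 2) -> LatentModel:
    """SVD PCA on the univariate-scaled, centered sample x feature matrix."""
    if len(X) < 3:
        raise ValueError("PCA requires at least 3 samples")
    Z, center, scale, dropped = _scale_matrix(X)
    n_components = min(n_components, len(X) - 1, Z.shape[1])
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    scores, loadings = _orient_sign(scores, loadings)
    var = (s**2) / (s**2).sum()
    return LatentModel(
        scores=pd.DataFrame(scores, index=X.index,
                            columns=[f"PC{k+1}" for k in range(n_components)]),
        loadings=pd.DataFrame(loadings, index=Z.columns,
                              columns=[f"PC{k+1}" for k in range(n_components)]),
        explained_variance=var[:n_components],
        center=center, scale=scale, method="pca", dropped_features=dropped,
    )


def _one_hot(labels: Sequence) -> tuple[np.ndarray, list]:
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y, classes


def _q2_cv(Z: np.ndarray, Y: np.ndarray, n_components: int, seed: int) -> float:
    """Cross-validated Q2 on the one-hot responses (LOO when n <= 10)."""
    n = len(Z)
    splitter = LeaveOneOut() if n <= 10 else KFold(10, shuffle=True, random_state=seed)
    press, tss = 0.0, float(((Y - Y.mean(axis=0)) ** 2).sum())
    for train, test in splitter.split(Z):
        if len(np.unique(np.argmax(Y[train], axis=1))) < 2:
            continue
        k = min(n_components, len(train) - 1, Z.shape[1])
        try:
            pls = PLSRegression(n_components=k, scale=False)
            with np.errstate(invalid="ignore", divide="ignore"):
                pls.fit(Z[train], Y[train])
            pred = pls.predict(Z[test])
            if not np.all(np.isfinite(pred)):
                raise FloatingPointError("non-finite prediction")
        except Exception:
            # degenerate fold (no X-Y covariance): predict the training mean
            pred = np.tile(Y[train].mean(axis=0), (len(test), 1))
        press += float(((Y[test] - pred) ** 2).sum())
    return 1.0 - press / tss


def fit_plsda(
    X: pd.DataFrame,
    labels: Sequence,
    n_components: int = 2,
    seed: int = 0,
) -> LatentModel:
    """NIPALS PLS2 against one-hot class indicators on scaled, centered X."""
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("PLS-DA requires >= 2 classes")
    counts = {c: labels.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"every class needs >= 2 samples, got {counts}")
    Z, center, scale, dropped = _scale_matrix(X)
    Y, _ = _one_hot(labels)
    n_components = min(n_components, len(X) - 1, Z.shape[1])
    Yc = Y - Y.mean(axis=0)
    if np.linalg.norm(Z.to_numpy().T @ Yc) < 1e-10:
        # classes carry no covariance with X (e.g. identical rows across
        # classes): NIPALS is undefined; fall back to unsupervised axes,
        # which by construction separate nothing
        pca = fit_pca(X, n_components)
        q2 = _q2_cv(Z.to_numpy(), Y, n_components, seed)
        pca.method = "plsda"
        pca.labels = list(labels)
        pca.q2 = q2
        return pca
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Z.to_numpy(), Y)
    scores = pls.x_scores_.copy()
    # rotations satisfy scores = Z @ rotations, so transform() reprojects exactly
    loadings = pls.x_rotations_.copy()
    scores, loadings = _orient_sign(scores, loadings)
    total = float((Z.to_numpy() ** 2).sum())
    var = np.array([(scores[:, k] ** 2).sum() / total for k in range(n_components)])
    q2 = _q2_cv(Z.to_numpy(), Y, n_components, seed)
    return LatentModel(
        scores=pd.DataFrame(scores, index=X.index,
                            columns=[f"PC{k+1}" for k in range(n_components)]),
        loadings=pd.DataFrame(loadings, index=Z.columns,
                              columns=[f"PC{k+1}" for k in range(n_components)]),
        explained_variance=var,
        center=center, scale=scale, method="plsda", labels=labels, q2=q2,
        dropped_features=dropped,
    )


@dataclass(frozen=True)
class TrendResult:
    """Axis-1 geometry of one (ref, uko, eko-endpoint) comparison."""

    lineage: str
    endpoint: int
    ref_centroid: float
    uko_centroid: float
    eko_centroid: float
    relative_distance: float
    matches_trend: bool


def relative_distance(
    model_or_scores,
    ref_samples: Sequence[str],
    uko_samples: Sequence[str],
    eko_samples: Sequence[str],
    lineage: str = "",
    endpoint: int = 0,
    threshold: float = TREND_THRESHOLD,
) -> TrendResult:
    """Apply the axis-1 relative-distance trend rule to one endpoint.

    relative_distance = |uko - eko| / |ref - uko| on axis-1 group
    centroids (arithmetic means of replicate scores); the result is
    invariant to a global sign flip of the axis.  Overshoot past the
    reference still counts toward a match (absolute distances).
    """
    scores = (model_or_scores.scores if isinstance(model_or_scores, LatentModel)
              else model_or_scores)
    axis1 = scores.iloc[:, 0]
    c_ref = float(axis1.loc[list(ref_samples)].mean())
    c_uko = float(axis1.loc[list(uko_samples)].mean())
    c_eko = float(axis1.loc[list(eko_samples)].mean())
    denom = abs(c_ref - c_uko)
    if denom < 1e-12:
        raise ValueError("ref and uko coincide on axis 1; relative distance undefined")
    # sign convention: orient axis 1 so ref <= uko
    if c_ref > c_uko:
        c_ref, c_uko, c_eko = -c_ref, -c_uko, -c_eko
    rd = abs(c_uko - c_eko) / denom
    return TrendResult(lineage, endpoint, c_ref, c_uko, c_eko, rd, rd > threshold)


def select_loading_features(
    model: LatentModel,
    correlations: Mapping[str, float] | pd.Series,
    top_fraction: float = 0.25,
    r_threshold: float = 0.88,
) -> list[str]:
    """Axis-1 loading-based feature selection.

    Selects features whose |axis-1 loading| ranks within the top
    ``top_fraction`` of all features AND whose profile correlation exceeds
    ``r_threshold``.  Ties at the quantile boundary are all included.
    """
    corr = pd.Series(correlations, dtype=float)
    mags = model.loadings.iloc[:, 0].abs().sort_values(ascending=False)
    k = int(np.ceil(top_fraction * len(mags)))
    cutoff = mags.iloc[k - 1] if k >= 1 else np.inf
    in_top = mags.index[mags >= cutoff - 1e-15]
    return [f for f in model.loadings.index
            if f in in_top and corr.get(f, np.nan) > r_threshold]
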