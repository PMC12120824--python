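"""Multivariate post-correction evaluation.

PCA score-space proximity metrics (intragroup distance to centroid and
pairwise intergroup centroid distance, both in the PC1-PC2 plane),
PLS-DA with VIP feature ranking (threshold 1.2 for distinctiveness),
and the cross-method feature-robustness comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .datamodel import FeatureTable

__all__ = [
    "PCAResult",
    "VIPResult",
    "pca_scores",
    "intragroup_distance",
    "intergroup_distance",
    "qcs_proximity",
    "plsda_vip",
    "robust_feature_comparison",
]


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_obs, A)
    loadings: np.ndarray  # (n_feat_kept, A)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None
    kept_features: np.ndarray  # column indices kept (zero-variance dropped when scaling)
    dropped_features: list


def pca_scores(
    X: np.ndarray | FeatureTable,
    n_components: int = 2,
    center: bool = True,
    scale: bool = True,
) -> PCAResult:
    """PCA via SVD with centering and unit-variance scaling (the study default).

    Zero-variance features are dropped (with a record) when scaling, since
    autoscaling them is undefined.  Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is positive.
    """
    feat_ids = None
    if isinstance(X, FeatureTable):
        feat_ids = X.feat_ids
        X = X.intensities
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 observations")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_obs-1, n_feat)={min(n - 1, p)}"
        )
    sd = X.std(axis=0, ddof=1)
    kept = np.arange(p)
    dropped: list = []
    work = X
    if scale:
        kept = np.flatnonzero(sd > 0)
        dropped = [feat_ids[i] if feat_ids else int(i) for i in np.flatnonzero(sd == 0)]
        work = X[:, kept]
    mean = work.mean(axis=0) if center else np.zeros(work.shape[1])
    work = work - mean
    scl = None
    if scale:
        scl = work.std(axis=0, ddof=1)
        work = work / scl

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(work)
    loadings = pca.components_.T  # (p_kept, A)
    # deterministic sign: largest-magnitude loading positive per component
    for a in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=mean,
        scale=scl,
        kept_features=kept,
        dropped_features=dropped,
    )


def intragroup_distance(scores: np.ndarray, group_labels) -> tuple[pd.Series, float]:
    """Mean Euclidean distance of group members to their centroid (PC1-PC2).

    Returns the per-group series and the grand average across groups.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("need at least 2 score columns (PC1 and PC2)")
    xy = scores[:, :2]
    labels = np.asarray(group_labels)
    per_group = {}
    for g in pd.unique(labels):
        pts = xy[labels == g]
        centroid = pts.mean(axis=0)
        per_group[g] = float(np.linalg.norm(pts - centroid, axis=1).mean())
    series = pd.Series(per_group, name="intragroup_distance")
    return series, float(series.mean())


def intergroup_distance(scores: np.ndarray, group_labels) -> tuple[pd.DataFrame, float]:
    """Pairwise centroid distances in PC1-PC2 and their average."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("need at least 2 score columns (PC1 and PC2)")
    labels = np.asarray(group_labels)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("intergroup distance needs >= 2 groups")
    xy = scores[:, :2]
    centroids = {g: xy[labels == g].mean(axis=0) for g in groups}
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    pairs = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            d = float(np.linalg.norm(centroids[g1] - centroids[g2]))
            mat.loc[g1, g2] = mat.loc[g2, g1] = d
            pairs.append(d)
    return mat, float(np.mean(pairs))


def qcs_proximity(table: FeatureTable, n_components: int = 2) -> float:
    """The "distance in PCA" metric: QCS spot proximity over all features.

    PCA (centered, scaled) is fit on the combined QCS + tissue table; the
    returned value is the mean distance of QCS spots to their common
    centroid in the PC1-PC2 plane.
    """
    qcs_mask = (table.obs_meta["region_type"] == "qcs").to_numpy()
    if not qcs_mask.any():
        raise ValueError("no QCS observations in table")
    res = pca_scores(table, n_components=n_components, center=True, scale=True)
    labels = np.where(qcs_mask, "qcs", "tissue")
    per_group, _ = intragroup_distance(res.scores, labels)
    return float(per_group["qcs"])


@dataclass
class VIPResult:
    vip: pd.Series  # per-feature VIP score
    n_components: int
    threshold: float
    selected: list  # feat_ids with VIP > threshold

    def selection_mask(self) -> pd.Series:
        return self.vip > self.threshold


def plsda_vip(
    X: np.ndarray | FeatureTable,
    group_labels=None,
    n_components: int | None = None,
    threshold: float = 1.2,
) -> VIPResult:
    """PLS-DA (NIPALS PLS2 on a one-hot response) with VIP scores.

    Features are autoscaled.  VIP_j = sqrt( p * sum_a SS_a (w_aj/||w_a||)^2
    / sum_a SS_a ) where SS_a is the response variance explained by
    component a; the scores satisfy mean(VIP^2) = 1 identically.  The
    default component count is (number of groups - 1).
    """
    feat_ids = None
    if isinstance(X, FeatureTable):
        feat_ids = X.feat_ids
        if group_labels is None:
            group_labels = X.obs_meta["group"].to_numpy()
        X = X.intensities
    X = np.asarray(X, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("PLS-DA needs >= 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 observations")
    n, p = X.shape
    if n_components is None:
        n_components = len(groups) - 1
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds the data rank bound")

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    Y = np.array([[1.0 if l == g else 0.0 for g in groups] for l in labels])
    Y = Y - Y.mean(axis=0)

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Y)
    W = pls.x_weights_  # (p_kept, A)
    T = pls.x_scores_  # (n, A)
    Q = pls.y_loadings_  # (q, A)
    ss = np.array(
        [(T[:, a] @ T[:, a]) * (Q[:, a] @ Q[:, a]) for a in range(n_components)]
    )
    w_norm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    p_kept = W.shape[0]
    vip_kept = np.sqrt(p_kept * (w_norm2 @ ss) / ss.sum())

    vip = np.zeros(p)
    vip[keep] = vip_kept
    index = feat_ids if feat_ids is not None else np.arange(p)
    series = pd.Series(vip, index=index, name="vip")
    selected = list(series.index[series > threshold])
    return VIPResult(vip=series, n_components=n_components, threshold=threshold, selected=selected)


def robust_feature_comparison(
    vip_results_by_method: dict[str, VIPResult],
    threshold: float | None = None,
    raw_method: str = "raw",
) -> pd.DataFrame:
    """Feature x method selection grid with robust/dropped annotations.

    Robust features are selected under every method; dropped features were
    selected in the raw data but under none of the corrected methods.
    """
    methods = list(vip_results_by_method)
    if len(methods) < 2:
        raise ValueError("need VIP results from >= 2 methods")
    index = vip_results_by_method[methods[0]].vip.index
    for m in methods[1:]:
        if not index.equals(vip_results_by_method[m].vip.index):
            raise ValueError("mismatched feature sets across methods")
    grid = pd.DataFrame(
        {
            m: (
                vip_results_by_method[m].vip
                > (threshold if threshold is not None else vip_results_by_method[m].threshold)
            )
            for m in methods
        }
    )
    grid["robust"] = grid[methods].all(axis=1)
    corrected = [m for m in methods if m != raw_method]
    if raw_method in methods and corrected:
        grid["dropped"] = grid[raw_method] & ~grid[corrected].any(axis=1)
    return grid
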