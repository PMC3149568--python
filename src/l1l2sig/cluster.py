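"""Correlation-distance k-means for structuring signatures into modules.

Variables of a signature with highly correlated expression profiles tend to
sit in the same pathways; grouping the profiles under the correlation
distance ``1 - Pearson(u, v)`` makes those modules visible. The cluster
count is conventionally taken from the size of the minimal-mu list (the
sparsest selection along the mu path).

Implementation note: after standardizing each profile to zero mean and unit
norm, squared Euclidean distance equals ``2 * (1 - Pearson)``, so ordinary
k-means on the standardized rows minimizes exactly the within-cluster
correlation-distance objective. The heavy lifting is delegated to
scikit-learn's Lloyd iteration with k-means++ restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = ["correlation_distance", "CorrelationKMeans", "cluster_signature",
           "save_heatmap"]


def _standardize_rows(P):
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError(f"profiles must form a 2-D matrix, got shape {P.shape}")
    if P.shape[1] < 3:
        raise ValueError(
            f"profiles need >= 3 observations, got {P.shape[1]}")
    if not np.all(np.isfinite(P)):
        raise ValueError("profiles contain non-finite values")
    centered = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance (constant) profiles at rows {zero.tolist()}: "
            "correlation distance is undefined")
    return centered / norms[:, None]


def correlation_distance(u, v):
    """``1 - Pearson(u, v)``, in [0, 2]; invariant to positive affine maps."""
    U = _standardize_rows(np.vstack([u, v]))
    r = float(np.clip(U[0] @ U[1], -1.0, 1.0))
    return 1.0 - r


class CorrelationKMeans(BaseEstimator):
    """K-means on expression profiles under the correlation distance.

    Parameters
    ----------
    n_clusters : number of modules; the convention is the minimal-mu list
        size of the same dataset's mu path.
    n_restarts : independent k-means++ initializations; the best objective
        is kept (restarts can only improve it).
    max_iter : Lloyd iteration cap per restart.
    random_state : seed; clustering is deterministic given it.

    Attributes
    ----------
    labels_ : cluster index per profile.
    inertia_ : total within-cluster squared distance (standardized geometry;
        equals twice the summed correlation distance to centroids).
    within_cluster_mean_distance_ : mean correlation distance of profiles to
        their cluster's mean profile.
    """

    def __init__(self, n_clusters=2, n_restarts=20, max_iter=300,
                 random_state=None):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        U = _standardize_rows(X)
        n_distinct = np.unique(np.round(U, 12), axis=0).shape[0]
        if self.n_clusters > n_distinct:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the number of "
                f"distinct profiles ({n_distinct})")
        km = KMeans(n_clusters=self.n_clusters, n_init=self.n_restarts,
                    max_iter=self.max_iter, random_state=self.random_state)
        km.fit(U)
        self.labels_ = km.labels_
        self.inertia_ = float(km.inertia_)
        self.cluster_centers_ = km.cluster_centers_
        # mean correlation distance to the cluster mean profile
        dists = []
        for k in range(self.n_clusters):
            members = U[self.labels_ == k]
            center = members.mean(axis=0)
            norm = np.linalg.norm(center)
            if norm == 0:
                dists.extend([1.0] * len(members))
                continue
            dists.extend((1.0 - members @ (center / norm)).tolist())
        self.within_cluster_mean_distance_ = float(np.mean(dists))
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_signature(data, signature, k, seed=0, n_restarts=20):
    """Cluster the signature variables' profiles across samples.

    Returns a DataFrame (variable_id, frequency, cluster) ordered by cluster
    then descending frequency — the exported, testable artifact.
    """
    sub = data.subset(signature.variable_ids)
    profiles = sub.X.T  # variables x samples
    km = CorrelationKMeans(n_clusters=k, n_restarts=n_restarts,
                           random_state=seed).fit(profiles)
    df = pd.DataFrame({
        "variable_id": signature.variable_ids,
        "frequency": [f for _, f in signature.entries],
        "cluster": km.labels_,
    })
    return df.sort_values(["cluster", "frequency", "variable_id"],
                          ascending=[True, False, True],
                          ignore_index=True)


def save_heatmap(data, assignment: pd.DataFrame, path):
    """Optional rendering: variables ordered by cluster, min-max scaled rows.

    Expressions are scaled to [0, 1] per variable for display only; the
    cluster assignment table remains the artifact of record.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = assignment["variable_id"].tolist()
    sub = data.subset(order)
    P = sub.X.T
    lo, hi = P.min(axis=1, keepdims=True), P.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (P - lo) / span
    sample_order = np.argsort(sub.y)[::-1]  # diseased block first
    fig, ax = plt.subplots(
        figsize=(max(6, 0.08 * P.shape[1]), max(4, 0.25 * P.shape[0])))
    ax.imshow(scaled[:, sample_order], aspect="auto", cmap="RdYlGn_r")
    boundaries = np.flatnonzero(np.diff(assignment["cluster"].to_numpy()))
    for b in boundaries:
        ax.axhline(b + 0.5, color="black", lw=2)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=6)
    ax.set_xlabel("samples (diseased | control)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
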