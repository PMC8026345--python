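"""Learner subtyping: K-means over difference features with silhouette selection.

Subjects are clustered on two features per subject — the mean and SD of
the posterior first-minus-last latent-state difference — after per-
dimension z-scoring (the two features have very different spreads).  The
number of clusters is chosen by maximizing the mean silhouette
coefficient over a candidate range (default 3..7), ties broken toward
the smaller k.  Cluster labels are relabeled by descending cluster mean
of ``diff_mean`` so that cluster 1 always contains the strongest
learners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = ["SubgroupModel", "cluster_learners"]


@dataclass
class SubgroupModel:
    """Result of silhouette-selected K-means learner subtyping."""

    selected_k: int
    labels: pd.Series  # subject_id -> cluster label in 1..selected_k
    centroids: np.ndarray  # (selected_k, 2), original feature units
    silhouette_by_k: dict[int, float]
    feature_means: np.ndarray
    feature_sds: np.ndarray

    @property
    def silhouette(self) -> float:
        return self.silhouette_by_k[self.selected_k]


def cluster_learners(features: pd.DataFrame,
                     k_range: tuple[int, int] = (3, 7),
                     n_restarts: int = 50,
                     seed: int = 0) -> SubgroupModel:
    """Cluster a cohort's difference features into learner subgroups.

    ``features`` needs columns ``subject_id``, ``diff_mean``,
    ``diff_sd``.  For each k in ``k_range`` (inclusive) K-means with
    ``n_restarts`` k-means++ initializations is fitted on the z-scored
    features and the mean silhouette coefficient computed; the k with the
    highest silhouette wins.  Candidate k >= n_subjects are skipped with
    a warning.
    """
    for col in ("subject_id", "diff_mean", "diff_sd"):
        if col not in features.columns:
            raise ValueError(f"features lack required column {col!r}")
    X_raw = features[["diff_mean", "diff_sd"]].to_numpy(float)
    if not np.isfinite(X_raw).all():
        raise ValueError("non-finite difference features")
    n = len(X_raw)
    means = X_raw.mean(axis=0)
    sds = X_raw.std(axis=0)
    if np.all(sds < 1e-12):
        raise ValueError("all features identical: clustering is degenerate")
    sds = np.where(sds < 1e-12, 1.0, sds)
    X = (X_raw - means) / sds

    k_lo, k_hi = k_range
    sil: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in range(k_lo, k_hi + 1):
        if k >= n:
            warnings.warn(f"skipping k={k}: only {n} subjects", stacklevel=2)
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**31))
        lab = km.fit_predict(X)
        sil[k] = float(silhouette_score(X, lab))
        fits[k] = km
    if not sil:
        raise ValueError(f"no feasible k in {k_range} for {n} subjects")

    best = max(sil.values())
    selected_k = min(k for k, s in sil.items() if s == best)
    km = fits[selected_k]
    raw_labels = km.labels_

    # relabel by descending cluster mean of diff_mean: 1 = most learning
    cluster_means = np.array(
        [X_raw[raw_labels == c, 0].mean() for c in range(selected_k)]
    )
    order = np.argsort(-cluster_means)
    remap = np.empty(selected_k, int)
    remap[order] = np.arange(1, selected_k + 1)
    labels = pd.Series(remap[raw_labels],
                       index=features["subject_id"].astype(str).to_numpy(),
                       name="subgroup")
    centroids_scaled = km.cluster_centers_[order]
    centroids = centroids_scaled * sds + means
    return SubgroupModel(
        selected_k=selected_k, labels=labels, centroids=centroids,
        silhouette_by_k=sil, feature_means=means, feature_sds=sds,
    )
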