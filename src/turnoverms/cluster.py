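"""Aging-trend clustering: row z-scoring, k-means with silhouette-chosen k, PCA.

Protein FA profiles across age groups are z-scored per row and clustered with
k-means; the number of clusters is the one maximizing the mean silhouette
score among candidate k whose smallest cluster still meets a minimum size
(trend groups below ~10 proteins are not interpretable).  A sample-space PCA
checks replicate reproducibility.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .matrix import FaMatrix

__all__ = ["zscore_rows", "TrendClusterer", "select_k", "cluster", "pca_samples"]

logger = logging.getLogger(__name__)


def zscore_rows(m: pd.DataFrame | FaMatrix) -> pd.DataFrame:
    """Row-wise z-score (x - mean) / sd with the n-1 sd convention.

    Rows with fewer than two finite values or zero variance cannot be scaled
    and are dropped (a count is logged); NaN cells in surviving rows are kept.
    """
    df = m.values if isinstance(m, FaMatrix) else m
    if df.shape[1] < 2:
        raise ValueError("need at least two columns to z-score rows")
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    finite = df.notna().sum(axis=1)
    keep = (finite >= 2) & (sd > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("zscore_rows: dropped %d constant/short rows", dropped)
    out = df.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return out


class TrendClusterer(BaseEstimator, ClusterMixin):
    """K-means trend clustering with silhouette-based selection of k.

    For every k in ``k_range`` a seeded k-means (``n_init`` restarts,
    Euclidean) is fitted and the mean silhouette computed; the chosen k
    maximizes silhouette among solutions whose smallest cluster has at least
    ``min_cluster_size`` members, ties resolved toward smaller k.

    Parameters
    ----------
    k_range : (int, int)
        Inclusive candidate range for the number of clusters.
    min_cluster_size : int
        Minimum admissible cluster size (protein-group size).
    n_init, max_iter : int
        Passed to :class:`sklearn.cluster.KMeans`.
    random_state : int | None
        Seed; outputs are deterministic given the seed.

    Attributes (after ``fit``)
    --------------------------
    n_clusters_ : selected k.
    labels_ : cluster label per row.
    cluster_centers_ : (k, n_features) centroid matrix.
    silhouette_by_k_ : dict k -> mean silhouette score.
    feasible_k_ : candidate k passing the size constraint.
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (2, 8),
        min_cluster_size: int = 10,
        n_init: int = 50,
        max_iter: int = 300,
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.min_cluster_size = min_cluster_size
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if np.any(~np.isfinite(X)):
            raise ValueError("X contains non-finite values; drop or impute first")
        lo, hi = self.k_range
        lo = max(2, lo)
        hi = min(hi, X.shape[0] - 1)
        if hi < lo:
            raise ValueError("k_range empty after bounding by the row count")

        self.silhouette_by_k_ = {}
        self.feasible_k_ = []
        fits = {}
        for k in range(lo, hi + 1):
            km = KMeans(
                n_clusters=k,
                n_init=self.n_init,
                max_iter=self.max_iter,
                random_state=self.random_state,
            ).fit(X)
            sil = float(silhouette_score(X, km.labels_, metric="euclidean"))
            self.silhouette_by_k_[k] = sil
            fits[k] = km
            if np.bincount(km.labels_).min() >= self.min_cluster_size:
                self.feasible_k_.append(k)
        if not self.feasible_k_:
            raise ValueError(
                "no candidate k satisfies the minimum cluster size "
                f"{self.min_cluster_size}"
            )
        # max silhouette; ties go to the smaller k (feasible_k_ is ascending)
        best = max(self.feasible_k_, key=lambda k: (self.silhouette_by_k_[k], -k))
        self.n_clusters_ = best
        self.kmeans_ = fits[best]
        self.labels_ = fits[best].labels_
        self.cluster_centers_ = fits[best].cluster_centers_
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def select_k(
    matrix: pd.DataFrame | np.ndarray,
    k_range: tuple[int, int] = (2, 8),
    min_size: int = 10,
    seed: int | None = None,
) -> TrendClusterer:
    """Functional wrapper over :class:`TrendClusterer`."""
    est = TrendClusterer(k_range=k_range, min_cluster_size=min_size, random_state=seed)
    X = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix
    return est.fit(X)


def cluster(
    matrix: pd.DataFrame | np.ndarray, k: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Plain seeded k-means at a fixed k; returns (labels, centroids)."""
    X = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of rows")
    km = KMeans(n_clusters=k, n_init=50, max_iter=300, random_state=seed).fit(X)
    return km.labels_, km.cluster_centers_


def pca_samples(m: FaMatrix, n_components: int | None = None):
    """Centered PCA of samples in protein space (complete-case proteins).

    Returns (coordinates DataFrame indexed by sample, explained-variance-ratio
    array).  Used to check that biological replicates of an age group lie
    close together.
    """
    complete = m.values.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("fewer than 2 complete-case proteins")
    if complete.shape[1] < 3:
        raise ValueError("need at least 3 samples for a PCA")
    X = complete.to_numpy(float).T  # samples x proteins
    k = n_components or min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords,
        index=complete.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return frame, pca.explained_variance_ratio_
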