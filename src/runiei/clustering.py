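"""Profile clustering of (IEC, IED) pairs.

Implements the clustering stage of the analysis: a Ward dendrogram as the
cluster-number diagnostic, crisp k-means, fuzzy k-means with membership
diagnostics, partition-agreement measures, and the convention mapping
cluster centers to affective pattern labels
(positive/negative x discrepant/non-discrepant).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

__all__ = [
    "PATTERN_LABELS",
    "ward_tree",
    "cut_tree_k",
    "kmeans_cluster",
    "FuzzyKMeans",
    "rand_index",
    "match_clusters",
    "overlap_table",
    "mean_membership_table",
    "label_clusters",
]

PATTERN_LABELS = (
    "positive_non_discrepant",
    "positive_discrepant",
    "negative_discrepant",
    "negative_non_discrepant",
)


def ward_tree(points) -> np.ndarray:
    """Agglomerative merge history under Ward's criterion (scipy linkage).

    Euclidean distances; merge heights are monotone non-decreasing. Use
    :func:`cut_tree_k` to obtain flat labels for any number of clusters.
    """
    points = check_array(points, dtype=float, ensure_min_samples=2)
    return linkage(points, method="ward")


def cut_tree_k(tree: np.ndarray, k: int) -> np.ndarray:
    """Flat 0-based labels from cutting a Ward tree into ``k`` clusters."""
    return fcluster(tree, t=k, criterion="maxclust") - 1


def kmeans_cluster(
    points,
    k: int,
    n_starts: int = 25,
    max_iter: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Crisp k-means on squared Euclidean distances, best of ``n_starts``.

    Returns ``(labels, centers, inertia)``. Deterministic under a fixed
    seed. Empty clusters are repaired internally by relocating a center to
    a distant point (sklearn's strategy).
    """
    points = check_array(points, dtype=float)
    if not 1 <= k <= len(points):
        raise ValueError("need 1 <= k <= n points")
    km = KMeans(
        n_clusters=k, n_init=n_starts, max_iter=max_iter, random_state=seed
    ).fit(points)
    return km.labels_.astype(int), km.cluster_centers_, float(km.inertia_)


class FuzzyKMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering (Bezdek) as an sklearn-style estimator.

    Each observation holds graded membership degrees summing to 1 across the
    ``n_clusters`` clusters, controlled by the fuzziness exponent ``m > 1``
    (``m -> 1`` recovers crisp k-means; larger ``m`` spreads membership).
    The alternating optimization minimizes

        J = sum_i sum_k u_ik^m ||x_i - c_k||^2

    with the stationarity updates

        c_k = sum_i u_ik^m x_i / sum_i u_ik^m
        u_ik = 1 / sum_j (d_ik / d_ij)^(2 / (m - 1)).

    Each start begins from a random row-normalized membership matrix and
    iterates until the maximum absolute membership change drops below
    ``tol``; the best of ``n_starts`` by final objective is kept.

    Parameters
    ----------
    n_clusters : int, default 4
    m : float, default 2.0
        Membership (fuzziness) exponent, must be > 1.
    n_starts : int, default 25
    max_iter : int, default 1000
    tol : float, default 1e-9
        Convergence threshold on the membership change.
    random_state : int or RandomState, optional

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters, n_features)
    membership_ : ndarray (n_samples, n_clusters)
        Rows sum to 1.
    labels_ : ndarray (n_samples,)
        Hard labels by maximum membership.
    objective_ : float
        Final fuzzy objective of the best start.
    objective_history_ : ndarray
        Objective per iteration of the best start (non-increasing).
    n_iter_ : int
    """

    def __init__(
        self,
        n_clusters: int = 4,
        m: float = 2.0,
        n_starts: int = 25,
        max_iter: int = 1000,
        tol: float = 1e-9,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
        """Membership update from squared distances; exact at zero distance."""
        u = np.empty_like(d2)
        zero = d2 <= 0.0
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        ok = ~any_zero
        u[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
        if any_zero.any():
            u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        return u

    def _single_start(self, X: np.ndarray, rng) -> tuple:
        n, _ = X.shape
        k, m = self.n_clusters, self.m
        u = rng.random((n, k)) + 1e-12
        u /= u.sum(axis=1, keepdims=True)
        history = []
        for it in range(1, self.max_iter + 1):
            um = u**m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            d2 = cdist(X, centers, metric="sqeuclidean")
            u_new = self._memberships(d2, m)
            history.append(float(((u_new**m) * d2).sum()))
            delta = np.abs(u_new - u).max()
            u = u_new
            if delta < self.tol:
                break
        return history[-1], centers, u, np.asarray(history), it

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        if self.n_clusters > len(X):
            raise ValueError("n_clusters may not exceed the number of points")
        if self.m <= 1.0:
            raise ValueError("membership exponent m must be > 1")
        rng = check_random_state(self.random_state)
        best = None
        for _ in range(self.n_starts):
            result = self._single_start(X, rng)
            if best is None or result[0] < best[0]:
                best = result
        obj, centers, u, history, n_iter = best
        self.cluster_centers_ = centers
        self.membership_ = u
        self.labels_ = u.argmax(axis=1)
        self.objective_ = obj
        self.objective_history_ = history
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def soft_predict(self, X) -> np.ndarray:
        """Membership degrees of new points given the fitted centers."""
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X, dtype=float)
        d2 = cdist(X, self.cluster_centers_, metric="sqeuclidean")
        return self._memberships(d2, self.m)

    def predict(self, X) -> np.ndarray:
        return self.soft_predict(X).argmax(axis=1)


def rand_index(labels_a, labels_b) -> float:
    """Rand index: fraction of point pairs on which two partitions agree
    (co-clustered in both or separated in both)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 points")

    def _comb2_sum(counts):
        counts = np.asarray(counts, dtype=float)
        return float((counts * (counts - 1) / 2).sum())

    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1)
    total = n * (n - 1) / 2
    sum_ij = _comb2_sum(contingency)
    sum_a = _comb2_sum(contingency.sum(axis=1))
    sum_b = _comb2_sum(contingency.sum(axis=0))
    return (total + 2 * sum_ij - sum_a - sum_b) / total


def _confusion(labels_a, labels_b, k: int) -> np.ndarray:
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (np.asarray(labels_a), np.asarray(labels_b)), 1)
    return conf


def match_clusters(fuzzy_hard_labels, kmeans_labels) -> dict[int, int]:
    """Optimal one-to-one relabeling of fuzzy clusters onto crisp clusters.

    Solves the assignment problem on the k x k confusion matrix, maximizing
    total overlap; returns a map ``fuzzy label -> crisp label``. Both
    partitions must use the same number of clusters (labels 0..k-1).
    """
    a = np.asarray(fuzzy_hard_labels)
    b = np.asarray(kmeans_labels)
    ka, kb = a.max() + 1, b.max() + 1
    if ka != kb:
        raise ValueError(f"partitions have different cluster counts: {ka} vs {kb}")
    conf = _confusion(a, b, int(ka))
    rows, cols = linear_sum_assignment(-conf)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def overlap_table(fuzzy_hard_labels, kmeans_labels, k: int | None = None) -> np.ndarray:
    """Row-percentage overlap of fuzzy hard clusters with crisp clusters.

    Entry (i, j) is the percentage of fuzzy-cluster-i members assigned to
    crisp cluster j; each nonempty row sums to 100.
    """
    a = np.asarray(fuzzy_hard_labels)
    b = np.asarray(kmeans_labels)
    if k is None:
        k = int(max(a.max(), b.max()) + 1)
    conf = _confusion(a, b, k).astype(float)
    rows = conf.sum(axis=1, keepdims=True)
    empty = rows[:, 0] == 0
    if empty.any():
        warnings.warn(f"empty fuzzy cluster(s): {np.flatnonzero(empty).tolist()}")
        rows[empty] = 1.0
    return 100.0 * conf / rows


def mean_membership_table(hard_labels, membership) -> np.ndarray:
    """Mean membership degree (in percent) by hard-assigned cluster.

    Entry (i, j) is the mean membership in cluster j over observations
    hard-assigned to cluster i, times 100; rows sum to 100 because
    membership rows are normalized.
    """
    hard = np.asarray(hard_labels)
    u = np.asarray(membership, dtype=float)
    k = u.shape[1]
    table = np.zeros((k, k))
    for i in range(k):
        members = hard == i
        if not members.any():
            raise ValueError(f"empty hard cluster {i}")
        table[i] = 100.0 * u[members].mean(axis=0)
    return table


def label_clusters(centers) -> list[str]:
    """Assign affective pattern labels to k = 4 centers in (IEC, IED) space.

    Convention: the center with the largest IED is "positive discrepant",
    the smallest IED "negative discrepant"; of the remaining two, the larger
    IEC is "positive non-discrepant" and the smaller "negative
    non-discrepant". Ties are broken by IEC and then by center index.
    """
    centers = check_array(centers, dtype=float)
    if centers.shape != (4, 2):
        raise ValueError("expected 4 centers in (IEC, IED) space")
    iec, ied = centers[:, 0], centers[:, 1]
    order_ied = np.lexsort((np.arange(4), iec, ied))
    labels = [""] * 4
    labels[order_ied[-1]] = "positive_discrepant"
    labels[order_ied[0]] = "negative_discrepant"
    remaining = sorted(order_ied[1:3], key=lambda i: (iec[i], -i))
    labels[remaining[1]] = "positive_non_discrepant"
    labels[remaining[0]] = "negative_non_discrepant"
    return labels
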