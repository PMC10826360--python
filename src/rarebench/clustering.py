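"""Two-cluster assignment of samples from a distance matrix, and accuracy.

Three clustering algorithms are compared: partitioning around medoids (PAM,
classical BUILD + SWAP k-medoids on the distance matrix), K-means on the
rows of the distance matrix treated as feature vectors (mirroring a direct
call of a K-means routine on the square matrix; a principal-coordinates
embedding is available behind a flag), and complete-linkage hierarchical
clustering cut at k = 2.

Accuracy is the best-matched fraction of *all* samples assigned to the
correct treatment group; samples discarded by a minimum-library-size
threshold always count as errors, so accuracies can fall below 50%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .distances import DistanceMatrix

CLUSTER_METHODS = ("pam", "kmeans", "hclust")


def _pam(d: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    return np.argmin(d[:, _pam_medoids(d, k, max_iter)], axis=1)


def _pam_medoids(d: np.ndarray, k: int, max_iter: int = 100) -> list[int]:
    """Classical k-medoids: greedy BUILD then SWAP to a local optimum.

    Ties are broken toward the lowest sample index for determinism.
    """
    n = d.shape[0]
    # BUILD: first medoid minimizes total distance; then greedy gain
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - d, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best, improved = trial, c, True
        if not improved:
            break
    return medoids


def pcoa_embedding(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical MDS coordinates from a (possibly non-Euclidean) matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    w_pos = np.maximum(w[order], 0)
    return v[:, order] * np.sqrt(w_pos)


def cluster(dm: DistanceMatrix, method: str, k: int = 2, seed: int = 0,
            embed: str = "rows") -> np.ndarray:
    """Assign each retained sample to one of ``k`` clusters.

    ``embed`` controls the K-means feature space: ``"rows"`` uses the raw
    distance-matrix rows, ``"pcoa"`` a principal-coordinates embedding.
    """
    d = dm.values
    n = dm.n
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} samples")
    if method == "pam":
        return _pam(d, k)
    if method == "kmeans":
        feats = d if embed == "rows" else pcoa_embedding(d)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(feats)
    if method == "hclust":
        z = linkage(dm.condensed(), method="complete")
        return fcluster(z, t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown clustering method {method!r}")


def accuracy(labels: np.ndarray, true_groups: np.ndarray,
             n_removed: int = 0) -> float:
    """Best-matched clustering accuracy over all samples.

    The two cluster ids are matched to the two treatment groups whichever
    way yields more correct assignments; the denominator includes the
    ``n_removed`` samples discarded before clustering, which are always
    counted as misclustered.
    """
    labels = np.asarray(labels)
    true_groups = np.asarray(true_groups)
    if len(labels) != len(true_groups):
        raise ValueError("labels and true groups must align")
    n_total = len(labels) + n_removed
    # map labels to {0,1}; count both matchings
    uniq = np.unique(labels)
    lab01 = (labels == uniq[-1]).astype(int)
    grp01 = np.asarray([g == "B" for g in true_groups], dtype=int) \
        if true_groups.dtype.kind in "US" else np.asarray(true_groups, dtype=int)
    agree = int((lab01 == grp01).sum())
    correct = max(agree, len(labels) - agree)
    return correct / n_total


def method_win_rates(records: pd.DataFrame,
                     accuracy_col: str = "accuracy",
                     method_col: str = "cluster_method") -> pd.Series:
    """Per-method fraction of cells where it was at least as good as every rival.

    ``records`` holds one row per (cell, clustering method); cells are all
    remaining columns.  Ties count as wins for every tied method, so the
    fractions need not sum to one.
    """
    key_cols = [c for c in records.columns
                if c not in (accuracy_col, method_col)]
    best = records.groupby(key_cols, dropna=False)[accuracy_col].transform("max")
    wins = records[records[accuracy_col] >= best - 1e-12]
    total_cells = records.groupby(key_cols, dropna=False).ngroups
    return wins.groupby(method_col).size() / total_cells
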