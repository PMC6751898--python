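"""Clustering of motif-activity profiles and silhouette-guided choice of k.

Activity profiles (motifs x intervals) are partitioned with Euclidean k-means.
The number of clusters is chosen by mean silhouette, subject to the cap that
no cluster may hold more than half of the motifs -- a guard against trivially
high-silhouette solutions that lump most profiles together.  Clusters are
validated descriptively by the mean pairwise Spearman correlation of their
member profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series  # motif -> cluster label (0..k-1)
    centroids: np.ndarray  # k x n_intervals
    wcss: float  # within-cluster sum of squares
    seed: int
    restarts: int


def kmeans_fit(
    profiles: pd.DataFrame, k: int, seed: int = 0, restarts: int = 50
) -> ClusterModel:
    """Best-of-restarts Euclidean k-means (k-means++ starts), deterministic
    given the seed."""
    n = len(profiles)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, {n}]")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())
    return ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=profiles.index, name="cluster"),
        centroids=km.cluster_centers_,
        wcss=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def mean_silhouette(profiles: pd.DataFrame, assignments: pd.Series) -> float:
    """Mean silhouette (b - a) / max(a, b) over points, Euclidean distance;
    singleton clusters contribute 0."""
    labels = assignments.reindex(profiles.index).to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(silhouette_score(profiles.to_numpy(), labels, metric="euclidean"))


@dataclass
class KSelectionReport:
    table: pd.DataFrame  # columns: k, silhouette, largest_cluster, eligible
    chosen_k: int
    cap_fraction: float
    cap: int  # absolute largest-cluster cap, floor(cap_fraction * n)


def largest_cluster_cap(n: int, cap_fraction: float = 0.5) -> int:
    """Absolute cap on the largest cluster: floor(cap_fraction * n)."""
    if not 0 < cap_fraction <= 1:
        raise ValueError("cap_fraction must be in (0, 1]")
    return int(np.floor(cap_fraction * n))


def select_k(
    profiles: pd.DataFrame,
    k_range: range | list[int] = range(2, 13),
    cap_fraction: float = 0.5,
    seed: int = 0,
    restarts: int = 50,
) -> KSelectionReport:
    """Choose k as the silhouette argmax among values whose largest cluster
    stays within the cap; ties go to the smallest k."""
    n = len(profiles)
    ks = [k for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n:
        raise ValueError(f"k_range must lie within [2, {n}]")
    cap = largest_cluster_cap(n, cap_fraction)
    rows = []
    for k in ks:
        model = kmeans_fit(profiles, k, seed=seed, restarts=restarts)
        sil = mean_silhouette(profiles, model.assignments)
        largest = int(model.assignments.value_counts().iloc[0])
        rows.append(
            {"k": k, "silhouette": sil, "largest_cluster": largest,
             "eligible": largest <= cap}
        )
    table = pd.DataFrame(rows)
    eligible = table[table["eligible"]]
    if eligible.empty:
        raise ValueError(
            f"no k in {ks} satisfies the largest-cluster cap {cap}:\n{table}"
        )
    best_sil = eligible["silhouette"].max()
    chosen = int(eligible.loc[eligible["silhouette"] == best_sil, "k"].min())
    return KSelectionReport(table=table, chosen_k=chosen, cap_fraction=cap_fraction, cap=cap)


def within_cluster_spearman(
    profiles: pd.DataFrame, assignments: pd.Series
) -> pd.Series:
    """Per-cluster mean pairwise Spearman rho of member profiles.

    Clusters of size < 2 are reported as NaN; pairs involving a constant
    profile (rank correlation undefined) are excluded from the mean with a
    warning.
    """
    labels = assignments.reindex(profiles.index)
    out = {}
    for cluster, members in profiles.groupby(labels, sort=True):
        if len(members) < 2:
            out[cluster] = np.nan
            continue
        vals = members.to_numpy()
        rhos = []
        skipped = 0
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                if np.std(vals[i]) == 0 or np.std(vals[j]) == 0:
                    skipped += 1
                    continue
                rho = spearmanr(vals[i], vals[j]).statistic
                rhos.append(rho)
        if skipped:
            warnings.warn(
                f"cluster {cluster}: skipped {skipped} pair(s) with a constant "
                "profile",
                stacklevel=2,
            )
        out[cluster] = float(np.mean(rhos)) if rhos else np.nan
    return pd.Series(out, name="mean_spearman")
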