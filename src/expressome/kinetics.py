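"""Stress-induction kinetics: gene selection, k-means time-course
clusters and sigma-factor regulon profiles.

Time-courses are the three transcriptome log2 ratios at 7, 45 and 90
minutes.  Clustering is plain k-means on the raw 3-vectors (Euclidean
distance, max 50 iterations, random member seeding under an explicit
seed), with the largest cluster optionally subdivided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

TIME_POINTS = (7, 45, 90)
RATIO_COLS = ("log2_7", "log2_45", "log2_90")
P_COLS = ("p_7", "p_45", "p_90")


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series      # gene_id -> cluster label (str)
    centroids: pd.DataFrame     # label x time-point
    iterations: int
    seed: int


def make_timecourses(experiments: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble gene x (log2, p) time-course table from the per-
    experiment transcriptome quantifications (keys total_7min/45/90)."""
    parts = []
    for t, key in zip(TIME_POINTS, ("total_7min", "total_45min", "total_90min")):
        df = experiments[key][["gene_id", "log2_ratio", "p_value", "call"]]
        df = df.rename(columns={"log2_ratio": f"log2_{t}", "p_value": f"p_{t}",
                                "call": f"call_{t}"})
        parts.append(df.set_index("gene_id"))
    return parts[0].join(parts[1:], how="outer")


def select_induced(
    timecourses: pd.DataFrame, threshold: float = 0.8, alpha: float = 0.05
) -> pd.DataFrame:
    """Genes with significant induction (log2 >= threshold, p < alpha)
    at one of the three time-points."""
    keep = np.zeros(len(timecourses), bool)
    for rc, pc in zip(RATIO_COLS, P_COLS):
        ratio = timecourses[rc].to_numpy(float)
        p = np.nan_to_num(timecourses[pc].to_numpy(float), nan=1.0)
        keep |= (ratio >= threshold) & (p < alpha)
    return timecourses[keep]


def core_set(timecourses: pd.DataFrame) -> pd.Index:
    """Genes called up at all three time-points."""
    mask = np.ones(len(timecourses), bool)
    for t in TIME_POINTS:
        mask &= (timecourses[f"call_{t}"] == "up").to_numpy()
    return timecourses.index[mask]


def kmeans_cluster(
    timecourses: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    max_iter: int = 50,
    prefix: str = "",
) -> ClusterResult:
    """Euclidean k-means on complete 3-point profiles.

    Genes with a missing ratio at any time-point are excluded
    (Euclidean distance needs complete vectors).  Labels are "1".."k"
    by decreasing cluster size, so the largest cluster — the usual
    target of subdivision — is always label 1.
    """
    data = timecourses[list(RATIO_COLS)].dropna()
    n = len(data)
    if k > n:
        raise ValueError(f"k={k} exceeds number of complete profiles ({n})")
    km = KMeans(n_clusters=k, init="random", n_init=1, max_iter=max_iter,
                random_state=seed)
    raw = km.fit_predict(data.to_numpy(float))
    order = pd.Series(raw).value_counts().index.to_list()
    relabel = {old: f"{prefix}{rank + 1}" for rank, old in enumerate(order)}
    labels = pd.Series([relabel[r] for r in raw], index=data.index,
                       name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=list(RATIO_COLS))
    centroids.index = [relabel[i] for i in range(k)]
    centroids = centroids.sort_index()
    return ClusterResult(k=k, assignments=labels, centroids=centroids,
                         iterations=int(km.n_iter_), seed=seed)


def subdivide_cluster(
    timecourses: pd.DataFrame,
    result: ClusterResult,
    cluster_label: str,
    k2: int,
    seed: int = 0,
) -> ClusterResult:
    """Re-run k-means on one cluster's members; sub-labels get letter
    suffixes (e.g. cluster 2 -> 2a, 2b, 2c)."""
    members = result.assignments[result.assignments == cluster_label].index
    if len(members) == 0:
        raise ValueError(f"cluster {cluster_label!r} is empty")
    sub = kmeans_cluster(timecourses.loc[members], k=k2, seed=seed,
                         max_iter=50)
    letters = "abcdefghijklmnopqrstuvwxyz"
    mapping = {f"{i + 1}": f"{cluster_label}{letters[i]}" for i in range(k2)}
    sub.assignments = sub.assignments.map(mapping)
    sub.centroids.index = [mapping[i] for i in sub.centroids.index]
    return sub


def regulon_kinetics(
    members: list[str] | pd.Index,
    timecourses: pd.DataFrame,
    threshold: float = 0.8,
) -> dict:
    """Mean log2 profile of a regulon, over members reaching log2 >=
    threshold at one or more time-points."""
    present = timecourses.index.intersection(pd.Index(members).unique())
    sub = timecourses.loc[present, list(RATIO_COLS)]
    peak = sub.max(axis=1, skipna=True)
    retained = sub[peak >= threshold]
    if retained.empty:
        return {"n": 0, "mean_log2": {t: float("nan") for t in TIME_POINTS}}
    means = retained.mean(axis=0, skipna=True)
    return {"n": int(len(retained)),
            "mean_log2": {t: float(means[f"log2_{t}"]) for t in TIME_POINTS}}
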