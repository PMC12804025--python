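"""Fuzzy c-means clustering of z-scored temporal expression profiles.

Soft clustering of differential proteins' time courses: memberships
u_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1)) and centroids
v_j = sum_i u_ij^m x_i / sum_i u_ij^m, alternated until the membership
matrix stabilizes. The fuzzifier m controls assignment softness (m -> 1
recovers k-means). The cluster number is selected by mean silhouette of the
hardened assignment (a minimum-centroid-distance criterion is available as
an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from granulekit.preprocess import trajectory_matrix

DEFAULT_M = 2.0


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row (protein) to mean 0, SD 1 across time points
    (population SD). Zero-variance profiles are dropped.

    Accepts either a wide protein x time matrix or a tidy trajectory frame.
    """
    if {"protein", "time_min", "value"}.issubset(profiles.columns):
        profiles = trajectory_matrix(profiles)
    if profiles.shape[1] < 2:
        raise ValueError("need at least two time points per profile")
    matrix = profiles.dropna(axis=0)
    sd = matrix.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all profiles have zero variance")
    matrix = matrix[keep]
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd[keep], axis=0)


@dataclass
class ClusterResult:
    proteins: list
    c: int
    m: float
    membership: pd.DataFrame  # protein x cluster, rows sum to 1
    centroids: pd.DataFrame  # cluster x time
    objective: float
    objective_history: list = field(default_factory=list)
    n_iter: int = 0

    def hard_labels(self) -> pd.Series:
        """Hardened assignment: cluster of maximal membership per protein."""
        return self.membership.idxmax(axis=1).rename("cluster")

    def to_frame(self) -> pd.DataFrame:
        labels = self.hard_labels()
        return pd.DataFrame(
            {
                "protein": self.membership.index,
                "cluster": labels,
                "max_membership": self.membership.max(axis=1),
            }
        ).reset_index(drop=True)


def _memberships(dist2: np.ndarray, m: float) -> np.ndarray:
    """u_ij from squared distances, with the coincident-point convention
    (a point sitting on a centroid gets full membership there)."""
    n, c = dist2.shape
    u = np.zeros((n, c))
    zero = dist2 <= 0
    coincident = zero.any(axis=1)
    if coincident.any():
        rows = np.where(coincident)[0]
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    regular = ~coincident
    if regular.any():
        power = 1.0 / (m - 1.0)
        inv = dist2[regular] ** (-power)
        u[regular] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    X: pd.DataFrame | np.ndarray,
    c: int,
    m: float = DEFAULT_M,
    max_iter: int = 300,
    tol: float = 1e-5,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> ClusterResult:
    """Fuzzy c-means with seeded row-sampling initialization (or explicit
    ``init`` centroids of shape (c, n_times)).

    The objective J = sum_ij u_ij^m ||x_i - v_j||^2 is non-increasing across
    iterations (asserted); iteration stops when max |delta u| < tol.
    """
    if c < 2:
        raise ValueError("need at least two clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    data = np.asarray(X, dtype=float)
    n = data.shape[0]
    if c > n:
        raise ValueError(f"c={c} exceeds the number of profiles ({n})")

    if init is not None:
        centroids = np.array(init, dtype=float)
        if centroids.shape != (c, data.shape[1]):
            raise ValueError("init centroids must have shape (c, n_times)")
    else:
        rng = np.random.default_rng(seed)
        centroids = data[rng.choice(n, size=c, replace=False)]

    u_prev = None
    history: list[float] = []
    for iteration in range(1, max_iter + 1):
        dist2 = ((data[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _memberships(dist2, m)
        um = u**m
        objective = float((um * dist2).sum())
        if history and objective > history[-1] + 1e-9 * max(1.0, abs(history[-1])):
            raise AssertionError("fuzzy c-means objective increased")
        history.append(objective)
        denom = um.sum(axis=0)
        # empty cluster (possible at tiny n): keep its previous centroid
        nonempty = denom > 0
        centroids[nonempty] = (um.T[nonempty] @ data) / denom[nonempty, None]
        if u_prev is not None and np.max(np.abs(u - u_prev)) < tol:
            break
        u_prev = u

    cluster_ids = [f"C{j + 1}" for j in range(c)]
    membership = pd.DataFrame(u, index=index, columns=cluster_ids)
    columns = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(data.shape[1])
    return ClusterResult(
        proteins=list(index),
        c=c,
        m=m,
        membership=membership,
        centroids=pd.DataFrame(centroids, index=cluster_ids, columns=columns),
        objective=history[-1],
        objective_history=history,
        n_iter=iteration,
    )


def _min_centroid_distance(result: ClusterResult) -> float:
    v = result.centroids.to_numpy()
    d = np.sqrt(((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=2))
    return float(d[np.triu_indices(len(v), k=1)].min())


def select_cluster_number(
    X: pd.DataFrame | np.ndarray,
    c_range: Sequence[int],
    m: float = DEFAULT_M,
    seed: int = 0,
    criterion: str = "silhouette",
) -> int:
    """Pick the cluster count from ``c_range``.

    ``silhouette`` (default) maximizes the mean silhouette of the hardened
    assignment; ``dmin`` picks the elbow-free alternative of maximizing the
    minimum inter-centroid distance. Ties break toward smaller c.
    Deterministic given the seed.
    """
    data = np.asarray(X, dtype=float)
    if len(np.unique(data, axis=0)) < 2:
        raise ValueError("degenerate input: all profiles identical")
    scores: dict[int, float] = {}
    for c in sorted(c_range):
        result = fuzzy_cmeans(X, c=c, m=m, seed=seed)
        if criterion == "dmin":
            scores[c] = _min_centroid_distance(result)
            continue
        labels = result.membership.to_numpy().argmax(axis=1)
        if len(np.unique(labels)) < 2:
            scores[c] = -1.0
        else:
            scores[c] = float(silhouette_score(data, labels))
    return _best_c(scores)


def _best_c(scores: Mapping[int, float]) -> int:
    """Highest-scoring cluster count; exact ties break toward smaller c."""
    return max(sorted(scores), key=lambda c: (scores[c], -c))


def cluster_trajectories(
    trajectories: pd.DataFrame,
    c_range: Sequence[int] = range(2, 9),
    m: float = DEFAULT_M,
    seed: int = 0,
) -> ClusterResult:
    """Standardize a trajectory set, auto-select c, and cluster."""
    X = zscore_profiles(trajectories)
    c_range = [c for c in c_range if 2 <= c <= len(X) - 1]
    if not c_range:
        raise ValueError("c_range empty after bounding by profile count")
    c = select_cluster_number(X, c_range, m=m, seed=seed)
    return fuzzy_cmeans(X, c=c, m=m, seed=seed)


def estimate_fuzzifier(X: pd.DataFrame | np.ndarray) -> float:
    """Heuristic data-driven fuzzifier for omics profiles (dimension- and
    size-based); flagged as heuristic, default remains m = 2."""
    data = np.asarray(X, dtype=float)
    n, d = data.shape
    return float(1.0 + (1418.0 / n + 22.05) * d**-2 + (12.33 / n + 0.243) * d**-0.0406 * np.log(n) ** -0.1134)
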