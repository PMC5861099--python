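"""Group-level brain-state estimation by pooled k-means, with stability analysis.

Pooled edge-vector windows from all subjects are clustered into K states.
Clustering instability is quantified by repeatedly splitting the windows in
half (and independently subsampling half the edge dimensions), clustering
each half, and Hungarian-matching the two centroid sets; the summed matched
dissimilarity, averaged over replicates, is the instability at K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "StateAtlas",
    "InstabilityProfile",
    "state_names",
    "cluster_states",
    "centroid_dissimilarity_matrix",
    "match_centroids_hungarian",
    "instability_analysis",
    "identify_stable_solutions",
]


def state_names(K: int) -> list[str]:
    """Ordered names A, B, C, ... for a K-state solution."""
    if K > 26:
        raise ValueError("at most 26 states supported")
    return [chr(ord("A") + i) for i in range(K)]


@dataclass
class StateAtlas:
    """K centroid edge vectors for one clustering solution.

    States are ordered by descending occupancy (fraction of pooled windows
    assigned), so the first state — named A — is the most-expressed one.
    """

    K: int
    centroids: np.ndarray  # (K, E) on the Fisher-z scale
    state_labels: list[str]
    occupancy: np.ndarray  # (K,) fractions, descending
    pooled_window_count: int = 0
    seed: int = 0
    n_restarts: int = 10
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.centroids.shape[0] != self.K:
            raise ValueError("centroid count != K")
        if len(set(self.state_labels)) != self.K:
            raise ValueError("state labels must be unique")

    @property
    def n_edges(self) -> int:
        return self.centroids.shape[1]

    def index_of(self, label: str) -> int:
        return self.state_labels.index(label)


def cluster_states(
    pooled_windows: np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> StateAtlas:
    """Best-of-``n_restarts`` k-means (k-means++ init, squared Euclidean).

    Deterministic for a fixed seed.  Returned states are reordered by
    descending occupancy and named A, B, C, ...
    """
    X = np.asarray(pooled_windows, dtype=float)
    if X.ndim != 2:
        raise ValueError("pooled_windows must be (n_windows, n_edges)")
    if X.shape[0] < K:
        raise ValueError(f"{X.shape[0]} windows < K={K}")
    km = KMeans(
        n_clusters=K, n_init=n_restarts, random_state=seed, init="k-means++"
    ).fit(X)
    counts = np.bincount(km.labels_, minlength=K)
    order = np.argsort(-counts, kind="stable")
    return StateAtlas(
        K=K,
        centroids=km.cluster_centers_[order],
        state_labels=state_names(K),
        occupancy=counts[order] / counts.sum(),
        pooled_window_count=X.shape[0],
        seed=seed,
        n_restarts=n_restarts,
        inertia=float(km.inertia_),
    )


def _corr_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (A @ B.T) / np.outer(na, nb)
    C[~np.isfinite(C)] = 0.0  # zero-variance rows: define correlation as 0
    return C


def centroid_dissimilarity_matrix(
    centroids_a: np.ndarray, centroids_b: np.ndarray
) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between two centroid sets."""
    return 1.0 - _corr_rows(np.asarray(centroids_a), np.asarray(centroids_b))


def match_centroids_hungarian(
    atlas_a: StateAtlas | np.ndarray, atlas_b: StateAtlas | np.ndarray
) -> tuple[np.ndarray, float]:
    """Minimum-cost bijection between two equal-K centroid sets.

    Returns ``assignment`` (index into B for each state of A) and the summed
    matched dissimilarity (1 - Pearson r).
    """
    A = atlas_a.centroids if isinstance(atlas_a, StateAtlas) else np.asarray(atlas_a)
    B = atlas_b.centroids if isinstance(atlas_b, StateAtlas) else np.asarray(atlas_b)
    if A.shape[0] != B.shape[0]:
        raise ValueError("Hungarian matching requires equal K")
    cost = centroid_dissimilarity_matrix(A, B)
    rows, cols = linear_sum_assignment(cost)
    return cols[np.argsort(rows)], float(cost[rows, cols].sum())


@dataclass
class InstabilityProfile:
    K_range: list[int]
    instability: dict[int, float]
    n_replicates: int = 30
    resampling_axes: tuple[str, ...] = ("windows", "edges")
    replicate_costs: dict[int, np.ndarray] = field(default_factory=dict)


def instability_analysis(
    pooled_windows: np.ndarray,
    K_range,
    n_replicates: int = 30,
    seed: int = 0,
    edge_fraction: float = 0.5,
    n_restarts: int = 4,
) -> InstabilityProfile:
    """Split-resampling instability of the clustering across solution sizes.

    Per replicate: shuffle windows into two halves, draw ``edge_fraction``
    of the edge dimensions without replacement, cluster each half on the
    shared edge subspace, Hungarian-match the two centroid sets and record
    the total matched dissimilarity.  ``instability[K]`` is the mean over
    replicates.
    """
    X = np.asarray(pooled_windows, dtype=float)
    K_range = list(K_range)
    half = X.shape[0] // 2
    if half < max(K_range):
        raise ValueError("half-split smaller than the largest K requested")
    rng = np.random.default_rng(seed)
    E = X.shape[1]
    n_edge = max(2, int(round(E * edge_fraction)))
    costs: dict[int, list[float]] = {K: [] for K in K_range}
    for rep in range(n_replicates):
        perm = rng.permutation(X.shape[0])
        edges = rng.choice(E, size=n_edge, replace=False)
        Xa = X[np.ix_(perm[:half], edges)]
        Xb = X[np.ix_(perm[half : 2 * half], edges)]
        for K in K_range:
            atlas_a = cluster_states(Xa, K, seed=seed + rep, n_restarts=n_restarts)
            atlas_b = cluster_states(Xb, K, seed=seed + rep, n_restarts=n_restarts)
            _, cost = match_centroids_hungarian(atlas_a, atlas_b)
            costs[K].append(cost)
    return InstabilityProfile(
        K_range=K_range,
        instability={K: float(np.mean(v)) for K, v in costs.items()},
        n_replicates=n_replicates,
        replicate_costs={K: np.asarray(v) for K, v in costs.items()},
    )


def identify_stable_solutions(profile: InstabilityProfile) -> set[int]:
    """K values at strict local minima of the instability curve.

    Endpoints qualify only when strictly below their single neighbor.
    """
    Ks = profile.K_range
    if len(Ks) < 3:
        raise ValueError("need at least 3 K values")
    if sorted(Ks) != list(range(min(Ks), max(Ks) + 1)):
        raise ValueError("K_range must be contiguous")
    vals = [profile.instability[K] for K in Ks]
    stable = set()
    for i, K in enumerate(Ks):
        if i == 0:
            if vals[0] < vals[1]:
                stable.add(K)
        elif i == len(Ks) - 1:
            if vals[-1] < vals[-2]:
                stable.add(K)
        elif vals[i] < vals[i - 1] and vals[i] < vals[i + 1]:
            stable.add(K)
    return stable
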