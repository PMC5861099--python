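"""Hierarchical relations between adjacent clustering solutions.

A child (S+1)-state solution descends from a parent S-state solution when
two of its states are subdivisions of one parent state.  For every candidate
pair of child states we form a "hybrid" centroid (their element-wise mean),
Hungarian-match the resulting S-state set to the parent, and keep the pair
with minimal total matched dissimilarity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .state_atlas import StateAtlas, match_centroids_hungarian

__all__ = [
    "HierarchyMatch",
    "build_hybrid_atlas",
    "match_hierarchy_level",
    "build_hierarchy",
    "state_lineage",
]


@dataclass
class HierarchyMatch:
    parent_K: int
    child_K: int
    merged_pair: tuple[int, int]  # child state indices that merge
    assignment: dict[int, int]  # hybrid index -> parent index (bijection)
    parent_of: dict[int, int]  # every child state -> its parent state
    cost: float


def build_hybrid_atlas(
    child_atlas: StateAtlas, pair: tuple[int, int]
) -> StateAtlas:
    """Replace the two named child centroids by their element-wise mean."""
    i, j = sorted(pair)
    if i == j:
        raise ValueError("merged pair indices must be distinct")
    if not 0 <= i < j < child_atlas.K:
        raise ValueError(f"pair {pair} out of range for K={child_atlas.K}")
    centroids = []
    labels = []
    occupancy = []
    for k in range(child_atlas.K):
        if k == j:
            continue
        if k == i:
            centroids.append(
                0.5 * (child_atlas.centroids[i] + child_atlas.centroids[j])
            )
            labels.append(
                f"{child_atlas.state_labels[i]}+{child_atlas.state_labels[j]}"
            )
            occupancy.append(child_atlas.occupancy[i] + child_atlas.occupancy[j])
        else:
            centroids.append(child_atlas.centroids[k])
            labels.append(child_atlas.state_labels[k])
            occupancy.append(child_atlas.occupancy[k])
    return StateAtlas(
        K=child_atlas.K - 1,
        centroids=np.stack(centroids),
        state_labels=labels,
        occupancy=np.asarray(occupancy),
        pooled_window_count=child_atlas.pooled_window_count,
        seed=child_atlas.seed,
        n_restarts=child_atlas.n_restarts,
    )


def _hybrid_index_map(K: int, pair: tuple[int, int]) -> dict[int, int]:
    """Child state index -> index in the hybrid atlas."""
    i, j = sorted(pair)
    mapping = {}
    h = 0
    for k in range(K):
        if k == j:
            mapping[k] = mapping[i]
            continue
        mapping[k] = h
        h += 1
    return mapping


def match_hierarchy_level(
    parent_atlas: StateAtlas, child_atlas: StateAtlas
) -> HierarchyMatch:
    """Exhaustive pair search: which two child states subdivide a parent state.

    All K(K-1)/2 candidate pairs are hybridized and Hungarian-matched to the
    parent; the minimal-cost pair wins, with ties broken by the
    lexicographically smallest pair.
    """
    if child_atlas.K != parent_atlas.K + 1:
        raise ValueError(
            f"child K={child_atlas.K} must equal parent K={parent_atlas.K} + 1"
        )
    best: HierarchyMatch | None = None
    for pair in itertools.combinations(range(child_atlas.K), 2):
        hybrid = build_hybrid_atlas(child_atlas, pair)
        assignment, cost = match_centroids_hungarian(hybrid, parent_atlas)
        if best is None or cost < best.cost - 1e-15:
            idx_map = _hybrid_index_map(child_atlas.K, pair)
            parent_of = {
                c: int(assignment[idx_map[c]]) for c in range(child_atlas.K)
            }
            best = HierarchyMatch(
                parent_K=parent_atlas.K,
                child_K=child_atlas.K,
                merged_pair=pair,
                assignment={h: int(p) for h, p in enumerate(assignment)},
                parent_of=parent_of,
                cost=float(cost),
            )
    assert best is not None
    return best


def build_hierarchy(atlases: dict[int, StateAtlas]) -> list[HierarchyMatch]:
    """One HierarchyMatch per adjacent level over a contiguous K range."""
    Ks = sorted(atlases)
    if Ks != list(range(Ks[0], Ks[-1] + 1)):
        raise ValueError("atlas K range must be contiguous")
    return [
        match_hierarchy_level(atlases[K], atlases[K + 1]) for K in Ks[:-1]
    ]


def state_lineage(
    hierarchy: list[HierarchyMatch], start_K: int, state: int
) -> list[int]:
    """Trace a state of the deepest solution up through its ancestors.

    Returns the state's index at each level from ``start_K`` down to the
    shallowest parent in the hierarchy.
    """
    by_child_K = {m.child_K: m for m in hierarchy}
    lineage = [state]
    K = start_K
    while K in by_child_K:
        state = by_child_K[K].parent_of[state]
        lineage.append(state)
        K -= 1
    return lineage
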