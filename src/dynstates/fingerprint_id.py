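"""Connectome fingerprinting: reliability and rank-based identification.

Per-state mean connectivity profiles from two sessions are compared by
Pearson correlation.  Within-subject similarities (same subject, session 1
vs session 2) are tested against between-subject similarities, and a
permutation test asks whether subjects can be identified by maximal
similarity of their own two sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .state_dynamics import SubjectStateProfile

__all__ = [
    "IdentificationResult",
    "profile_similarity_distributions",
    "identification_rank_test",
    "concatenated_identification_rank_test",
]


@dataclass
class IdentificationResult:
    state: str
    identification_rate: float
    ranks: dict[str, int]  # subject -> rank of own session-2 profile (1 = best)
    p_value: float
    n_permutations: int
    null_rates: np.ndarray
    subject_ids: list[str]


def _state_vectors(
    profiles: Mapping[str, SubjectStateProfile] | Mapping[str, np.ndarray],
    state: str,
) -> dict[str, np.ndarray]:
    out = {}
    for sid, prof in profiles.items():
        if isinstance(prof, SubjectStateProfile):
            if state in prof.profiles:
                out[sid] = prof.profiles[state]
        else:
            out[sid] = np.asarray(prof, dtype=float)
    return out


def _similarity_matrix(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    a = v1 - v1.mean(axis=1, keepdims=True)
    b = v2 - v2.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("degenerate constant profile")
    return (a @ b.T) / np.outer(na, nb)


def profile_similarity_distributions(
    profiles_t1: Mapping,
    profiles_t2: Mapping,
    state: str,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Within- vs between-subject profile correlations plus a Welch t-test.

    A subject contributes a "within" value only when both sessions express
    the state; the "between" pool is symmetric (both orderings of every
    cross-subject pair).
    Returns (within r values, between r values, t statistic, p value).
    """
    v1 = _state_vectors(profiles_t1, state)
    v2 = _state_vectors(profiles_t2, state)
    common = [s for s in v1 if s in v2]
    if len(common) < 2:
        raise ValueError("need at least 2 subjects expressing the state in both sessions")
    M = _similarity_matrix(
        np.stack([v1[s] for s in common]), np.stack([v2[s] for s in common])
    )
    within = np.diag(M).copy()
    mask = ~np.eye(len(common), dtype=bool)
    between = M[mask]
    t, p = stats.ttest_ind(within, between, equal_var=False)
    return within, between, float(t), float(p)


def identification_rank_test(
    profiles_t1: Mapping,
    profiles_t2: Mapping,
    state: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> IdentificationResult:
    """Rank identification with a label-shuffling permutation null.

    For each subject, their session-1 profile is correlated with every
    session-2 profile; rank 1 means their own session-2 profile was the best
    match.  The identification rate is the fraction of rank-1 subjects.  The
    null shuffles session-2 subject labels ``n_permutations`` times and the
    p-value uses the add-one formula.
    """
    v1 = _state_vectors(profiles_t1, state)
    v2 = _state_vectors(profiles_t2, state)
    common = [s for s in v1 if s in v2]
    n = len(common)
    if n < 3:
        raise ValueError("need at least 3 subjects expressing the state in both sessions")
    M = _similarity_matrix(
        np.stack([v1[s] for s in common]), np.stack([v2[s] for s in common])
    )
    diag = np.diag(M)
    ranks = {
        sid: int(1 + np.sum(M[i] > diag[i]))
        for i, sid in enumerate(common)
    }
    row_max = M.argmax(axis=1)
    observed = float(np.mean(row_max == np.arange(n)))

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        # identification under shuffled session-2 labels: subject i's "own"
        # profile is column perm[i]
        null[b] = np.mean(row_max == perm)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_permutations)
    return IdentificationResult(
        state=state,
        identification_rate=observed,
        ranks=ranks,
        p_value=float(p),
        n_permutations=n_permutations,
        null_rates=null,
        subject_ids=common,
    )


def concatenated_identification_rank_test(
    profiles_t1: Mapping[str, SubjectStateProfile],
    profiles_t2: Mapping[str, SubjectStateProfile],
    states: list[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> IdentificationResult:
    """Pooled variant: identification on profiles concatenated across states.

    Extension beyond the per-state analysis: subjects contribute only if
    they express every listed state in both sessions; their per-state
    profiles are concatenated into one long vector per session before the
    standard rank test.
    """
    def concat(profiles):
        out = {}
        for sid, prof in profiles.items():
            if all(s in prof.profiles for s in states):
                out[sid] = np.concatenate([prof.profiles[s] for s in states])
        return out

    result = identification_rank_test(
        concat(profiles_t1),
        concat(profiles_t2),
        state="+".join(states),
        n_permutations=n_permutations,
        seed=seed,
    )
    return result
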