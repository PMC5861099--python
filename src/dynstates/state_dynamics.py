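"""Per-subject state assignment and temporal statistics.

Each subject's windows are labeled with the nearest atlas centroid (maximal
Pearson correlation of edge vectors).  From the resulting state sequences we
derive dwell fractions, persistence, the conditional switch matrix,
half-scan frequency shifts, and per-state mean connectivity profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .dfc_windows import WindowedConnectivity
from .state_atlas import StateAtlas

__all__ = [
    "StateSequence",
    "DwellTransitionSummary",
    "SubjectStateProfile",
    "assign_windows",
    "dwell_fractions",
    "transition_statistics",
    "half_scan_comparison",
    "subject_state_profiles",
]


@dataclass
class StateSequence:
    """Window-to-state labels for one run."""

    subject_id: str
    run_id: str
    labels: np.ndarray  # window-indexed array of state names
    K: int
    state_labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)

    def indices(self) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.state_labels)}
        return np.asarray([lookup[s] for s in self.labels], dtype=int)


@dataclass
class DwellTransitionSummary:
    state_labels: list[str]
    dwell_fraction: dict[str, float]
    persistence: dict[str, float]  # NaN when the state is never left from
    switch_matrix: np.ndarray  # (K, K) conditional switch probs, diag 0, NaN rows undefined
    defined_rows: np.ndarray  # bool mask: state had at least one outgoing switch
    n_switches: int
    n_windows: int


@dataclass
class SubjectStateProfile:
    subject_id: str
    visit_id: str
    profiles: dict[str, np.ndarray]  # only states the subject expressed
    counts: dict[str, int]  # window counts, zero for absent states

    def expressed(self) -> list[str]:
        return [s for s, c in self.counts.items() if c > 0]


def _windows_array(wc) -> np.ndarray:
    if isinstance(wc, WindowedConnectivity):
        return wc.edge_vectors()
    return np.asarray(wc, dtype=float)


def assign_windows(wc, atlas: StateAtlas, subject_id: str = "", run_id: str = "") -> StateSequence:
    """Label each window with the maximally correlated centroid.

    Ties resolve to the lowest-index (highest-occupancy) state.
    """
    X = _windows_array(wc)
    if X.shape[1] != atlas.n_edges:
        raise ValueError(
            f"window edge dimension {X.shape[1]} != atlas {atlas.n_edges}"
        )
    if isinstance(wc, WindowedConnectivity):
        subject_id = subject_id or wc.subject_id
        run_id = run_id or wc.run_id
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = atlas.centroids - atlas.centroids.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ Cc.T) / np.outer(
            np.linalg.norm(Xc, axis=1), np.linalg.norm(Cc, axis=1)
        )
    corr[~np.isfinite(corr)] = -np.inf
    idx = np.argmax(corr, axis=1)  # first max -> lowest-index tie rule
    return StateSequence(
        subject_id=subject_id,
        run_id=run_id,
        labels=np.asarray(atlas.state_labels)[idx],
        K=atlas.K,
        state_labels=list(atlas.state_labels),
    )


def _as_sequences(seqs) -> list[StateSequence]:
    if isinstance(seqs, StateSequence):
        return [seqs]
    return list(seqs)


def dwell_fractions(seqs: StateSequence | Iterable[StateSequence]) -> dict[str, float]:
    """Fraction of windows spent in each state (pooled across the given runs)."""
    seqs = _as_sequences(seqs)
    if not seqs or sum(len(s) for s in seqs) == 0:
        raise ValueError("empty state sequence")
    states = seqs[0].state_labels
    counts = {s: 0 for s in states}
    total = 0
    for seq in seqs:
        for s in seq.labels:
            counts[s] += 1
        total += len(seq)
    return {s: counts[s] / total for s in states}


def transition_statistics(
    seqs: StateSequence | Iterable[StateSequence],
) -> DwellTransitionSummary:
    """Dwell, persistence and the conditional switch matrix.

    Transitions are counted within runs only — run boundaries are never
    bridged.  ``persistence[s]`` is #(s->s) / #(transitions starting in s);
    the switch matrix row-normalizes off-diagonal counts over switches only.
    Rows for states with no observed outgoing switch are NaN and flagged in
    ``defined_rows``.
    """
    seqs = _as_sequences(seqs)
    states = seqs[0].state_labels
    K = len(states)
    counts = np.zeros((K, K), dtype=float)
    for seq in seqs:
        if len(seq) < 2:
            continue
        idx = seq.indices()
        np.add.at(counts, (idx[:-1], idx[1:]), 1.0)
    out_total = counts.sum(axis=1)
    persistence = {}
    for i, s in enumerate(states):
        persistence[s] = (
            float(counts[i, i] / out_total[i]) if out_total[i] > 0 else float("nan")
        )
    off = counts.copy()
    np.fill_diagonal(off, 0.0)
    row_switch = off.sum(axis=1)
    switch = np.full((K, K), np.nan)
    defined = row_switch > 0
    switch[defined] = off[defined] / row_switch[defined, None]
    n_switches = int(off.sum())
    return DwellTransitionSummary(
        state_labels=list(states),
        dwell_fraction=dwell_fractions(seqs),
        persistence=persistence,
        switch_matrix=switch,
        defined_rows=defined,
        n_switches=n_switches,
        n_windows=sum(len(s) for s in seqs),
    )


def half_scan_comparison(
    sequences_by_subject: Mapping[str, Sequence[StateSequence]],
    target_state: str,
):
    """Per-subject first- vs second-half frequency of a state, plus paired t.

    Each run is split at floor(W/2); frequencies are averaged across a
    subject's runs.  The paired t-statistic tests (second - first) across
    subjects and is omitted (None) with a single subject.
    """
    firsts, seconds, subject_ids = [], [], []
    for sid, seqs in sequences_by_subject.items():
        f, s = [], []
        for seq in _as_sequences(seqs):
            half = len(seq) // 2
            f.append(np.mean(seq.labels[:half] == target_state))
            s.append(np.mean(seq.labels[half:] == target_state))
        subject_ids.append(sid)
        firsts.append(float(np.mean(f)))
        seconds.append(float(np.mean(s)))
    per_subject = {
        sid: (f, s) for sid, f, s in zip(subject_ids, firsts, seconds)
    }
    if len(subject_ids) < 2:
        return per_subject, None, None
    t, p = stats.ttest_rel(seconds, firsts)
    return per_subject, float(t), float(p)


def subject_state_profiles(
    pairs: Sequence[tuple[object, StateSequence]] | tuple,
    subject_id: str = "",
    visit_id: str = "",
) -> SubjectStateProfile:
    """Per-state element-wise mean of a subject's windows assigned to the state.

    ``pairs`` is a list of (windows, sequence) per run; profiles pool across
    runs.  States with zero windows are flagged absent rather than
    zero-filled.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[1], StateSequence):
        pairs = [pairs]
    pairs = [(_windows_array(w), s) for w, s in pairs]
    states = pairs[0][1].state_labels
    sums: dict[str, np.ndarray] = {}
    counts = {s: 0 for s in states}
    for X, seq in pairs:
        if X.shape[0] != len(seq):
            raise ValueError("window count != sequence length")
        if not subject_id:
            subject_id = seq.subject_id
        for s in states:
            mask = seq.labels == s
            n = int(mask.sum())
            if n == 0:
                continue
            contrib = X[mask].sum(axis=0)
            sums[s] = sums.get(s, 0) + contrib
            counts[s] += n
    profiles = {s: sums[s] / counts[s] for s in sums}
    return SubjectStateProfile(
        subject_id=subject_id, visit_id=visit_id, profiles=profiles, counts=counts
    )
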