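"""Sliding-window connectivity estimation and edge vectorization.

A parcellated BOLD run (time x region matrix) is converted into a stack of
windowed, Fisher z-transformed correlation matrices.  Matrices are handled
in two interchangeable forms: full symmetric ``(R, R)`` arrays with a zero
diagonal, and flat "edge vectors" holding the upper triangle (row-major,
diagonal excluded).  The edge-vector form is the canonical representation
used by clustering, fingerprinting and prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcelTimeSeries",
    "WindowedConnectivity",
    "fisher_z_transform",
    "inverse_fisher_z",
    "sliding_window_correlations",
    "vectorize_connectivity",
    "devectorize_connectivity",
    "n_edges",
    "within_network_edge_indices",
    "between_network_edge_indices",
    "subsample_windows",
]

#: |r| is clipped to this value before arctanh so degenerate r = +/-1
#: stays finite while preserving ordering.
R_CLIP = 1.0 - 1e-7


@dataclass
class ParcelTimeSeries:
    """One run's time x region signal matrix plus region metadata."""

    values: np.ndarray
    region_ids: list[str]
    network_labels: dict[str, str]
    subject_id: str = ""
    run_id: str = ""
    visit_id: str = ""
    sampling_interval: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D time x region matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 regions")
        if self.values.shape[1] != len(self.region_ids):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.region_ids)} region ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing/non-finite entries")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def region_networks(self) -> list[str]:
        """Network label per region, in region order."""
        return [self.network_labels[r] for r in self.region_ids]


@dataclass
class WindowedConnectivity:
    """Per-run stack of Fisher-z correlation matrices, one per window."""

    z_matrices: np.ndarray  # (W, R, R), symmetric, zero diagonal
    window_width: int
    stride: int
    window_start_indices: np.ndarray
    region_ids: list[str] = field(default_factory=list)
    subject_id: str = ""
    run_id: str = ""
    visit_id: str = ""

    @property
    def n_windows(self) -> int:
        return self.z_matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.z_matrices.shape[1]

    def edge_vectors(self) -> np.ndarray:
        """(W, R(R-1)/2) stack of upper-triangle edge vectors."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.z_matrices[:, iu[0], iu[1]]


def fisher_z_transform(r):
    """arctanh variance-stabilizing transform, with |r| clipped to 1 - 1e-7."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    clipped = np.clip(r, -R_CLIP, R_CLIP)
    out = np.arctanh(clipped)
    return out if out.ndim else float(out)


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_z_transform` (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


def expected_window_count(n_timepoints: int, width: int, stride: int = 1) -> int:
    return (n_timepoints - width) // stride + 1


def sliding_window_correlations(
    ts: ParcelTimeSeries, width: int = 11, stride: int = 1
) -> WindowedConnectivity:
    """Windowed Pearson correlations of every region pair, Fisher z-transformed.

    Rectangular (untapered) windows of ``width`` samples advance by
    ``stride``; a run of T time points yields ``(T - width) // stride + 1``
    matrices.  The stored diagonal is zero by convention.
    """
    if width < 3:
        raise ValueError("window width must be >= 3")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    T = ts.n_timepoints
    if T < width:
        raise ValueError(f"run has {T} time points < window width {width}")
    starts = np.arange(0, T - width + 1, stride)
    R = ts.n_regions
    z = np.empty((len(starts), R, R), dtype=float)
    for w, s in enumerate(starts):
        seg = ts.values[s : s + width]
        sd = seg.std(axis=0)
        if np.any(sd == 0):
            bad = ts.region_ids[int(np.argmin(sd))]
            raise ValueError(
                f"zero variance in window {w} (start {s}) for region {bad}"
            )
        corr = np.corrcoef(seg, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        zm = fisher_z_transform(corr)
        zm = 0.5 * (zm + zm.T)  # enforce exact symmetry
        z[w] = zm
    return WindowedConnectivity(
        z_matrices=z,
        window_width=width,
        stride=stride,
        window_start_indices=starts,
        region_ids=list(ts.region_ids),
        subject_id=ts.subject_id,
        run_id=ts.run_id,
        visit_id=ts.visit_id,
    )


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def vectorize_connectivity(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle of a square symmetric matrix, row-major, diagonal excluded."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("input must be a square matrix")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def devectorize_connectivity(vector: np.ndarray) -> np.ndarray:
    """Reconstruct the symmetric zero-diagonal matrix from an edge vector."""
    vector = np.asarray(vector, dtype=float)
    L = vector.shape[0]
    R = int(round((1 + math.isqrt(1 + 8 * L)) / 2))
    if n_edges(R) != L:
        raise ValueError(f"edge vector length {L} is not R(R-1)/2 for integer R")
    mat = np.zeros((R, R), dtype=float)
    iu = np.triu_indices(R, k=1)
    mat[iu] = vector
    mat += mat.T
    return mat


def _edge_network_pairs(region_networks: list[str]) -> tuple[np.ndarray, np.ndarray]:
    nets = np.asarray(region_networks)
    iu = np.triu_indices(len(nets), k=1)
    return nets[iu[0]], nets[iu[1]]


def within_network_edge_indices(region_networks: list[str]) -> dict[str, np.ndarray]:
    """Map network name -> edge-vector indices of its within-network edges."""
    a, b = _edge_network_pairs(region_networks)
    out: dict[str, np.ndarray] = {}
    for net in dict.fromkeys(region_networks):  # preserve first-seen order
        out[net] = np.flatnonzero((a == net) & (b == net))
    return out


def between_network_edge_indices(
    region_networks: list[str],
) -> dict[tuple[str, str], np.ndarray]:
    """Map unordered network pair -> edge-vector indices of between-network edges."""
    a, b = _edge_network_pairs(region_networks)
    nets = list(dict.fromkeys(region_networks))
    out: dict[tuple[str, str], np.ndarray] = {}
    for i, ni in enumerate(nets):
        for nj in nets[i + 1 :]:
            mask = ((a == ni) & (b == nj)) | ((a == nj) & (b == ni))
            out[(ni, nj)] = np.flatnonzero(mask)
    return out


def subsample_windows(
    wc: WindowedConnectivity, mode: str = "stride", rate: float = 0.1
) -> WindowedConnectivity:
    """Thin the window stack before pooled clustering.

    ``stride`` keeps every ceil(1/rate)-th window starting at the first.
    ``variance_maxima`` keeps windows whose across-edge variance is a strict
    local maximum over window index, truncating or padding (largest variance
    first) to the count the stride mode would select.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    W = wc.n_windows
    step = math.ceil(1.0 / rate)
    stride_idx = np.arange(0, W, step)
    if mode == "stride":
        keep = stride_idx
    elif mode == "variance_maxima":
        target = len(stride_idx)
        var = wc.edge_vectors().var(axis=1)
        maxima = [
            i
            for i in range(1, W - 1)
            if var[i] > var[i - 1] and var[i] > var[i + 1]
        ]
        maxima.sort(key=lambda i: -var[i])
        keep_list = maxima[:target]
        if len(keep_list) < target:
            rest = sorted(set(range(W)) - set(keep_list), key=lambda i: -var[i])
            keep_list += rest[: target - len(keep_list)]
        keep = np.sort(np.asarray(keep_list, dtype=int))
    else:
        raise ValueError(f"unknown subsampling mode {mode!r}")
    if keep.size == 0:
        raise ValueError("subsampling selected no windows")
    return WindowedConnectivity(
        z_matrices=wc.z_matrices[keep],
        window_width=wc.window_width,
        stride=wc.stride,
        window_start_indices=wc.window_start_indices[keep],
        region_ids=list(wc.region_ids),
        subject_id=wc.subject_id,
        run_id=wc.run_id,
        visit_id=wc.visit_id,
    )


def local_variance_maxima(variance: np.ndarray) -> list[int]:
    """Indices of strict local maxima of a 1-D variance profile (interior only)."""
    variance = np.asarray(variance, dtype=float)
    return [
        i
        for i in range(1, len(variance) - 1)
        if variance[i] > variance[i - 1] and variance[i] > variance[i + 1]
    ]
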