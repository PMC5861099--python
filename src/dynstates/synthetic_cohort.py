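"""Synthetic multi-subject cohort generator with known latent state structure.

Time series are emitted by a Markov chain switching among K latent
covariance states at time-point resolution.  The generator plants every
signal the downstream analyses look for, and returns the ground truth
needed to verify recovery:

* block-structured state covariances, one muted "attractor" state;
* stable subject-specific edge perturbations (fingerprints) reused across
  runs and visits;
* patient-group reductions of within-network coupling confined to chosen
  (state, network) cells;
* a binary symptom label drawn from a logistic model on the true edge
  strength of one designated state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .dfc_windows import fisher_z_transform, n_edges, vectorize_connectivity

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "GroundTruth",
    "default_network_labels",
    "block_correlation_matrix",
    "spd_repair",
    "generate_state_covariances",
    "stationary_distribution",
    "simulate_state_sequence",
    "window_majority_sequence",
    "simulate_subject_timeseries",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

from .dfc_windows import ParcelTimeSeries

#: PANSS-like generator defaults (positive/negative/general scale means and
#: SDs for symptomatic vs non-symptomatic patients).
PANSS_PARAMS = {
    "positive": {"active": (19.90, 5.67), "inactive": (8.88, 2.20)},
    "negative": {"active": (13.98, 7.76), "inactive": (10.18, 3.93)},
    "general": {"active": (31.46, 7.81), "inactive": (26.53, 7.74)},
}

SPD_EIG_FLOOR = 1e-6


def default_network_labels(
    n_regions: int = 114, n_networks: int | None = None
) -> dict[str, str]:
    """Region -> network map: two hemispheres, contiguous network blocks.

    Defaults mimic a 114-region / 17-network cortical parcellation with 57
    regions per hemisphere; for smaller region counts the network count
    shrinks to at most half the regions per hemisphere.
    """
    if n_regions % 2 != 0:
        raise ValueError("n_regions must be even (two hemispheres)")
    half = n_regions // 2
    if n_networks is None:
        n_networks = min(17, max(1, half // 2))
    if n_networks > half:
        raise ValueError("more networks than regions per hemisphere")
    labels: dict[str, str] = {}
    for hemi, offset in (("L", 0), ("R", half)):
        for i in range(half):
            net = min(i * n_networks // half, n_networks - 1)
            labels[f"{hemi}{i + 1:03d}"] = f"net{net + 1:02d}"
    # keys ordered L then R; dict preserves insertion order
    return labels


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; every field has a usable default."""

    n_regions: int = 114
    network_labels: dict[str, str] | None = None
    n_states: int = 4
    attractor_state: int = 0
    transition_matrix: np.ndarray | None = None
    state_covariances: list[np.ndarray] | None = None
    n_controls: int = 10
    n_patients: int = 10
    fingerprint_sd: float = 0.02
    group_effect: dict[tuple[int, str], float] = field(default_factory=dict)
    symptom_state: int = 1
    symptom_edges: np.ndarray | None = None
    symptom_effect_size: float = 1.0
    # SD of the per-subject perturbation on symptom edges, applied to the
    # symptom state ONLY (the shared fingerprint is zeroed there), so the
    # planted label signal is specific to one state
    symptom_signal_sd: float = 0.25
    n_timepoints: int = 120
    runs_per_subject: int = 1
    visits_per_subject: int = 1
    observation_noise_sd: float = 0.1
    ar_coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.network_labels is None:
            self.network_labels = default_network_labels(self.n_regions)
        if len(self.network_labels) != self.n_regions:
            raise ValueError("network_labels must cover every region")
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(
                self.n_states, self.attractor_state
            )
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)

    @property
    def region_ids(self) -> list[str]:
        return list(self.network_labels)

    @property
    def region_networks(self) -> list[str]:
        return list(self.network_labels.values())

    @property
    def networks(self) -> list[str]:
        return list(dict.fromkeys(self.network_labels.values()))

    def validate(self) -> None:
        P = self.transition_matrix
        if P.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape does not match n_states")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1 (+/- 1e-12)")
        if self.n_timepoints < 11:
            raise ValueError("n_timepoints must be >= window width (11)")
        if self.fingerprint_sd < 0 or self.observation_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not 0 <= self.attractor_state < self.n_states:
            raise ValueError("attractor_state out of range")
        if not 0 <= self.symptom_state < self.n_states:
            raise ValueError("symptom_state out of range")
        if self.state_covariances is not None:
            for k, C in enumerate(self.state_covariances):
                C = np.asarray(C)
                if C.shape != (self.n_regions, self.n_regions):
                    raise ValueError(f"state covariance {k} has wrong shape")
                if not np.allclose(C, C.T):
                    raise ValueError(f"state covariance {k} is not symmetric")
                if not np.allclose(np.diag(C), 1.0):
                    raise ValueError(f"state covariance {k} lacks unit diagonal")
                if np.linalg.eigvalsh(C).min() <= 0:
                    raise ValueError(f"state covariance {k} is not positive definite")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "control" | "patient"
    covariates: dict[str, float]
    runs: list[ParcelTimeSeries]
    active_psychosis: int | None = None
    panss: dict[str, float] | None = None


@dataclass
class GroundTruth:
    """Planted structure: what a perfect analysis should recover."""

    state_sequences: dict[tuple[str, str], np.ndarray]  # (subject, run) -> timepoint labels
    centroids: np.ndarray  # (K, E) Fisher-z edge vectors of state correlations
    fingerprints: dict[str, np.ndarray]  # subject -> (E,) edge perturbation
    symptom_perturbations: dict[str, np.ndarray]  # subject -> values on symptom edges
    symptom_edges: np.ndarray
    symptom_state: int
    attractor_state: int

    def window_sequences(self, width: int = 11, stride: int = 1) -> dict:
        """Truth at window resolution: majority state within each window."""
        return {
            key: window_majority_sequence(seq, width, stride)
            for key, seq in self.state_sequences.items()
        }


def default_transition_matrix(
    n_states: int,
    attractor_state: int = 0,
    self_attractor: float = 0.95,
    self_other: float = 0.94,
    attractor_pull: float = 1.5,
) -> np.ndarray:
    """Row-stochastic matrix with one sticky attractor drawing transitions.

    High self-transition probabilities keep typical dwell episodes longer
    than the 11-point analysis window, so windowed estimates see mostly
    pure-state epochs.
    """
    P = np.zeros((n_states, n_states))
    for i in range(n_states):
        self_p = self_attractor if i == attractor_state else self_other
        others = [j for j in range(n_states) if j != i]
        leave = 1.0 - self_p
        weights = np.array(
            [attractor_pull if j == attractor_state else 1.0 for j in others],
            dtype=float,
        )
        P[i, others] = leave * weights / weights.sum()
        P[i, i] = self_p
    return P


def block_correlation_matrix(
    region_networks: list[str],
    within: dict[str, float] | float,
    between: float = 0.0,
) -> np.ndarray:
    """Unit-diagonal matrix with constant within-/between-network blocks."""
    nets = np.asarray(region_networks)
    R = len(nets)
    if np.isscalar(within):
        within = {n: float(within) for n in dict.fromkeys(region_networks)}
    mat = np.full((R, R), float(between))
    for net, val in within.items():
        idx = np.flatnonzero(nets == net)
        mat[np.ix_(idx, idx)] = val
    np.fill_diagonal(mat, 1.0)
    return mat


def spd_repair(mat: np.ndarray, floor: float = SPD_EIG_FLOOR) -> np.ndarray:
    """Floor the eigenvalues at ``floor``, then renormalize to unit diagonal."""
    mat = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(mat)
    vals = np.maximum(vals, floor)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    if np.linalg.eigvalsh(out).min() <= 0:
        raise ValueError("matrix is not positive definite after SPD repair")
    return out


def generate_state_covariances(spec: CohortSpec) -> list[np.ndarray]:
    """K block-structured SPD correlation matrices; the attractor is muted.

    The attractor carries uniformly low within-network coupling plus a weak
    checkerboard of negative between-network couplings (muted amplitude but
    a distinctive shape, so correlation-based matching can discriminate it).
    Each other state boosts a rotating disjoint pair of networks with strong
    within/cross coupling and fixed-amplitude couplings to the last two
    networks; the symmetry keeps the non-attractor states roughly
    equidistant from one another, which makes the planted K the stable
    clustering solution.
    """
    if spec.state_covariances is not None:
        return [np.asarray(C, dtype=float) for C in spec.state_covariances]
    nets = spec.networks
    region_networks = spec.region_networks
    rn = np.asarray(region_networks)
    n_nets = len(nets)

    def set_block(mat: np.ndarray, a: str, b: str, value: float) -> None:
        ia = np.flatnonzero(rn == a)
        ib = np.flatnonzero(rn == b)
        mat[np.ix_(ia, ib)] = value
        mat[np.ix_(ib, ia)] = value

    covs = []
    rank = 0
    for k in range(spec.n_states):
        if k == spec.attractor_state:
            mat = block_correlation_matrix(
                region_networks, {n: 0.15 for n in nets}, 0.0
            )
            for i in range(n_nets):
                for j in range(i + 1, n_nets):
                    if (i + j) % 2 == 0:
                        set_block(mat, nets[i], nets[j], -0.12)
        else:
            b1 = nets[(2 * rank) % n_nets]
            b2 = nets[(2 * rank + 1) % n_nets]
            within = {n: (0.65 if n in (b1, b2) else 0.2) for n in nets}
            mat = block_correlation_matrix(region_networks, within, 0.0)
            set_block(mat, b1, b2, 0.45)
            for target, value in ((nets[-2], -0.3), (nets[-1], 0.2)):
                if n_nets > 2 and target not in (b1, b2):
                    set_block(mat, b1, target, value)
                    set_block(mat, b2, target, value)
            rank += 1
        covs.append(spd_repair(mat))
    return covs


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution via the leading left eigenvector."""
    P = np.asarray(transition_matrix, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_state_sequence(
    transition_matrix: np.ndarray, length: int, seed=None
) -> np.ndarray:
    """Markov chain of state indices; initial state from the stationary law."""
    P = np.asarray(transition_matrix, dtype=float)
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    rng = np.random.default_rng(seed)
    K = P.shape[0]
    cum = np.cumsum(P, axis=1)
    seq = np.empty(length, dtype=int)
    pi = stationary_distribution(P)
    seq[0] = rng.choice(K, p=pi)
    u = rng.random(length - 1)
    for t in range(1, length):
        seq[t] = int(np.searchsorted(cum[seq[t - 1]], u[t - 1], side="right"))
    return seq


def window_majority_sequence(
    states: np.ndarray, width: int = 11, stride: int = 1
) -> np.ndarray:
    """Window-resolution truth: the majority state within each window.

    Ties resolve to the smallest state index.
    """
    states = np.asarray(states, dtype=int)
    n_win = (len(states) - width) // stride + 1
    out = np.empty(n_win, dtype=int)
    for w in range(n_win):
        seg = states[w * stride : w * stride + width]
        out[w] = int(np.argmax(np.bincount(seg)))
    return out


def _subject_covariances(
    spec: CohortSpec,
    base_covs: list[np.ndarray],
    fingerprint: np.ndarray,
    is_patient: bool,
    symptom_matrix: np.ndarray | None = None,
) -> list[np.ndarray]:
    """State covariances with the subject fingerprint (and patient deltas) applied.

    ``symptom_matrix`` is added to the symptom state's covariance only.
    """
    nets = np.asarray(spec.region_networks)
    covs = []
    for k, C in enumerate(base_covs):
        M = C + fingerprint
        if symptom_matrix is not None and k == spec.symptom_state:
            M = M + symptom_matrix
        if is_patient:
            for (state, net), delta in spec.group_effect.items():
                if state != k:
                    continue
                idx = np.flatnonzero(nets == net)
                block = np.ix_(idx, idx)
                off = np.ones((len(idx), len(idx))) - np.eye(len(idx))
                M[block] = M[block] + delta * off
        covs.append(spd_repair(M))
    return covs


def _draw_fingerprint(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    R = spec.n_regions
    F = np.zeros((R, R))
    iu = np.triu_indices(R, k=1)
    F[iu] = rng.normal(0.0, spec.fingerprint_sd, size=len(iu[0]))
    return F + F.T


def simulate_subject_timeseries(
    spec: CohortSpec,
    subject_covs: list[np.ndarray],
    seed,
    subject_id: str = "",
) -> tuple[list[ParcelTimeSeries], dict[str, np.ndarray]]:
    """Simulate every run of one subject from their state covariances.

    Returns the runs and a map run_id -> true time-point state sequence.
    Draws are zero-mean Gaussian conditional on the latent state, with an
    optional AR(1) smoothing of the innovations and additive white
    observation noise.
    """
    rng = np.random.default_rng(seed)
    chols = [np.linalg.cholesky(C) for C in subject_covs]
    phi = spec.ar_coefficient
    runs, truth = [], {}
    for visit in range(spec.visits_per_subject):
        for run in range(spec.runs_per_subject):
            seq = simulate_state_sequence(
                spec.transition_matrix, spec.n_timepoints, rng
            )
            innov = rng.standard_normal((spec.n_timepoints, spec.n_regions))
            if phi:
                e = np.empty_like(innov)
                e[0] = innov[0]
                s = np.sqrt(1.0 - phi**2)
                for t in range(1, spec.n_timepoints):
                    e[t] = phi * e[t - 1] + s * innov[t]
                innov = e
            x = np.empty_like(innov)
            for t in range(spec.n_timepoints):
                x[t] = chols[seq[t]] @ innov[t]
            if spec.observation_noise_sd:
                x += rng.normal(
                    0.0, spec.observation_noise_sd, size=x.shape
                )
            run_id = f"v{visit + 1}r{run + 1}"
            runs.append(
                ParcelTimeSeries(
                    values=x,
                    region_ids=spec.region_ids,
                    network_labels=dict(spec.network_labels),
                    subject_id=subject_id,
                    run_id=run_id,
                    visit_id=f"v{visit + 1}",
                )
            )
            truth[run_id] = seq
    return runs, truth


def _default_symptom_edges(spec: CohortSpec, n_edges_total: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 987654321]))
    k = max(5, min(40, n_edges_total // 10))
    return np.sort(rng.choice(n_edges_total, size=k, replace=False))


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate the full cohort and its ground truth, deterministically."""
    spec.validate()
    n_subjects = spec.n_controls + spec.n_patients
    if n_subjects == 0:
        raise ValueError("cohort must contain at least one subject")
    base_covs = generate_state_covariances(spec)
    E = n_edges(spec.n_regions)
    symptom_edges = (
        np.asarray(spec.symptom_edges, dtype=int)
        if spec.symptom_edges is not None
        else _default_symptom_edges(spec, E)
    )

    root = np.random.SeedSequence(spec.seed)
    subj_seeds = root.spawn(n_subjects)

    groups = ["control"] * spec.n_controls + ["patient"] * spec.n_patients
    fingerprints: dict[str, np.ndarray] = {}
    symptom_perturbations: dict[str, np.ndarray] = {}
    subj_covs: dict[str, list[np.ndarray]] = {}
    covariates: dict[str, dict[str, float]] = {}
    ids = [f"S{i + 1:04d}" for i in range(n_subjects)]

    R = spec.n_regions
    iu_full = np.triu_indices(R, k=1)
    for sid, grp, ss in zip(ids, groups, subj_seeds):
        rng = np.random.default_rng(ss.spawn(1)[0])
        F = _draw_fingerprint(spec, rng)
        # fingerprints stay off the symptom edges; the symptom perturbation
        # (applied to the symptom state only) owns that variance
        F[iu_full[0][symptom_edges], iu_full[1][symptom_edges]] = 0.0
        F[iu_full[1][symptom_edges], iu_full[0][symptom_edges]] = 0.0
        fingerprints[sid] = F
        delta = rng.normal(0.0, spec.symptom_signal_sd, size=len(symptom_edges))
        symptom_perturbations[sid] = delta
        D = np.zeros((R, R))
        D[iu_full[0][symptom_edges], iu_full[1][symptom_edges]] = delta
        D = D + D.T
        subj_covs[sid] = _subject_covariances(
            spec, base_covs, F, grp == "patient", symptom_matrix=D
        )
        covariates[sid] = {
            "age": float(rng.normal(30.0, 8.0)),
            "sex": float(rng.integers(0, 2)),
            "motion": float(np.abs(rng.normal(0.05, 0.02))),
        }

    # Symptom labels for patients from the logistic model on the TRUE
    # symptom-state edge strengths (z-scored across patients).
    label_rng = np.random.default_rng(root.spawn(1)[0])
    patient_ids = [sid for sid, g in zip(ids, groups) if g == "patient"]
    active: dict[str, int] = {}
    if patient_ids:
        strengths = np.array(
            [
                fisher_z_transform(
                    np.clip(
                        vectorize_connectivity(
                            subj_covs[sid][spec.symptom_state]
                        )[symptom_edges],
                        -0.999999,
                        0.999999,
                    )
                ).sum()
                for sid in patient_ids
            ]
        )
        sd = strengths.std()
        zs = (strengths - strengths.mean()) / sd if sd > 0 else np.zeros_like(strengths)
        probs = expit(spec.symptom_effect_size * zs)
        draws = label_rng.random(len(patient_ids))
        for sid, p, u in zip(patient_ids, probs, draws):
            active[sid] = int(u < p)

    subjects: list[SubjectRecord] = []
    sequences: dict[tuple[str, str], np.ndarray] = {}
    for sid, grp, ss in zip(ids, groups, subj_seeds):
        runs, truth = simulate_subject_timeseries(
            spec, subj_covs[sid], ss.spawn(2)[1], subject_id=sid
        )
        for run_id, seq in truth.items():
            sequences[(sid, run_id)] = seq
        rec = SubjectRecord(
            subject_id=sid, group=grp, covariates=covariates[sid], runs=runs
        )
        if grp == "patient":
            rec.active_psychosis = active[sid]
            prng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, int(sid[1:]), 7])
            )
            status = "active" if active[sid] else "inactive"
            rec.panss = {
                scale: float(
                    max(params[status][0] + prng.normal(0.0, params[status][1]), 7.0)
                )
                for scale, params in PANSS_PARAMS.items()
            }
        subjects.append(rec)

    iu = np.triu_indices(spec.n_regions, k=1)
    truth = GroundTruth(
        state_sequences=sequences,
        centroids=np.stack(
            [fisher_z_transform(vectorize_connectivity(C)) for C in base_covs]
        ),
        fingerprints={sid: F[iu] for sid, F in fingerprints.items()},
        symptom_perturbations=symptom_perturbations,
        symptom_edges=symptom_edges,
        symptom_state=spec.symptom_state,
        attractor_state=spec.attractor_state,
    )
    return subjects, truth


# ---------------------------------------------------------------------------
# text-format I/O


def write_cohort(
    subjects: list[SubjectRecord], truth: GroundTruth, outdir
) -> Path:
    """One TSV per run, a manifest CSV and a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in subjects:
        for ts in rec.runs:
            fname = f"{rec.subject_id}_{ts.run_id}.tsv"
            pd.DataFrame(ts.values, columns=ts.region_ids).to_csv(
                outdir / fname, sep="\t", index=False
            )
            row = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "run_id": ts.run_id,
                "visit_id": ts.visit_id,
                "active_psychosis": rec.active_psychosis,
                "path": fname,
            }
            row.update(rec.covariates)
            if rec.panss:
                row.update({f"panss_{k}": v for k, v in rec.panss.items()})
            rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    networks = subjects[0].runs[0].network_labels
    gt = {
        "state_sequences": {
            f"{s}|{r}": seq.tolist() for (s, r), seq in truth.state_sequences.items()
        },
        "centroids": truth.centroids.tolist(),
        "fingerprints": {s: f.tolist() for s, f in truth.fingerprints.items()},
        "symptom_perturbations": {
            s: d.tolist() for s, d in truth.symptom_perturbations.items()
        },
        "symptom_edges": truth.symptom_edges.tolist(),
        "symptom_state": int(truth.symptom_state),
        "attractor_state": int(truth.attractor_state),
        "network_labels": networks,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh)
    return outdir


def read_cohort(indir) -> tuple[list[SubjectRecord], GroundTruth | None]:
    """Inverse of :func:`write_cohort`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    gt_path = indir / "ground_truth.json"
    networks = None
    truth = None
    if gt_path.exists():
        with open(gt_path) as fh:
            gt = json.load(fh)
        networks = gt["network_labels"]
        truth = GroundTruth(
            state_sequences={
                tuple(k.split("|")): np.asarray(v, dtype=int)
                for k, v in gt["state_sequences"].items()
            },
            centroids=np.asarray(gt["centroids"]),
            fingerprints={
                s: np.asarray(f) for s, f in gt["fingerprints"].items()
            },
            symptom_perturbations={
                s: np.asarray(d) for s, d in gt["symptom_perturbations"].items()
            },
            symptom_edges=np.asarray(gt["symptom_edges"], dtype=int),
            symptom_state=gt["symptom_state"],
            attractor_state=gt["attractor_state"],
        )
    covariate_cols = [
        c
        for c in manifest.columns
        if c
        not in {"subject_id", "group", "run_id", "visit_id", "active_psychosis", "path"}
        and not c.startswith("panss_")
    ]
    panss_cols = [c for c in manifest.columns if c.startswith("panss_")]
    subjects = []
    for sid, sub in manifest.groupby("subject_id", sort=False):
        runs = []
        for _, row in sub.iterrows():
            df = pd.read_csv(indir / row["path"], sep="\t")
            if networks is None:
                networks = {c: "net01" for c in df.columns}
            runs.append(
                ParcelTimeSeries(
                    values=df.to_numpy(),
                    region_ids=list(df.columns),
                    network_labels=networks,
                    subject_id=sid,
                    run_id=row["run_id"],
                    visit_id=row["visit_id"],
                )
            )
        first = sub.iloc[0]
        rec = SubjectRecord(
            subject_id=sid,
            group=first["group"],
            covariates={c: float(first[c]) for c in covariate_cols},
            runs=runs,
            active_psychosis=(
                None
                if pd.isna(first["active_psychosis"])
                else int(first["active_psychosis"])
            ),
            panss=(
                {c.removeprefix("panss_"): float(first[c]) for c in panss_cols}
                if panss_cols and not pd.isna(first.get(panss_cols[0]))
                else None
            ),
        )
        subjects.append(rec)
    return subjects, truth
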