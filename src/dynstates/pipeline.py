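"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes simulate -> windows -> cluster -> hierarchy ->
dynamics -> fingerprint -> groupdiff -> predict on a single JSON-style
configuration, writing per-stage outputs plus a provenance record, all
reproducible from the configured seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dfc_windows import (
    sliding_window_correlations,
    subsample_windows,
    within_network_edge_indices,
)
from .fingerprint_id import identification_rank_test, profile_similarity_distributions
from .group_stats import (
    dwell_group_tests,
    edgewise_group_differences,
    network_level_tests,
    network_summary,
)
from .state_atlas import cluster_states, identify_stable_solutions, instability_analysis
from .state_dynamics import (
    assign_windows,
    dwell_fractions,
    subject_state_profiles,
    transition_statistics,
)
from .state_hierarchy import build_hierarchy
from .symptom_prediction import (
    fit_predict_loocv,
    holdout_evaluate,
    roc_auc,
    stratified_split,
    train_model_bundle,
)
from .synthetic_cohort import CohortSpec, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger("dynstates")

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = (
    "simulate",
    "windows",
    "cluster",
    "hierarchy",
    "dynamics",
    "fingerprint",
    "groupdiff",
    "predict",
)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    cohort_dir: str | None = None  # read an existing cohort instead of simulating
    seed: int = 0
    # cohort generation (forwarded to CohortSpec)
    cohort: dict = field(default_factory=dict)
    # windowing
    window_width: int = 11
    stride: int = 1
    subsample_mode: str = "stride"
    subsample_rate: float = 0.1
    # clustering
    k_min: int = 2
    k_max: int = 8
    n_replicates: int = 10
    n_restarts: int = 10
    analysis_k: int = 4
    # statistics
    covariate_names: list[str] = field(default_factory=lambda: ["age", "sex", "motion"])
    n_permutations: int = 200
    test_fraction: float = 0.3
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _write_provenance(stage_dir: Path, stage: str, inputs: dict) -> None:
    record = {
        "stage": stage,
        "version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
    }
    with open(stage_dir / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the enabled stages in dependency order; returns stage -> output dir."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    stages = [s for s in ALL_STAGES if s in config.stages]

    # --- simulate / load cohort -------------------------------------------
    if "simulate" in stages:
        stage_dir = out_root / "cohort"
        spec = CohortSpec(seed=config.seed, **config.cohort)
        subjects, truth = generate_cohort(spec)
        write_cohort(subjects, truth, stage_dir)
        _write_provenance(stage_dir, "simulate", {"seed": config.seed})
        manifest["simulate"] = stage_dir
        logger.info("simulate: %d subjects -> %s", len(subjects), stage_dir)
    elif config.cohort_dir:
        subjects, truth = read_cohort(config.cohort_dir)
    else:
        raise ValueError("either enable the simulate stage or set cohort_dir")

    region_networks = subjects[0].runs[0].region_networks
    remaining = [s for s in stages if s != "simulate"]
    if not remaining:
        return manifest

    # --- windows -----------------------------------------------------------
    windows_by_run: dict[tuple[str, str], object] = {}
    for rec in subjects:
        for ts in rec.runs:
            windows_by_run[(rec.subject_id, ts.run_id)] = sliding_window_correlations(
                ts, width=config.window_width, stride=config.stride
            )
    if "windows" in stages:
        stage_dir = out_root / "windows"
        stage_dir.mkdir(exist_ok=True)
        meta = {
            "window_width": config.window_width,
            "stride": config.stride,
            "edge_ordering": "row-major upper triangle, diagonal excluded",
            "n_windows_per_run": {
                f"{s}|{r}": wc.n_windows for (s, r), wc in windows_by_run.items()
            },
        }
        with open(stage_dir / "windows_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        _write_provenance(stage_dir, "windows", {"width": config.window_width})
        manifest["windows"] = stage_dir

    # --- cluster -----------------------------------------------------------
    pooled = np.concatenate(
        [
            subsample_windows(
                wc, mode=config.subsample_mode, rate=config.subsample_rate
            ).edge_vectors()
            for wc in windows_by_run.values()
        ]
    )
    atlases = {
        K: cluster_states(pooled, K, seed=config.seed, n_restarts=config.n_restarts)
        for K in range(config.k_min, config.k_max + 1)
    }
    if "cluster" in stages:
        stage_dir = out_root / "atlas"
        stage_dir.mkdir(exist_ok=True)
        profile = instability_analysis(
            pooled,
            range(config.k_min, config.k_max + 1),
            n_replicates=config.n_replicates,
            seed=config.seed,
        )
        pd.DataFrame(
            {
                "K": profile.K_range,
                "instability": [profile.instability[K] for K in profile.K_range],
            }
        ).to_csv(stage_dir / "instability.csv", index=False)
        for K, atlas in atlases.items():
            pd.DataFrame(
                atlas.centroids.T, columns=atlas.state_labels
            ).to_csv(stage_dir / f"centroids_K{K}.csv", index=False)
        with open(stage_dir / "atlas.json", "w") as fh:
            json.dump(
                {
                    "k_range": list(atlases),
                    "seed": config.seed,
                    "pooled_window_count": int(pooled.shape[0]),
                    "occupancy": {
                        K: atlases[K].occupancy.tolist() for K in atlases
                    },
                    "stable_solutions": sorted(identify_stable_solutions(profile)),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        _write_provenance(stage_dir, "cluster", {"seed": config.seed})
        manifest["cluster"] = stage_dir

    # --- hierarchy ---------------------------------------------------------
    if "hierarchy" in stages:
        stage_dir = out_root / "hierarchy"
        stage_dir.mkdir(exist_ok=True)
        matches = build_hierarchy(atlases)
        with open(stage_dir / "hierarchy.json", "w") as fh:
            json.dump(
                [
                    {
                        "parent_K": m.parent_K,
                        "child_K": m.child_K,
                        "merged_pair": list(m.merged_pair),
                        "assignment": {str(k): v for k, v in m.assignment.items()},
                        "parent_of": {str(k): v for k, v in m.parent_of.items()},
                        "cost": m.cost,
                    }
                    for m in matches
                ],
                fh,
                indent=2,
                sort_keys=True,
            )
        pd.DataFrame(
            [
                {"child_K": m.child_K, "child_state": c, "parent_state": p}
                for m in matches
                for c, p in m.parent_of.items()
            ]
        ).to_csv(stage_dir / "parent_child_edges.csv", index=False)
        _write_provenance(stage_dir, "hierarchy", {})
        manifest["hierarchy"] = stage_dir

    # --- dynamics ----------------------------------------------------------
    atlas = atlases[config.analysis_k]
    sequences = {
        key: assign_windows(wc, atlas) for key, wc in windows_by_run.items()
    }
    seqs_by_subject = {}
    for (sid, _), seq in sequences.items():
        seqs_by_subject.setdefault(sid, []).append(seq)
    dwell = pd.DataFrame(
        {sid: dwell_fractions(seqs) for sid, seqs in seqs_by_subject.items()}
    ).T
    profiles_by_subject = {}
    for rec in subjects:
        pairs = [
            (windows_by_run[(rec.subject_id, ts.run_id)], sequences[(rec.subject_id, ts.run_id)])
            for ts in rec.runs
        ]
        profiles_by_subject[rec.subject_id] = subject_state_profiles(
            pairs, subject_id=rec.subject_id
        )
    if "dynamics" in stages:
        stage_dir = out_root / "dynamics"
        stage_dir.mkdir(exist_ok=True)
        pd.DataFrame(
            [
                {
                    "subject_id": sid,
                    "run_id": rid,
                    "window_index": w,
                    "state": lab,
                }
                for (sid, rid), seq in sequences.items()
                for w, lab in enumerate(seq.labels)
            ]
        ).to_csv(stage_dir / "sequences.csv", index=False)
        dwell.rename_axis("subject_id").to_csv(stage_dir / "dwell.csv")
        summary = transition_statistics(
            [s for seqs in seqs_by_subject.values() for s in seqs]
        )
        pd.DataFrame(
            summary.switch_matrix,
            index=summary.state_labels,
            columns=summary.state_labels,
        ).to_csv(stage_dir / "switch_matrix.csv")
        pd.DataFrame(
            {
                "state": summary.state_labels,
                "persistence": [
                    summary.persistence[s] for s in summary.state_labels
                ],
                "dwell_fraction": [
                    summary.dwell_fraction[s] for s in summary.state_labels
                ],
            }
        ).to_csv(stage_dir / "state_summary.csv", index=False)
        _write_provenance(stage_dir, "dynamics", {"K": config.analysis_k})
        manifest["dynamics"] = stage_dir

    covariates = pd.DataFrame(
        {rec.subject_id: rec.covariates for rec in subjects}
    ).T[config.covariate_names]

    # --- fingerprint -------------------------------------------------------
    if "fingerprint" in stages:
        stage_dir = out_root / "fingerprint"
        stage_dir.mkdir(exist_ok=True)
        visits = sorted({ts.visit_id for rec in subjects for ts in rec.runs})
        if len(visits) >= 2:
            v1, v2 = visits[0], visits[1]
            prof_v = {v: {} for v in (v1, v2)}
            for rec in subjects:
                for v in (v1, v2):
                    pairs = [
                        (
                            windows_by_run[(rec.subject_id, ts.run_id)],
                            sequences[(rec.subject_id, ts.run_id)],
                        )
                        for ts in rec.runs
                        if ts.visit_id == v
                    ]
                    if pairs:
                        prof_v[v][rec.subject_id] = subject_state_profiles(
                            pairs, subject_id=rec.subject_id, visit_id=v
                        )
            rows = []
            for state in atlas.state_labels:
                try:
                    within, between, t, p_t = profile_similarity_distributions(
                        prof_v[v1], prof_v[v2], state
                    )
                    res = identification_rank_test(
                        prof_v[v1],
                        prof_v[v2],
                        state,
                        n_permutations=config.n_permutations,
                        seed=config.seed,
                    )
                    rows.append(
                        {
                            "state": state,
                            "identification_rate": res.identification_rate,
                            "p": res.p_value,
                            "mean_within_r": float(np.mean(within)),
                            "mean_between_r": float(np.mean(between)),
                            "t_within_vs_between": t,
                        }
                    )
                except ValueError as err:
                    rows.append({"state": state, "error": str(err)})
            pd.DataFrame(rows).to_csv(stage_dir / "identification.csv", index=False)
        else:
            (stage_dir / "SKIPPED.txt").write_text(
                "fingerprint stage requires two visits per subject\n"
            )
        _write_provenance(stage_dir, "fingerprint", {"perms": config.n_permutations})
        manifest["fingerprint"] = stage_dir

    # --- groupdiff ---------------------------------------------------------
    groups = {rec.subject_id: rec.group for rec in subjects}
    has_patients = any(g == "patient" for g in groups.values())
    if "groupdiff" in stages and has_patients:
        stage_dir = out_root / "groupdiff"
        stage_dir.mkdir(exist_ok=True)
        net_edges = within_network_edge_indices(region_networks)
        profs, glabels, gcov = {}, {}, {}
        for state in atlas.state_labels:
            sids = [
                s
                for s in profiles_by_subject
                if state in profiles_by_subject[s].profiles
            ]
            profs[state] = np.stack(
                [profiles_by_subject[s].profiles[state] for s in sids]
            )
            glabels[state] = [groups[s] for s in sids]
            gcov[state] = covariates.loc[sids]
        edgewise_rows = []
        for state in atlas.state_labels:
            if len(set(glabels[state])) < 2:
                continue
            res = edgewise_group_differences(
                profs[state], glabels[state], gcov[state], state=state
            )
            edgewise_rows.append(
                {
                    "state": state,
                    "n_significant_edges": int(res.mask.sum()),
                    "n_edges": len(res.mask),
                    "n_control": res.n_control,
                    "n_patient": res.n_patient,
                }
            )
            pd.DataFrame(
                {
                    "edge": np.arange(len(res.estimate)),
                    "estimate": res.estimate,
                    "t": res.t_stat,
                    "p": res.p_value,
                    "q": res.q_value,
                    "significant": res.mask,
                }
            ).to_csv(stage_dir / f"edgewise_{state}.csv", index=False)
        pd.DataFrame(edgewise_rows).to_csv(
            stage_dir / "edgewise_summary.csv", index=False
        )
        network_level_tests(profs, glabels, gcov, net_edges).to_csv(
            stage_dir / "network_tests.csv", index=False
        )
        network_summary(profs, net_edges, atlas.state_labels[0]).to_csv(
            stage_dir / "network_summary.csv", index=False
        )
        dwell_group_tests(
            dwell, [groups[s] for s in dwell.index], covariates.loc[dwell.index]
        ).to_csv(stage_dir / "dwell_tests.csv", index=False)
        _write_provenance(stage_dir, "groupdiff", {"K": config.analysis_k})
        manifest["groupdiff"] = stage_dir

    # --- predict -----------------------------------------------------------
    if "predict" in stages and has_patients:
        stage_dir = out_root / "predict"
        stage_dir.mkdir(exist_ok=True)
        patients = [
            rec
            for rec in subjects
            if rec.group == "patient"
            and rec.active_psychosis is not None
            and len(profiles_by_subject[rec.subject_id].expressed()) == atlas.K
        ]
        labels = np.array([rec.active_psychosis for rec in patients])
        if len(patients) >= 10 and len(np.unique(labels)) == 2:
            tr, te = stratified_split(
                labels, test_fraction=config.test_fraction, seed=config.seed
            )
            rows = []
            bundles = {}
            for state in atlas.state_labels:
                X = np.stack(
                    [
                        profiles_by_subject[rec.subject_id].profiles[state]
                        for rec in patients
                    ]
                )
                for sign in ("positive", "negative"):
                    try:
                        probs = fit_predict_loocv(
                            X[tr], labels[tr], state=state, sign=sign, seed=config.seed
                        )
                        train_auc = roc_auc(probs, labels[tr]).auc
                        bundle = train_model_bundle(
                            X[tr], labels[tr], state=state, sign=sign, seed=config.seed
                        )
                        bundles[(state, sign)] = bundle
                        hold = holdout_evaluate(
                            bundle,
                            X[te],
                            labels[te],
                            n_permutations=config.n_permutations,
                            seed=config.seed,
                        )
                        rows.append(
                            {
                                "state": state,
                                "sign": sign,
                                "train_loocv_auc": train_auc,
                                "holdout_auc": hold.auc,
                                "holdout_p": hold.p_value,
                                "n_train": len(tr),
                                "n_holdout": len(te),
                            }
                        )
                    except ValueError as err:
                        rows.append({"state": state, "sign": sign, "error": str(err)})
            pd.DataFrame(rows).to_csv(stage_dir / "prediction.csv", index=False)
            with open(stage_dir / "models.json", "w") as fh:
                json.dump(
                    {
                        f"{state}|{sign}": {
                            "beta0": b.model.beta0,
                            "beta1": b.model.beta1,
                            "gamma": b.model.gamma.tolist(),
                            "alpha": b.model.alpha,
                            "lambda": b.model.lam,
                            "positive_edges": b.feature_set.positive_edges.tolist(),
                            "negative_edges": b.feature_set.negative_edges.tolist(),
                        }
                        for (state, sign), b in bundles.items()
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
        else:
            (stage_dir / "SKIPPED.txt").write_text(
                "predict stage needs >= 10 labeled patients with both classes\n"
            )
        _write_provenance(stage_dir, "predict", {"seed": config.seed})
        manifest["predict"] = stage_dir

    # stage paths relative to the output root, and no absolute paths in the
    # config record, so identical configs yield byte-identical trees
    with open(out_root / "pipeline_manifest.json", "w") as fh:
        json.dump(
            {
                "stages": {
                    k: str(v.relative_to(out_root)) for k, v in manifest.items()
                },
                "config": {
                    k: v
                    for k, v in dataclasses.asdict(config).items()
                    if k not in ("out_dir", "cohort_dir")
                },
            },
            fh,
            indent=2,
            sort_keys=True,
            default=str,
        )
    return manifest
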