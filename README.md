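# dynstates

Dynamic functional-connectivity brain-state analysis: estimate transient
connectivity states from sliding-window correlations of parcellated BOLD
time series, characterize their hierarchy and temporal dynamics,
fingerprint individuals, compare clinical groups edgewise, and predict a
binary clinical label from state-specific network strength. A synthetic
cohort generator with full ground truth stands in for non-shareable fMRI
data, so every stage of the pipeline is testable end to end.

## Modules

| module | what it does |
| --- | --- |
| `dynstates.synthetic_cohort` | Multi-subject, multi-run time series from a Markov chain switching among K latent covariance states, with planted fingerprints, group effects, and a symptom label; writes TSV runs + manifest + ground-truth JSON |
| `dynstates.dfc_windows` | Sliding-window Pearson correlations (default width 11, stride 1), Fisher z transform, upper-triangle edge vectorization, window subsampling |
| `dynstates.state_atlas` | Pooled k-means brain-state centroids (K = 2..20), Hungarian centroid matching, split-resampling instability curves and stable-K detection |
| `dynstates.state_hierarchy` | Hybrid-state construction and exhaustive pair search to test whether states of solution S+1 subdivide states of solution S |
| `dynstates.state_dynamics` | Window-to-state assignment, dwell fractions, persistence, conditional switch matrices, half-scan comparisons, per-subject state profiles |
| `dynstates.fingerprint_id` | Within- vs between-subject profile reliability and rank-based permutation identification |
| `dynstates.group_stats` | Covariate residualization, edgewise group differences with BH-FDR, network-level Bonferroni tests, dwell-time tests, cross-state coefficient-of-variance ANOVA |
| `dynstates.symptom_prediction` | Sign-split edge selection, network strength, elastic-net logistic regression with LOOCV, trapezoidal ROC/AUC, permutation tests, frozen-model holdout evaluation, PANSS binarization, stratified splitting |
| `dynstates.pipeline` / `dynstates.cli` | End-to-end orchestration with per-stage outputs and provenance, exposed as the `dynstates` CLI |

## CLI

```bash
# simulate a synthetic cohort
dynstates simulate --config cohort.json --out cohort/ --seed 1

# full pipeline from one JSON config
dynstates run --config pipeline.json --out out/ --seed 1

# individual stages (simulate on the fly, or point --cohort at existing data)
dynstates cluster --cohort cohort/ --out out/ --seed 1
dynstates predict --cohort cohort/ --out out/ --seed 1
```

`pipeline.json` accepts the fields of `dynstates.pipeline.PipelineConfig`
(window width/stride, subsampling mode/rate, K range, replicate and
permutation counts, covariate names, split fraction, stage toggles); the
`cohort` sub-object is forwarded to `dynstates.synthetic_cohort.CohortSpec`.
Every stage writes tidy CSV/JSON outputs plus a `provenance.json`, and
rerunning an identical config reproduces byte-identical outputs.

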