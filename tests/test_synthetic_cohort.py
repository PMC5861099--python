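import numpy as np
import pytest
from scipy import stats

from dynstates.dfc_windows import vectorize_connectivity
from dynstates.synthetic_cohort import (
    CohortSpec,
    block_correlation_matrix,
    default_network_labels,
    default_transition_matrix,
    generate_cohort,
    generate_state_covariances,
    read_cohort,
    simulate_state_sequence,
    simulate_subject_timeseries,
    spd_repair,
    stationary_distribution,
    window_majority_sequence,
    write_cohort,
)


class TestNetworkLabels:
    def test_default_114_regions_17_networks(self):
        labels = default_network_labels()
        assert len(labels) == 114
        assert len(set(labels.values())) == 17
        left = [r for r in labels if r.startswith("L")]
        assert len(left) == 57


class TestStateCovariances:
    def test_zero_blocks_give_identity(self):
        mat = block_correlation_matrix(["a", "a", "b", "b"], within=0.0, between=0.0)
        assert np.array_equal(mat, np.eye(4))

    def test_within_block_construction(self):
        nets = ["n1", "n1", "n1", "n2"]
        mat = block_correlation_matrix(nets, within={"n1": 0.5, "n2": 0.0}, between=0.0)
        sub = mat[:3, :3]
        assert np.all(sub[~np.eye(3, dtype=bool)] == 0.5)
        assert np.all(np.diag(mat) == 1.0)

    def test_all_covariances_positive_definite(self):
        # oracle: full eigendecomposition of every returned matrix
        spec = CohortSpec(n_regions=30, n_states=5, seed=3)
        for C in generate_state_covariances(spec):
            vals = np.linalg.eigvalsh(C)
            assert vals.min() > 0
            assert np.allclose(np.diag(C), 1.0)
            assert np.allclose(C, C.T)

    def test_attractor_has_muted_within_network_blocks(self):
        spec = CohortSpec(n_regions=20, n_states=4, attractor_state=0, seed=0)
        covs = generate_state_covariances(spec)
        nets = np.asarray(spec.region_networks)
        for net in spec.networks:
            idx = np.flatnonzero(nets == net)
            block = np.ix_(idx, idx)
            off = ~np.eye(len(idx), dtype=bool)
            attractor_mean = covs[0][block][off].mean()
            for k in range(1, 4):
                assert attractor_mean < covs[k][block][off].mean()

    def test_spd_repair_fixes_indefinite_matrix(self):
        mat = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        assert np.linalg.eigvalsh(mat).min() < 0
        fixed = spd_repair(mat)
        assert np.linalg.eigvalsh(fixed).min() > 0
        assert np.allclose(np.diag(fixed), 1.0)


class TestStateSequence:
    def test_identity_matrix_is_absorbing(self):
        seq = simulate_state_sequence(np.eye(3), 50, seed=0)
        assert len(set(seq)) == 1

    def test_uniform_chain_frequencies(self):
        P = np.full((4, 4), 0.25)
        seq = simulate_state_sequence(P, 100_000, seed=1)
        freqs = np.bincount(seq, minlength=4) / len(seq)
        assert np.allclose(freqs, 0.25, atol=0.01)

    def test_sticky_state_dwells_most(self):
        # oracle: stationary distribution from the leading left eigenvector
        P = default_transition_matrix(4, attractor_state=0)
        pi = stationary_distribution(P)
        assert np.argmax(pi) == 0
        seq = simulate_state_sequence(P, 100_000, seed=2)
        freqs = np.bincount(seq, minlength=4) / len(seq)
        assert np.argmax(freqs) == 0
        assert np.allclose(freqs, pi, atol=0.01)

    def test_non_stochastic_matrix_fails(self):
        with pytest.raises(ValueError):
            simulate_state_sequence(np.array([[0.5, 0.4], [0.5, 0.5]]), 10, seed=0)

    def test_empirical_transition_matrix_recovery(self):
        P = default_transition_matrix(3, attractor_state=1)
        seq = simulate_state_sequence(P, 100_000, seed=3)
        # direct-count oracle
        counts = np.zeros((3, 3))
        np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
        est = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(est - P).max() < 0.02


class TestWindowMajority:
    def test_hand_example(self):
        states = np.array([0, 0, 0, 1, 1])
        assert window_majority_sequence(states, width=3).tolist() == [0, 0, 1]

    def test_length_matches_window_formula(self):
        states = np.zeros(120, dtype=int)
        assert len(window_majority_sequence(states, width=11)) == 110


class TestSubjectTimeseries:
    def test_sample_correlation_matches_state_correlation(self):
        spec = CohortSpec(
            n_regions=10,
            n_states=1,
            transition_matrix=np.array([[1.0]]),
            n_timepoints=30_000,
            observation_noise_sd=0.0,
            seed=0,
        )
        # 3e4 samples keep the MAX abs deviation over all 45 entries
        # inside the 0.02 consistency tolerance (elementwise SE ~ 0.006)
        covs = generate_state_covariances(spec)
        runs, _ = simulate_subject_timeseries(spec, covs, seed=5)
        sample = np.corrcoef(runs[0].values, rowvar=False)
        assert np.abs(sample - covs[0]).max() < 0.02

    def test_zero_fingerprint_gives_identical_covariances(self):
        spec = CohortSpec(
            n_regions=12, n_controls=2, n_patients=0, fingerprint_sd=0.0,
            n_timepoints=20, seed=0,
        )
        _, truth = generate_cohort(spec)
        f = list(truth.fingerprints.values())
        assert np.array_equal(f[0], f[1])
        assert np.all(f[0] == 0)

    def test_same_seed_is_bitwise_identical(self):
        spec = CohortSpec(n_regions=10, n_timepoints=30, seed=0)
        covs = generate_state_covariances(spec)
        runs1, seq1 = simulate_subject_timeseries(spec, covs, seed=9)
        runs2, seq2 = simulate_subject_timeseries(spec, covs, seed=9)
        assert np.array_equal(runs1[0].values, runs2[0].values)
        assert np.array_equal(seq1["v1r1"], seq2["v1r1"])

    def test_ar_coefficient_increases_autocorrelation(self):
        base = dict(n_regions=8, n_states=1, transition_matrix=np.array([[1.0]]),
                    n_timepoints=2000, observation_noise_sd=0.0)
        covs = generate_state_covariances(CohortSpec(**base, seed=0))

        def lag1(spec):
            runs, _ = simulate_subject_timeseries(spec, covs, seed=4)
            x = runs[0].values[:, 0]
            return np.corrcoef(x[:-1], x[1:])[0, 1]

        assert lag1(CohortSpec(**base, ar_coefficient=0.8, seed=0)) > (
            lag1(CohortSpec(**base, ar_coefficient=0.0, seed=0)) + 0.5
        )


class TestGenerateCohort:
    def test_bookkeeping(self):
        spec = CohortSpec(
            n_regions=12, n_controls=3, n_patients=2, n_timepoints=40, seed=0
        )
        subjects, truth = generate_cohort(spec)
        assert len(subjects) == 5
        assert sum(s.group == "control" for s in subjects) == 3
        for rec in subjects:
            for ts in rec.runs:
                assert len(truth.state_sequences[(rec.subject_id, ts.run_id)]) == 40

    def test_zero_subjects_fails(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(n_regions=12, n_controls=0, n_patients=0))

    def test_null_symptom_effect_gives_no_association(self):
        spec = CohortSpec(
            n_regions=12, n_controls=0, n_patients=200, n_timepoints=12,
            symptom_effect_size=0.0, fingerprint_sd=0.05, seed=11,
        )
        subjects, truth = generate_cohort(spec)
        labels = np.array([s.active_psychosis for s in subjects])
        strength = np.array(
            [truth.symptom_perturbations[s.subject_id].sum() for s in subjects]
        )
        r = np.corrcoef(labels, strength)[0, 1]
        assert abs(r) < 0.1

    def test_strong_symptom_effect_gives_association(self):
        spec = CohortSpec(
            n_regions=12, n_controls=0, n_patients=200, n_timepoints=12,
            symptom_effect_size=5.0, fingerprint_sd=0.05, seed=11,
        )
        subjects, truth = generate_cohort(spec)
        labels = np.array([s.active_psychosis for s in subjects])
        strength = np.array(
            [truth.symptom_perturbations[s.subject_id].sum() for s in subjects]
        )
        assert np.corrcoef(labels, strength)[0, 1] > 0.4

    def test_active_patients_have_higher_positive_panss(self):
        spec = CohortSpec(
            n_regions=12, n_controls=0, n_patients=100, n_timepoints=12, seed=2
        )
        subjects, _ = generate_cohort(spec)
        active = [s.panss["positive"] for s in subjects if s.active_psychosis]
        inactive = [s.panss["positive"] for s in subjects if not s.active_psychosis]
        assert len(active) >= 5 and len(inactive) >= 5
        assert np.mean(active) > np.mean(inactive)

    def test_seed_determinism(self, tiny_cohort):
        spec, subjects, truth = tiny_cohort
        subjects2, truth2 = generate_cohort(spec)
        for a, b in zip(subjects, subjects2):
            assert a.active_psychosis == b.active_psychosis
            for ra, rb in zip(a.runs, b.runs):
                assert np.array_equal(ra.values, rb.values)
        assert np.array_equal(truth.centroids, truth2.centroids)

    def test_fingerprint_persistence_across_visits(self):
        # within-subject across-visit profile correlation beats between-subject
        spec = CohortSpec(
            n_regions=12, n_controls=12, n_patients=0, n_timepoints=60,
            visits_per_subject=2, fingerprint_sd=0.2, seed=5,
        )
        subjects, truth = generate_cohort(spec)
        covs_by_visit = {1: [], 2: []}
        for rec in subjects:
            for ts in rec.runs:
                visit = int(ts.visit_id[1])
                # empirical edge profile of the run (static connectivity)
                covs_by_visit[visit].append(
                    vectorize_connectivity(np.corrcoef(ts.values, rowvar=False))
                )
        v1 = np.stack(covs_by_visit[1])
        v2 = np.stack(covs_by_visit[2])
        corr = np.corrcoef(v1, v2)[: len(v1), len(v1):]
        within = np.diag(corr)
        between = corr[~np.eye(len(v1), dtype=bool)]
        t, p = stats.ttest_ind(within, between, equal_var=False)
        assert t > 0 and p < 0.01


class TestCohortIO:
    def test_write_read_round_trip(self, tiny_cohort, tmp_path):
        spec, subjects, truth = tiny_cohort
        write_cohort(subjects, truth, tmp_path / "cohort")
        loaded, truth2 = read_cohort(tmp_path / "cohort")
        assert len(loaded) == len(subjects)
        for a, b in zip(subjects, loaded):
            assert a.subject_id == b.subject_id
            assert a.group == b.group
            assert a.active_psychosis == b.active_psychosis
            assert np.allclose(a.runs[0].values, b.runs[0].values)
        assert np.allclose(truth.centroids, truth2.centroids)
        assert np.array_equal(truth.symptom_edges, truth2.symptom_edges)
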