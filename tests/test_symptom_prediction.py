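import itertools

import numpy as np
import pytest

from dynstates.symptom_prediction import (
    EdgeFeatureSet,
    ElasticNetLogisticModel,
    binarize_panss,
    fit_elastic_net_logistic,
    fit_predict_loocv,
    holdout_evaluate,
    network_strength,
    permutation_auc_test,
    predicted_probability,
    roc_auc,
    select_edge_features,
    stratified_split,
    train_model_bundle,
)


class TestSelectEdgeFeatures:
    def test_null_selection_rate(self):
        n, E = 60, 2000
        rng = np.random.default_rng(0)
        X = rng.standard_normal((n, E))
        y = rng.integers(0, 2, n)
        fs = select_edge_features(X, y, p_threshold=0.05)
        selected = len(fs.positive_edges) + len(fs.negative_edges)
        expect = 0.05 * E
        # binomial error: 4 SD around the expectation
        assert abs(selected - expect) < 4 * np.sqrt(E * 0.05 * 0.95)

    def test_planted_edges_selected_positive(self, rng):
        n, E = 100, 50
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, E)) * 0.3
        planted = [3, 7, 11]
        X[y == 1][:, planted] += 0  # noop to keep view semantics explicit
        X[:, planted] += np.outer(y, np.ones(3)) * 2.0
        fs = select_edge_features(X, y)
        assert set(planted) <= set(fs.positive_edges.tolist())

    def test_label_sign_flip_swaps_sets(self, rng):
        X = rng.standard_normal((40, 30))
        y = rng.integers(0, 2, 40)
        while len(np.unique(y)) < 2 or min(np.bincount(y)) < 3:
            y = rng.integers(0, 2, 40)
        fs = select_edge_features(X, y)
        fs_flip = select_edge_features(X, 1 - y)
        assert np.array_equal(fs.positive_edges, fs_flip.negative_edges)
        assert np.array_equal(fs.negative_edges, fs_flip.positive_edges)

    def test_constant_edge_excluded_with_warning(self, rng):
        X = rng.standard_normal((30, 5))
        X[:, 2] = 1.0
        y = np.repeat([0, 1], 15)
        with pytest.warns(UserWarning, match="constant"):
            fs = select_edge_features(X, y)
        assert 2 not in fs.positive_edges and 2 not in fs.negative_edges

    def test_too_few_per_class_fails(self, rng):
        with pytest.raises(ValueError):
            select_edge_features(rng.standard_normal((5, 4)), [0, 0, 0, 1, 1])


class TestNetworkStrength:
    def _fs(self, pos, neg=()):
        return EdgeFeatureSet(
            state="B",
            positive_edges=np.asarray(pos, dtype=int),
            negative_edges=np.asarray(neg, dtype=int),
            r=np.zeros(10),
            p=np.ones(10),
        )

    def test_sum(self):
        profile = np.zeros(10)
        profile[[1, 4, 6]] = [0.1, 0.2, 0.3]
        s, empty = network_strength(profile, self._fs([1, 4, 6]), "positive")
        assert s == pytest.approx(0.6)
        assert not empty

    def test_empty_set_flagged(self):
        s, empty = network_strength(np.ones(10), self._fs([]), "positive")
        assert s == 0.0 and empty

    def test_linearity(self, rng):
        profile = rng.standard_normal(10)
        fs = self._fs([0, 3, 5])
        s1, _ = network_strength(profile, fs, "positive")
        s2, _ = network_strength(2 * profile, fs, "positive")
        assert s2 == pytest.approx(2 * s1)

    def test_missing_edges_fail(self):
        with pytest.raises(ValueError):
            network_strength(np.ones(3), self._fs([7]), "positive")


class TestPredictedProbability:
    def _model(self, b0=0.0, b1=0.0, gamma=()):
        return ElasticNetLogisticModel(
            beta0=b0, beta1=b1, gamma=np.asarray(gamma, dtype=float),
            alpha=0.5, lam=0.1,
        )

    def test_zero_weights_give_half(self):
        assert predicted_probability(self._model(), 1.7) == 0.5

    def test_limits(self):
        m = self._model(b1=1.0)
        assert predicted_probability(m, 0.0) == 0.5
        assert predicted_probability(m, 1e3) > 0.999

    def test_closed_form(self):
        # oracle: logistic(1 + 2*0.5) = e^2 / (1 + e^2) = 0.8808
        m = self._model(b0=1.0, b1=2.0)
        assert round(predicted_probability(m, 0.5), 4) == 0.8808

    def test_complement_identity(self, rng):
        m = self._model(b0=0.3, b1=-1.2, gamma=[0.5])
        p = predicted_probability(m, 0.7, [1.1])
        eta = 0.3 - 1.2 * 0.7 + 0.5 * 1.1
        assert p + 1 / (1 + np.exp(eta)) == pytest.approx(1.0)

    def test_covariate_mismatch_fails(self):
        with pytest.raises(ValueError):
            predicted_probability(self._model(gamma=[1.0, 2.0]), 0.0, [1.0])


class TestElasticNetFit:
    def test_separable_data_learns_direction(self, rng):
        s = np.concatenate([rng.normal(-2, 0.5, 40), rng.normal(2, 0.5, 40)])
        y = np.repeat([0, 1], 40)
        m = fit_elastic_net_logistic(s[:, None], y, lambda_grid=[0.01], seed=0)
        assert m.beta1 > 0
        assert predicted_probability(m, 3.0) > 0.9
        assert predicted_probability(m, -3.0) < 0.1


class TestLoocv:
    def test_returns_n_probabilities(self, rng):
        n, E = 20, 30
        X = rng.standard_normal((n, E))
        y = np.repeat([0, 1], n // 2)
        probs = fit_predict_loocv(X, y, lambda_grid=[0.05], seed=0)
        assert probs.shape == (n,)
        assert np.all((probs > 0) & (probs < 1))

    def test_null_auc_near_chance(self):
        aucs = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            X = rng.standard_normal((40, 80))
            y = np.repeat([0, 1], 20)
            probs = fit_predict_loocv(X, y, lambda_grid=[0.05], seed=rep)
            aucs.append(roc_auc(probs, y).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_planted_signal_recovered(self, rng):
        n, E = 60, 100
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, E))
        X[:, :10] += np.outer(y, np.ones(10)) * 1.5
        probs = fit_predict_loocv(X, y, lambda_grid=[0.05], seed=0)
        assert roc_auc(probs, y).auc > 0.85

    def test_fold_losing_class_fails(self, rng):
        X = rng.standard_normal((8, 5))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="class"):
            fit_predict_loocv(X, y, lambda_grid=[0.05])


class TestRocAuc:
    def test_perfect_and_reversed(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc([0.1, 0.2, 0.8, 0.9], y).auc == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], y).auc == 0.0

    def test_printed_style_example(self):
        # oracle: 3 of 4 (pos, neg) pairs concordant -> AUC 0.75
        res = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert res.auc == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        assert roc_auc(np.ones(6), [0, 1, 0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_matches_concordant_pair_enumeration(self, rng):
        # oracle: tie-adjusted concordance probability by full enumeration
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        res = roc_auc(scores, y)
        pos = scores[y == 1]
        neg = scores[y == 0]
        total = 0.0
        for sp, sn in itertools.product(pos, neg):
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        assert res.auc == pytest.approx(total / (len(pos) * len(neg)))

    def test_reversal_identity(self, rng):
        scores = rng.standard_normal(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        assert roc_auc(scores, y).auc + roc_auc(-scores, y).auc == pytest.approx(1.0)

    def test_one_class_fails(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPermutationTest:
    def test_separable_data_floor_p(self, rng):
        y = np.repeat([0, 1], 10)
        scores = y.astype(float)  # perfectly separable, AUC 1.0

        def score_fn(labels):
            return scores  # scores fixed; permuted labels break the match

        p, null = permutation_auc_test(score_fn, y, n_permutations=99, seed=0)
        assert p == pytest.approx(0.01)

    def test_null_mean_near_half(self, rng):
        y = np.repeat([0, 1], 15)
        scores = rng.standard_normal(30)
        p, null = permutation_auc_test(
            lambda labels: scores, y, n_permutations=500, seed=1
        )
        assert abs(null.mean() - 0.5) < 0.02

    def test_invalid_permutation_count_fails(self):
        with pytest.raises(ValueError):
            permutation_auc_test(lambda y: y, [0, 1], n_permutations=0)


class TestHoldout:
    def _trained(self, rng):
        n, E = 60, 50
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, E))
        X[:, :8] += np.outer(y, np.ones(8)) * 1.2
        bundle = train_model_bundle(X, y, lambda_grid=[0.05], seed=0)
        return bundle, X, y

    def test_holdout_copy_equals_resubstitution(self, rng):
        bundle, X, y = self._trained(rng)
        res = holdout_evaluate(bundle, X, y, n_permutations=20, seed=0)
        from dynstates.symptom_prediction import network_strength as ns

        scores = [
            predicted_probability(
                bundle.model, ns(x, bundle.feature_set, "positive")[0]
            )
            for x in X
        ]
        assert res.auc == pytest.approx(roc_auc(scores, y).auc)

    def test_model_frozen_by_evaluation(self, rng):
        bundle, X, y = self._trained(rng)
        before = (
            bundle.model.beta0,
            bundle.model.beta1,
            bundle.model.gamma.tobytes(),
            bundle.feature_set.positive_edges.tobytes(),
        )
        holdout_evaluate(bundle, X[20:40], y[20:40], n_permutations=10, seed=1)
        after = (
            bundle.model.beta0,
            bundle.model.beta1,
            bundle.model.gamma.tobytes(),
            bundle.feature_set.positive_edges.tobytes(),
        )
        assert before == after

    def test_planted_signal_generalizes(self, rng):
        bundle, X, y = self._trained(rng)
        X_new = rng.standard_normal((40, 50))
        y_new = np.repeat([0, 1], 20)
        X_new[:, :8] += np.outer(y_new, np.ones(8)) * 1.2
        res = holdout_evaluate(bundle, X_new, y_new, n_permutations=200, seed=2)
        assert res.auc > 0.7
        assert res.p_value <= 0.05


class TestBinarizePanss:
    def test_positive_scale_cutoff(self):
        _, cutoff = binarize_panss([10.0], 18.46, 6.51)
        assert cutoff == pytest.approx(11.95)

    def test_negative_scale_cutoff(self):
        _, cutoff = binarize_panss([10.0], 13.48, 7.47)
        assert cutoff == pytest.approx(6.01)

    def test_boundary_score_is_high(self):
        labels, cutoff = binarize_panss([11.95, 11.94, 11.96], 18.46, 6.51)
        assert labels.tolist() == [1, 0, 1]

    def test_nonpositive_sd_fails(self):
        with pytest.raises(ValueError):
            binarize_panss([1.0], 10.0, 0.0)


class TestStratifiedSplit:
    def test_130_subjects_give_91_39(self):
        labels = np.array([1] * 80 + [0] * 50)
        train, test = stratified_split(labels, test_fraction=0.3, seed=0)
        assert len(train) == 91
        assert len(test) == 39
        assert len(np.intersect1d(train, test)) == 0

    def test_stratification_preserved(self):
        labels = np.array([1] * 80 + [0] * 50)
        train, test = stratified_split(labels, test_fraction=0.3, seed=1)
        # per-class proportions within 1 subject of exact 30%
        assert abs(labels[test].sum() - 0.3 * 80) <= 1
        assert abs((labels[test] == 0).sum() - 0.3 * 50) <= 1

    def test_seed_determinism(self):
        labels = np.repeat([0, 1], 20)
        t1 = stratified_split(labels, seed=5)
        t2 = stratified_split(labels, seed=5)
        assert np.array_equal(t1[0], t2[0]) and np.array_equal(t1[1], t2[1])

    def test_bad_fraction_fails(self):
        with pytest.raises(ValueError):
            stratified_split([0, 1], test_fraction=1.5)
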