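"""SDM fitting: pseudo-absences, partitioning, metrics, ensembling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangegap import sdm, synth


@pytest.fixture(scope="module")
def training_set(occurrences, score_stack, species):
    return sdm.build_training_set(occurrences, score_stack, species.endemism_region, 1.0, seed=0)


class TestTrainingSet:
    def test_one_to_one_ratio_and_disjoint(self, training_set, occurrences):
        assert len(training_set.absence_cells) == occurrences.n_unique
        pres = set(map(tuple, training_set.presence_cells))
        absn = set(map(tuple, training_set.absence_cells))
        assert pres.isdisjoint(absn)

    def test_absences_inside_calibration(self, training_set, species):
        a = training_set.absence_cells
        assert species.endemism_region[a[:, 0], a[:, 1]].all()

    def test_same_seed_identical(self, occurrences, score_stack, species):
        a = sdm.build_training_set(occurrences, score_stack, species.endemism_region, 1.0, seed=3)
        b = sdm.build_training_set(occurrences, score_stack, species.endemism_region, 1.0, seed=3)
        assert np.array_equal(a.absence_cells, b.absence_cells)

    def test_degenerate_calibration_rejected(self, occurrences, score_stack, species):
        only_pres = np.zeros_like(species.endemism_region)
        only_pres[occurrences.cells[:, 0], occurrences.cells[:, 1]] = True
        with pytest.raises(ValueError, match="candidates"):
            sdm.build_training_set(occurrences, score_stack, only_pres, 1.0, seed=0)


class TestPartition:
    def test_fifteen_or_more_gets_checkerboard(self, training_set):
        scheme = sdm.partition(training_set, n_unique=15, seed=0)
        assert scheme.method == "checkerboard"
        assert set(scheme.fold_of_record.tolist()) == {0, 1}

    def test_below_fifteen_gets_kfold(self, training_set):
        scheme = sdm.partition(training_set, n_unique=8, seed=0)
        assert scheme.method == "kfold"
        assert scheme.k == 5

    def test_checkerboard_parity_formula(self):
        # block 5: (2,3) -> (0+0)%2 = 0; (2,7) -> (0+1)%2 = 1
        assert sdm.checkerboard_fold(2, 3, 5) == 0
        assert sdm.checkerboard_fold(2, 7, 5) == 1

    @given(r=st.integers(0, 500), c=st.integers(0, 500), b=st.integers(1, 40))
    @settings(derandomize=True, max_examples=50)
    def test_checkerboard_is_pure_parity(self, r, c, b):
        assert sdm.checkerboard_fold(r, c, b) == ((r // b) + (c // b)) % 2

    def test_kfold_capped_at_n_unique(self, training_set):
        scheme = sdm.partition(training_set, n_unique=4, seed=0, k=5)
        assert scheme.k == 4

    def test_every_record_gets_exactly_one_fold(self, training_set):
        scheme = sdm.partition(training_set, seed=1)
        assert len(scheme.fold_of_record) == len(training_set.labels)


class TestAUC:
    def test_perfect_separation(self):
        assert sdm.auc([0.9, 0.8], [0.3, 0.4]) == 1.0

    def test_all_ties_is_half(self):
        assert sdm.auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_three_of_four_concordant(self):
        # pairs: (.7,.5)+ (.7,.1)+ (.2,.5)- (.2,.1)+ -> 3/4
        assert sdm.auc([0.7, 0.2], [0.5, 0.1]) == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sdm.auc([], [0.1])

    def test_matches_pairwise_oracle_on_random_instances(self, rng):
        def brute(pos, neg):
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            return wins / (len(pos) * len(neg))

        for _ in range(100):
            pos = rng.integers(0, 10, size=rng.integers(1, 51)) / 10.0
            neg = rng.integers(0, 10, size=rng.integers(1, 51)) / 10.0
            assert sdm.auc(pos, neg) == pytest.approx(brute(pos, neg))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.4
        if labels.any() and not labels.all():
            ours = sdm.auc(scores[labels], scores[~labels])
            assert ours == pytest.approx(roc_auc_score(labels, scores))


class TestJaccard:
    def test_identical_sets(self):
        assert sdm.jaccard([1, 1, 0], [1, 1, 0]) == 1.0

    def test_counts(self):
        # TP=3, FP=1, FN=0
        assert sdm.jaccard([1, 1, 1, 1], [1, 1, 1, 0]) == 0.75

    def test_disjoint_and_empty(self):
        assert sdm.jaccard([1, 0], [0, 1]) == 0.0
        assert sdm.jaccard([0, 0], [0, 0]) == 1.0

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_and_symmetric(self, pairs):
        p, o = zip(*pairs)
        j = sdm.jaccard(p, o)
        assert 0.0 <= j <= 1.0
        assert j == sdm.jaccard(o, p)


class TestEvaluate:
    def test_perfect_scores(self):
        m = sdm.evaluate_estimator([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m["auc"] == 1.0 and m["jaccard_max"] == 1.0

    def test_constant_scores_all_positive_prediction(self):
        m = sdm.evaluate_estimator([0.5] * 5, [1, 1, 0, 0, 0])
        assert m["jaccard_max"] == pytest.approx(2 / 5)

    def test_single_class_fold_rejected(self):
        with pytest.raises(ValueError, match="presence and one absence"):
            sdm.evaluate_estimator([0.5, 0.6], [1, 1])

    def test_jaccard_max_equals_bruteforce_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 200))
            scores = rng.integers(0, 20, size=n) / 20.0
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            best, _ = sdm.jaccard_max(scores, labels)
            oracle = max(
                sdm.jaccard(scores >= t, labels) for t in np.linspace(0, 1, 201)
            )
            assert best == pytest.approx(oracle)


class TestFitAndEnsemble:
    def test_separable_data_perfect_training_auc(self):
        X = np.vstack([np.full((10, 2), 2.0), np.full((10, 2), -2.0)])
        X += np.random.default_rng(0).normal(scale=0.1, size=X.shape)
        y = np.array([True] * 10 + [False] * 10)
        for est in sdm.default_registry():
            est.fit(X, y)
            s = est.score_samples(X)
            assert sdm.auc(s[y], s[~y]) == 1.0

    def test_suitability_maps_bounded(self, training_set, score_stack):
        scheme = sdm.partition(training_set, seed=0)
        results = sdm.fit_estimators(training_set, scheme, scores=score_stack)
        for r in results:
            vals = r.suitability[~np.isnan(r.suitability)]
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_strong_signal_reaches_useful_skill(self, training_set, score_stack):
        scheme = sdm.partition(training_set, seed=0)
        results = sdm.fit_estimators(training_set, scheme, scores=score_stack)
        assert max(r.mean_metric for r in results) >= 0.7

    def test_ensemble_retains_above_average(self):
        def res(aid, metric):
            return sdm.EstimatorResult(aid, [], metric, np.full((2, 2), metric))

        ens = sdm.ensemble([res("a", 0.9), res("b", 0.7), res("c", 0.5)])
        assert ens.retained_algorithms == ["a", "b"]  # mean 0.7, rule is >=

    def test_all_tied_keeps_all(self):
        maps = [np.full((2, 2), v) for v in (0.2, 0.8)]
        results = [
            sdm.EstimatorResult("a", [], 0.6, maps[0]),
            sdm.EstimatorResult("b", [], 0.6, maps[1]),
        ]
        ens = sdm.ensemble(results)
        assert ens.retained_algorithms == ["a", "b"]
        np.testing.assert_allclose(ens.suitability, 0.5)

    def test_single_algorithm_identity(self):
        m = np.array([[0.1, 0.9]])
        ens = sdm.ensemble([sdm.EstimatorResult("only", [], 0.5, m)])
        np.testing.assert_array_equal(ens.suitability, m)

    def test_ensemble_bounded_by_members(self, training_set, score_stack):
        scheme = sdm.partition(training_set, seed=0)
        results = sdm.fit_estimators(training_set, scheme, scores=score_stack)
        ens = sdm.ensemble(results)
        retained = [r for r in results if r.algorithm_id in ens.retained_algorithms]
        stack = np.stack([r.suitability for r in retained])
        ok = ~np.isnan(ens.suitability)
        assert (ens.suitability[ok] >= np.min(stack, axis=0)[ok] - 1e-12).all()
        assert (ens.suitability[ok] <= np.max(stack, axis=0)[ok] + 1e-12).all()
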