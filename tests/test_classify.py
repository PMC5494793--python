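import itertools
from collections import Counter

import numpy as np
import pytest

from mammocad import (
    FLDA,
    ClassifierSpec,
    FeatureTable,
    StagePlan,
    ValidationError,
    majority_vote,
    make_classifier,
    make_cv_plan,
    run_scheme,
)
from mammocad.io_dataset import HEALTH_LABELS, TISSUE_LABELS


def vote_oracle(votes, ranked_votes):
    """Mode with ties resolved by the best-ranked voter's label."""
    counts = Counter(votes)
    best, n = counts.most_common(1)[0]
    if n >= 2:
        return best
    return ranked_votes[0]


def gaussian_blobs(rng, means, n_per, scale=0.1):
    X, y = [], []
    for label, mu in means.items():
        X.append(rng.normal(mu, scale, size=(n_per, len(mu))))
        y += [label] * n_per
    return np.vstack(X), np.array(y)


def synthetic_table(rng, n_per_class=6, tissue_sep=40.0, health_sep=8.0):
    """Linearly separable 12-class features: tissue and health each coded
    on their own axes with well-separated means."""
    rows, tissue, health = [], [], []
    for it, t in enumerate(TISSUE_LABELS):
        for ih, h in enumerate(HEALTH_LABELS):
            centre = np.zeros(5)
            centre[0] = it * tissue_sep
            centre[1] = ih * health_sep
            rows.append(rng.normal(centre, 0.5, size=(n_per_class, 5)))
            tissue += [t] * n_per_class
            health += [h] * n_per_class
    X = np.vstack(rows)
    return FeatureTable(X, tissue, health, [f"r{i}" for i in range(len(tissue))])


class TestCvPlan:
    def test_233_per_class_11_folds(self):
        strata = [f"c{k}" for k in range(12) for _ in range(233)]
        plan = make_cv_plan(strata, k=11, seed=0)
        strata = np.array(strata)
        for k in range(12):
            sizes = np.bincount(plan.assignment[strata == f"c{k}"], minlength=11)
            assert set(sizes.tolist()) <= {21, 22}
            assert sizes.sum() == 233

    def test_tiny_balanced_split(self):
        strata = ["a"] * 4 + ["b"] * 4
        plan = make_cv_plan(strata, k=2, seed=1)
        s = np.array(strata)
        for lab in "ab":
            assert np.bincount(plan.assignment[s == lab]).tolist() == [2, 2]

    def test_deterministic_given_seed(self):
        strata = ["a", "b"] * 20
        p1 = make_cv_plan(strata, k=4, seed=7)
        p2 = make_cv_plan(strata, k=4, seed=7)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        p3 = make_cv_plan(strata, k=4, seed=8)
        assert not np.array_equal(p1.assignment, p3.assignment)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValidationError, match="'b'"):
            make_cv_plan(["a"] * 10 + ["b"] * 2, k=3)


class TestFLDA:
    def test_separable_blobs_perfect(self, rng):
        X, y = gaussian_blobs(rng, {"u": [-5, 0], "v": [5, 0]}, 50)
        Xt, yt = gaussian_blobs(np.random.default_rng(1), {"u": [-5, 0], "v": [5, 0]}, 20)
        model = FLDA().fit(X, y)
        assert np.mean(model.predict(Xt) == yt) == 1.0

    def test_class_mean_assigned_to_class(self, rng):
        X, y = gaussian_blobs(rng, {"u": [-3, 1], "v": [3, -1], "w": [0, 4]}, 30)
        model = FLDA().fit(X, y)
        for lab in "uvw":
            mean = X[y == lab].mean(axis=0)
            assert model.predict(mean[None, :])[0] == lab

    def test_duplication_invariance(self, rng):
        X, y = gaussian_blobs(rng, {"u": [-2, 0, 1], "v": [2, 1, 0]}, 25)
        Xt = rng.normal(0, 3, size=(40, 3))
        p1 = FLDA().fit(X, y).predict(Xt)
        p2 = FLDA().fit(np.vstack([X, X]), np.concatenate([y, y])).predict(Xt)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            FLDA().fit(rng.normal(size=(10, 3)), np.array(["a"] * 10))

    def test_scale_heterogeneous_features(self, rng):
        # one informative axis dwarfed by an uninformative huge-scale axis
        X, y = gaussian_blobs(rng, {"u": [-1, 0], "v": [1, 0]}, 50, scale=0.05)
        X = np.column_stack([X[:, 0], rng.normal(0, 1e6, X.shape[0])])
        model = FLDA().fit(X, y)
        assert np.mean(model.predict(X) == y) > 0.95


class TestMakeClassifier:
    def test_knn1_memorizes_training_set(self, rng):
        X, y = gaussian_blobs(rng, {"a": [0, 0], "b": [1, 1]}, 20, scale=0.3)
        model = make_classifier(ClassifierSpec("knn", knn_k=1))
        assert np.mean(model.fit(X, y).predict(X) == y) == 1.0

    def test_naive_bayes_on_axis_aligned_gaussians(self, rng):
        means = {"a": [-3, -3, -3], "b": [3, 3, 3]}
        X, y = gaussian_blobs(rng, means, 100, scale=1.0)
        Xt, yt = gaussian_blobs(np.random.default_rng(5), means, 50, scale=1.0)
        model = make_classifier(ClassifierSpec("naive_bayes")).fit(X, y)
        assert np.mean(model.predict(Xt) == yt) > 0.95

    def test_random_forest_seeded_deterministic(self, rng):
        X, y = gaussian_blobs(rng, {"a": [0, 0], "b": [2, 2]}, 30, scale=1.5)
        Xt = rng.normal(1, 2, size=(50, 2))
        p1 = make_classifier(ClassifierSpec("random_forest", seed=3)).fit(X, y).predict(Xt)
        p2 = make_classifier(ClassifierSpec("random_forest", seed=3)).fit(X, y).predict(Xt)
        np.testing.assert_array_equal(p1, p2)

    def test_every_kind_fits_and_predicts(self, rng):
        from mammocad import CLASSIFIER_KINDS

        X, y = gaussian_blobs(rng, {"a": [-4, 0], "b": [4, 0], "c": [0, 6]}, 20)
        for kind in CLASSIFIER_KINDS:
            model = make_classifier(ClassifierSpec(kind)).fit(X, y)
            acc = np.mean(model.predict(X) == y)
            assert acc > 0.9, kind

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            ClassifierSpec("perceptron")

    def test_knn_k_multiple_of_class_count_rejected(self):
        with pytest.raises(ValidationError):
            ClassifierSpec("knn", knn_k=6)


class TestMajorityVote:
    def test_two_votes_win(self):
        assert majority_vote([["A"], ["A"], ["B"]], [0, 1, 2]) == ["A"]

    def test_three_way_tie_goes_to_top_ranked(self):
        # voters c1, c2, c3 predict A, B, C; ranking puts voter index 1 first
        assert majority_vote([["A"], ["B"], ["C"]], [1, 0, 2]) == ["B"]

    def test_exhaustive_against_oracle(self):
        labels = ["x", "y", "z"]
        for votes in itertools.product(labels, repeat=3):
            for ranking in itertools.permutations(range(3)):
                preds = [[v] for v in votes]
                got = majority_vote(preds, list(ranking))[0]
                want = vote_oracle(list(votes), [votes[r] for r in ranking])
                assert got == want, (votes, ranking)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            majority_vote([["A"], ["A", "B"], ["B"]], [0, 1, 2])


class TestRunScheme:
    def test_one_stage_separable_diagonal(self, rng):
        table = synthetic_table(rng)
        cv = make_cv_plan(
            [f"{t}/{h}" for t, h in zip(table.tissue, table.health)], k=3, seed=0
        )
        res = run_scheme(table, StagePlan("one_stage"), cv, [ClassifierSpec("flda")])
        cm = res.confusions["flda"]
        assert np.trace(cm.counts) == cm.total == len(table)

    @pytest.mark.parametrize("scheme", ["one_stage", "two_stage", "three_stage"])
    def test_every_sample_counted_once(self, rng, scheme):
        table = synthetic_table(rng, health_sep=1.0)  # imperfect classes
        cv = make_cv_plan(
            [f"{t}/{h}" for t, h in zip(table.tissue, table.health)], k=2, seed=0
        )
        specs = [ClassifierSpec("flda"), ClassifierSpec("naive_bayes"),
                 ClassifierSpec("knn")]
        res = run_scheme(table, StagePlan(scheme), cv, specs)
        for cm in res.confusions.values():
            assert cm.total == len(table)

    def test_two_stage_with_perfect_tissue_equals_true_routing(self, rng):
        """With a trivially separable tissue axis, two-stage routing must
        match training/evaluating per-tissue one-stage models on true labels."""
        table = synthetic_table(rng, tissue_sep=1000.0)
        strata = [f"{t}/{h}" for t, h in zip(table.tissue, table.health)]
        cv = make_cv_plan(strata, k=2, seed=0)
        res = run_scheme(table, StagePlan("two_stage"), cv,
                         [ClassifierSpec("flda")], vote_top3=False)
        # manual truth-routed equivalent
        tissue = np.array(table.tissue)
        manual = np.empty(len(table), dtype=object)
        for t in TISSUE_LABELS:
            mask = tissue == t
            for fold in range(2):
                tr = mask & (cv.assignment != fold)
                te = mask & (cv.assignment == fold)
                model = FLDA().fit(table.features[tr],
                                   np.array(table.health, dtype=object)[tr])
                manual[te] = model.predict(table.features[te])
        assert res.predictions["flda"] == list(manual)

    def test_three_stage_routes_to_health_labels(self, rng):
        table = synthetic_table(rng)
        cv = make_cv_plan(
            [f"{t}/{h}" for t, h in zip(table.tissue, table.health)], k=2, seed=0
        )
        res = run_scheme(table, StagePlan("three_stage"), cv, [ClassifierSpec("flda")])
        assert set(res.predictions["flda"]) <= set(HEALTH_LABELS)

    def test_no_training_on_test_fold(self, rng):
        """Predictions for each fold equal those of a model refit on the
        training split alone — no test-fold information reaches training."""
        table = synthetic_table(rng, health_sep=2.0)
        cv = make_cv_plan(
            [f"{t}/{h}" for t, h in zip(table.tissue, table.health)], k=2, seed=0
        )
        res = run_scheme(table, StagePlan("one_stage"), cv, [ClassifierSpec("flda")])
        health = np.array(table.health, dtype=object)
        for fold in range(2):
            tr, te = cv.fold_indices(fold)
            external = FLDA().fit(table.features[tr], health[tr])
            expected = external.predict(table.features[te])
            got = np.array(res.predictions["flda"], dtype=object)[te]
            np.testing.assert_array_equal(got, expected)

    def test_voting_present_for_multistage(self, rng):
        table = synthetic_table(rng, health_sep=1.0)
        cv = make_cv_plan(
            [f"{t}/{h}" for t, h in zip(table.tissue, table.health)], k=2, seed=0
        )
        specs = [ClassifierSpec(k) for k in ("flda", "naive_bayes", "knn", "ldc")]
        res = run_scheme(table, StagePlan("two_stage"), cv, specs)
        assert res.top3 is not None and len(res.top3) == 3
        assert res.combined_confusion.total == len(table)
        # top3 are the best ranked by CV accuracy
        ranked = sorted(res.accuracies, key=lambda k: -res.accuracies[k])
        assert list(res.top3) == ranked[:3]

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValidationError):
            StagePlan("four_stage")
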