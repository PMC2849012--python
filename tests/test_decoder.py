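"""Linear SVM primitives, one-vs-one voting, cross-validation schemes.

The independent oracle for the SVM solver is sklearn's libsvm-backed SVC —
the implementation the original analysis used — compared on predictions and
on the value of the soft-margin objective.
"""

import numpy as np
import pytest
from sklearn.svm import SVC

from mempattern import (
    ClassifierConfig,
    DesignConfig,
    empirical_p,
    generate_trial_design,
    make_loto_scheme,
    train_binary_svm,
    train_multiclass,
)
from mempattern.preprocess import PatternSet


def _patterns(n_trials, n_vox=4, labels=None, rng=None):
    rng = rng or np.random.default_rng(0)
    labels = labels if labels is not None else (np.arange(n_trials) % 3) + 1
    return PatternSet(
        matrix=rng.normal(size=(n_trials, n_vox)),
        labels=np.asarray(labels),
        conditions=np.array(["cued"] * n_trials, dtype=object),
        voxel_index=np.arange(3 * n_vox).reshape(n_vox, 3),
    )


def separable_clouds(k, per_class=10, gap=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(k):
        center = np.zeros(2)
        center[0] = gap * np.cos(2 * np.pi * c / k)
        center[1] = gap * np.sin(2 * np.pi * c / k)
        X.append(center + 0.3 * rng.normal(size=(per_class, 2)))
        y.append(np.full(per_class, c + 1))
    return np.vstack(X), np.concatenate(y)


class TestBinarySVM:
    def test_separable_clouds_zero_training_errors(self):
        X, y = separable_clouds(2)
        yb = np.where(y == 1, 1, -1)
        model = train_binary_svm(X, yb)
        assert model.converged
        assert np.array_equal(model.predict(X), yb)

    def test_duplicated_columns_keep_decision_values(self):
        # weights split across duplicates; decision values are preserved
        X, y = separable_clouds(2, per_class=12, gap=3.0, seed=1)
        yb = np.where(y == 1, 1.0, -1.0)
        single = train_binary_svm(X, yb)
        doubled = train_binary_svm(np.hstack([X, X]), yb)
        np.testing.assert_allclose(
            doubled.decision_function(np.hstack([X, X])),
            single.decision_function(X),
            atol=5e-2,
        )

    def test_one_feature_boundary_in_class_gap(self):
        X = np.array([[-3.0], [-2.0], [-1.5], [1.5], [2.0], [3.0]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        model = train_binary_svm(X, y)
        boundary = -model.b / model.w[0]
        assert -1.5 < boundary < 1.5

    def test_matches_libsvm_oracle(self):
        # dual-route check: predictions and soft-margin objective vs libsvm
        def aug_obj(w, b, X, y, C=1.0):
            return 0.5 * (w @ w + b * b) + C * np.maximum(
                0, 1 - y * (X @ w + b)
            ).sum()

        cfg = ClassifierConfig(class_weight="none")
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 8))
            beta = rng.normal(size=8)
            y = np.where(X @ beta + rng.normal(size=30) > 0, 1.0, -1.0)
            if abs(y.sum()) == 30:
                continue
            mine = train_binary_svm(X, y, cfg)
            ref = SVC(kernel="linear", C=1.0).fit(X, y)
            # compare away from the boundary: the two solvers regularize the
            # bias differently, which may flip points with decision ~ 0
            confident = np.abs(ref.decision_function(X)) > 0.2
            assert np.array_equal(
                mine.predict(X)[confident], ref.predict(X).astype(int)[confident]
            ), f"seed {seed}"
            assert aug_obj(mine.w, mine.b, X, y) <= aug_obj(
                ref.coef_[0], ref.intercept_[0], X, y
            ) * (1 + 1e-3)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_binary_svm(np.ones((4, 2)), np.ones(4))

    def test_nonconvergence_is_flagged(self):
        X, y = separable_clouds(2, per_class=20, gap=0.5, seed=2)
        yb = np.where(y == 1, 1.0, -1.0)
        cfg = ClassifierConfig(max_iter=1)
        with pytest.warns(RuntimeWarning, match="converge"):
            model = train_binary_svm(X, yb, cfg)
        assert not model.converged


class TestMulticlass:
    def test_two_classes_reduce_to_binary(self):
        X, y = separable_clouds(2, seed=3)
        multi = train_multiclass(X, y)
        binary = train_binary_svm(X, np.where(y == 1, 1.0, -1.0))
        pred_multi = multi.predict(X)
        pred_binary = np.where(binary.predict(X) == 1, 1, 2)
        assert np.array_equal(pred_multi, pred_binary)

    def test_three_separable_clouds_votes_match_enumeration(self):
        X, y = separable_clouds(3, seed=4)
        model = train_multiclass(X, y)
        assert np.array_equal(model.predict(X), y)
        # hand-enumeration oracle: per-pair binary fits, tally votes
        decisions = model.decision_values(X)
        for i in range(len(X)):
            votes = {c: 0 for c in (1, 2, 3)}
            for p, (a, b) in enumerate(model.pairs):
                votes[a if decisions[i, p] > 0 else b] += 1
            assert model.predict(X[i : i + 1])[0] == max(votes, key=votes.get)

    def test_pairwise_models_match_pair_subsets(self):
        # each pair's weights equal a binary fit on just that pair's trials
        X, y = separable_clouds(3, seed=5)
        model = train_multiclass(X, y)
        for p, (a, b) in enumerate(model.pairs):
            sel = np.isin(y, (a, b))
            yb = np.where(y[sel] == a, 1.0, -1.0)
            binary = train_binary_svm(X[sel], yb)
            np.testing.assert_allclose(model.weights[p], binary.w, atol=1e-6)

    def test_vote_tie_breaks_deterministically(self):
        # symmetric 3-cloud geometry forces a 1-1-1 vote ring for the center
        # point; the tie-break (largest summed margin, then lowest id) must
        # give one deterministic answer
        X, y = separable_clouds(3, seed=6)
        model = train_multiclass(X, y)
        center = np.zeros((1, 2))
        p1 = model.predict(center)[0]
        for _ in range(5):
            assert model.predict(center)[0] == p1

    def test_missing_class_raises(self):
        with pytest.raises(ValueError):
            train_multiclass(np.ones((4, 2)), np.array([2, 2, 2, 2]))

    def test_matches_libsvm_multiclass_oracle(self):
        X, y = separable_clouds(3, per_class=15, gap=2.5, seed=7)
        mine = train_multiclass(X, y).predict(X)
        ref = SVC(kernel="linear", C=1.0, decision_function_shape="ovo").fit(X, y)
        agree = np.mean(mine == ref.predict(X))
        assert agree >= 0.95

    def test_prediction_invariant_to_feature_scaling(self):
        # rescale features by s and C by 1/s^2 on well-separated data
        X, y = separable_clouds(3, seed=8)
        base = train_multiclass(X, y).predict(X)
        s = 10.0
        scaled = train_multiclass(X * s, y, ClassifierConfig(C=1.0 / s**2)).predict(X * s)
        assert np.array_equal(base, scaled)


class TestCVScheme:
    def test_default_design_gives_51_folds(self):
        d = generate_trial_design(DesignConfig(seed=0))
        pats = _patterns(d.n_trials, labels=d.labels)
        scheme = make_loto_scheme(pats)
        assert scheme.k == 51  # 21 cued + 30 free

    def test_six_trial_design_gives_6_folds(self):
        scheme = make_loto_scheme(_patterns(6))
        assert scheme.k == 6

    def test_folds_partition_trials(self):
        scheme = make_loto_scheme(_patterns(12))
        tested = np.concatenate([te for _, te in scheme.folds])
        assert sorted(tested) == list(range(12))
        for tr, te in scheme.folds:
            assert not set(tr) & set(te)
            assert len(tr) + len(te) == 12

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            make_loto_scheme(_patterns(3))


class TestEmpiricalP:
    def test_observed_below_every_null_gives_one(self):
        assert empirical_p(0.1, np.array([0.3, 0.4, 0.5])) == 1.0

    def test_single_null_below_observed_gives_half(self):
        assert empirical_p(0.9, np.array([0.3])) == 0.5

    def test_tie_counts_as_extreme(self):
        assert empirical_p(0.5, np.array([0.5, 0.4, 0.3])) == pytest.approx(2 / 4)
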