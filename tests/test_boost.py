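"""SAMME boosting: learner-weight formula, vote oracle, CV and permutation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import AdaBoostClassifier

from carryover import (
    SammeClassifier,
    cumulative_importance_ranking,
    cv_error,
    drop_correlated_features,
    permutation_pvalue,
    train_samme,
)
from carryover.boost import CvReport, predict


def _frame(X, y, sex=None):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["rp"] = y
    df["sex"] = sex if sex is not None else "F"
    return df


class TestAlphaFormula:
    def test_alpha_matches_direct_formula_k3(self):
        # err = 0.4 with K = 3: alpha = ln(0.6/0.4) + ln(2)
        assert np.isclose(np.log(1.5) + np.log(2), 1.0986122886681098)
        # engineered sample: weighted error of the best stump is exactly 0.4
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 2, 2])
        # any single stump must misclassify at least one full class here
        clf = SammeClassifier(n_estimators=1).fit(X, y)
        err = (clf.estimators_[0].predict(X) != np.array([0, 0, 1, 2, 2])).mean()
        expected = np.log((1 - err) / err) + np.log(2)
        assert np.isclose(clf.estimator_weights_[0], expected)

    def test_binary_reduces_to_classical_adaboost(self, rng):
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(int)
        ours = SammeClassifier(n_estimators=15, max_depth=1, random_state=0).fit(X, y)
        ref = AdaBoostClassifier(n_estimators=15, random_state=0).fit(X, y)
        m = min(len(ours.estimator_weights_), len(ref.estimator_weights_))
        # identical weak learners are not guaranteed (tie-breaking), but the
        # first-round stump and its classical alpha = ln((1-err)/err) must agree
        e0 = (ours.estimators_[0].predict(X) != y).mean()
        assert np.isclose(ours.estimator_weights_[0], np.log((1 - e0) / e0))
        assert np.isclose(
            ref.estimator_weights_[0],
            np.log((1 - e0) / e0),
            rtol=1e-9,
        )
        preds_ours = ours.predict(X)
        preds_ref = ref.predict(X)
        assert (preds_ours == preds_ref).mean() > 0.95
        del m

    def test_chance_round_halts_boosting(self):
        # labels independent of the single constant-ish feature: first stump
        # is at chance for K=2, alpha 0 and the loop stops
        X = np.array([[0.0], [0.0], [0.0], [0.0]])
        y = np.array([0, 1, 0, 1])
        clf = SammeClassifier(n_estimators=10).fit(X, y)
        assert clf.m_rounds_ == 1
        assert clf.estimator_weights_[0] == 0.0

    def test_separable_toy_perfect_after_round_one(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        clf = SammeClassifier(n_estimators=50).fit(X, y)
        assert (clf.predict(X) == y).all()
        assert clf.m_rounds_ == 1  # perfect stump, early stop


class TestPredict:
    def test_single_learner_prediction_passthrough(self, rng):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        clf = SammeClassifier(n_estimators=1).fit(X, y)
        np.testing.assert_array_equal(
            clf.predict(X), clf.classes_[clf.estimators_[0].predict(X)]
        )

    def test_vote_tally_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.integers(0, 3, size=20)
        clf = SammeClassifier(n_estimators=5, max_depth=2, random_state=1).fit(X, y)
        pred = clf.predict(X)
        for i in range(len(X)):
            tally = {c: 0.0 for c in range(len(clf.classes_))}
            for tree, a in zip(clf.estimators_, clf.estimator_weights_):
                tally[int(tree.predict(X[i : i + 1])[0])] += a
            best = max(tally.values())
            winner = min(c for c, v in tally.items() if v == best)  # class order
            assert clf.classes_[winner] == pred[i]

    def test_unknown_feature_names_rejected(self, default_phenology):
        model = train_samme(default_phenology, seed=0)
        with pytest.raises(KeyError):
            predict(model, default_phenology.rename(columns={"wg_arrival": "zz"}))

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            SammeClassifier().fit(X, np.zeros(10))


class TestCvError:
    def test_label_leak_gives_zero_error(self, rng):
        y = rng.integers(0, 3, 90)
        df = _frame(np.column_stack([y.astype(float), rng.normal(size=90)]), y)
        rep = cv_error(df, k_folds=5, m_rounds=10, seed=0)
        assert rep.error_rate == 0.0
        assert rep.success_rate == 1.0

    def test_null_features_give_two_thirds_error(self, rng):
        n = 600
        y = np.repeat([0, 1, 2], n // 3)
        df = _frame(rng.normal(size=(n, 4)), y)
        rep = cv_error(df, k_folds=10, m_rounds=20, seed=1)
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(rep.error_rate - 2 / 3) <= 3 * se

    def test_success_rate_is_exact_complement(self):
        rep = CvReport.from_error(0.3784)
        assert rep.success_rate == 1.0 - 0.3784
        assert rep.success_percent == pytest.approx(62.16)

    def test_too_many_folds_rejected(self, rng):
        df = _frame(rng.normal(size=(10, 2)), np.repeat([0, 1], 5))
        with pytest.raises(ValueError):
            cv_error(df, k_folds=11)

    def test_same_seed_same_folds_and_error(self, default_phenology):
        a = cv_error(default_phenology, m_rounds=20, seed=3)
        b = cv_error(default_phenology, m_rounds=20, seed=3)
        assert a.error_rate == b.error_rate
        assert a.per_fold == b.per_fold


class TestPermutation:
    def test_minimum_attainable_pvalue(self, rng):
        # perfectly separable: observed error 0 beats every permutation
        y = np.repeat([0, 1, 2], 20)
        X = y[:, None] + 0.01 * rng.normal(size=(60, 1))
        df = _frame(X, y, sex=np.tile(["F", "M"], 30))
        p = permutation_pvalue(df, n_perm=19, k_folds=3, m_rounds=5, seed=0)
        assert p == pytest.approx(1 / 20)

    def test_null_features_rarely_significant(self, rng):
        hits = 0
        n_rep = 10
        for r in range(n_rep):
            y = np.repeat([0, 1, 2], 14)
            df = _frame(np.random.default_rng(r).normal(size=(42, 2)), y)
            p = permutation_pvalue(df, n_perm=19, k_folds=3, m_rounds=5, seed=r)
            if p < 0.05:
                hits += 1
        assert hits <= 1  # p >= 0.05 in at least 90% of replicates


class TestFeatureTools:
    def test_duplicate_feature_dropped_once(self, rng):
        x = rng.normal(size=100)
        df = _frame(np.column_stack([x, x, rng.normal(size=100)]),
                    rng.integers(0, 2, 100))
        _, dropped = drop_correlated_features(df, threshold=0.9)
        assert len(dropped) == 1
        assert dropped[0] in ("f0", "f1")

    def test_independent_features_untouched(self, rng):
        df = _frame(rng.normal(size=(200, 4)), rng.integers(0, 2, 200))
        _, dropped = drop_correlated_features(df, threshold=0.9)
        assert dropped == []

    def test_correlated_trio_matches_enumeration_oracle(self, rng):
        # one latent driver, three noisy copies: every pair correlates > 0.9,
        # so the minimal removal set has size two
        z = rng.normal(size=400)
        X = np.column_stack(
            [z + 0.05 * rng.normal(size=400) for _ in range(3)]
        )
        df = _frame(X, rng.integers(0, 2, 400))
        reduced, dropped = drop_correlated_features(df, threshold=0.9)
        corr = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(corr, 0)
        # enumeration oracle: smallest subset whose removal clears the threshold
        from itertools import combinations

        best = None
        for k in range(3):
            for keep in combinations(range(3), 3 - k):
                sub = corr[np.ix_(keep, keep)]
                if (sub <= 0.9).all():
                    best = k
                    break
            if best is not None:
                break
        assert len(dropped) == best == 2

    def test_constant_feature_flagged_not_tested(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        df = _frame(X, rng.integers(0, 2, 50))
        with pytest.warns(UserWarning, match="constant"):
            _, dropped = drop_correlated_features(df, threshold=0.9)
        assert dropped == []


class TestImportances:
    def test_importances_sum_to_one(self, default_phenology):
        model = train_samme(default_phenology, m_rounds=30, seed=0)
        assert np.isclose(model.feature_importances_.sum(), 1.0, atol=1e-9)

    def test_single_informative_feature_ranks_first(self, rng):
        y = rng.integers(0, 3, 150)
        X = np.column_stack([y + 0.01 * rng.normal(size=150),
                             rng.normal(size=150), rng.normal(size=150)])
        df = _frame(X, y)
        model = train_samme(df, m_rounds=20, seed=0)
        table = cumulative_importance_ranking(model)
        assert table.iloc[0]["feature"] == "f0"
        assert table.iloc[0]["importance"] > 0.9
        assert table["cumulative_importance"].iloc[-1] == pytest.approx(1.0, abs=1e-9)
        assert table["importance"].is_monotonic_decreasing

    def test_duplicated_informative_feature_shares_importance(self, rng):
        y = rng.integers(0, 3, 200)
        base = y + 0.05 * rng.normal(size=200)
        df_single = _frame(np.column_stack([base, rng.normal(size=200)]), y)
        df_dup = _frame(
            np.column_stack([base, base.copy(), rng.normal(size=200)]), y
        )
        m1 = train_samme(df_single, m_rounds=20, seed=0)
        m2 = train_samme(df_dup, m_rounds=20, seed=0)
        # combined importance of the two copies matches the single-copy run
        single_imp = m1.feature_importances_[0]
        combined = m2.feature_importances_[0] + m2.feature_importances_[1]
        assert combined == pytest.approx(single_imp, abs=0.05)
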