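import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutresponse.predictor import (
    TieredResponseClassifier,
    combine_probabilities,
    cv_feature_select,
    fuse_multiomics,
    roc_auc,
    train_tiered,
)


class TestCombineProbabilities:
    def test_certain_sd(self):
        assert combine_probabilities(0.3, 1.0) == (0.0, 1.0, 0.0)

    def test_certain_pr(self):
        assert combine_probabilities(1.0, 0.0) == (0.0, 0.0, 1.0)

    def test_formula_evaluation(self):
        p_pd, p_sd, p_pr = combine_probabilities(0.6, 0.5)
        assert (p_pd, p_sd, p_pr) == pytest.approx((0.2, 0.5, 0.3))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_probabilities(1.2, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=200)
    def test_sums_to_one(self, pa, pb):
        p_pd, p_sd, p_pr = combine_probabilities(pa, pb)
        assert abs(p_pd + p_sd + p_pr - 1.0) <= 1e-9
        assert min(p_pd, p_sd, p_pr) >= 0


class TestRocAuc:
    def test_perfect_ordering(self):
        auc, lo, hi = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_concordant_pair_count(self):
        # pairs: (0.9>0.8)+, (0.9>0.2)+, (0.4<0.8)-, (0.4>0.2)+ -> 3/4
        auc, _, _ = roc_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_full_ties_half(self):
        auc, _, _ = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == pytest.approx(0.5)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        labels[0] = True
        labels[1] = False
        auc, lo, hi = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert lo <= auc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestFuseMultiomics:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["p_pd", "p_sd", "p_pr"], index=["s1"])

    def test_single_input_identity(self):
        t = self._table([[0.2, 0.5, 0.3]])
        out = fuse_multiomics([t])
        np.testing.assert_allclose(out.to_numpy(), t.to_numpy())

    def test_identical_inputs_identity(self):
        t = self._table([[0.2, 0.5, 0.3]])
        out = fuse_multiomics([t, t.copy()])
        np.testing.assert_allclose(out.to_numpy(), t.to_numpy())

    def test_arithmetic_mean(self):
        a = self._table([[0.2, 0.5, 0.3]])
        b = self._table([[0.4, 0.1, 0.5]])
        out = fuse_multiomics([a, b])
        np.testing.assert_allclose(out.to_numpy()[0], [0.3, 0.3, 0.4], atol=1e-12)

    def test_mismatched_samples_rejected(self):
        a = self._table([[0.2, 0.5, 0.3]])
        b = a.copy()
        b.index = ["s2"]
        with pytest.raises(ValueError, match="identical samples"):
            fuse_multiomics([a, b])


class TestCvFeatureSelect:
    def test_planted_separator_ranks_first(self, rng):
        n, p = 16, 201
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)]
        )
        y = np.array(["a"] * 8 + ["b"] * 8)
        X["f0"] = np.where(y == "a", 2.0, -2.0) + rng.normal(0, 0.05, n)
        ranking = cv_feature_select(X, y, seed=3, n_reps=200)
        assert ranking.iloc[0]["feature"] == "f0"

    def test_minimal_smoke_case(self, rng):
        X = rng.normal(size=(4, 6))
        y = np.array(["a", "a", "b", "b"])
        ranking = cv_feature_select(X, y, n_folds=2, n_reps=1, seed=0)
        assert len(ranking) == 6
        assert set(ranking["feature"]) == {f"f{j}" for j in range(6)}

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(12, 30))
        y = np.array(["a", "b"] * 6)
        r1 = cv_feature_select(X, y, n_reps=20, seed=5)
        r2 = cv_feature_select(X, y, n_reps=20, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_ranks_roughly_exchangeable(self):
        """With pure-noise features no fixed feature should be
        systematically favoured: its rank is near-uniform over seeds."""
        from scipy import stats

        p = 40
        ranks = []
        for seed in range(30):
            rng = np.random.default_rng(9000 + seed)
            X = rng.normal(size=(16, p))
            y = np.array(["a", "b"] * 8)
            ranking = cv_feature_select(X, y, n_reps=30, seed=seed)
            ranks.append(ranking.index[ranking["feature"] == "f7"][0])
        u = (np.asarray(ranks) + 0.5) / p
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            cv_feature_select(rng.normal(size=(6, 4)), np.array(["a"] * 6))


def _separable_data(rng, n_per=12):
    """Three linearly separable classes on two informative features."""
    centers = {"PD": (4.0, 0.0), "SD": (0.0, 4.0), "PR": (-4.0, -4.0)}
    rows, labels = [], []
    for cls, (cx, cy) in centers.items():
        for _ in range(n_per):
            rows.append(
                np.concatenate(
                    [[cx, cy] + rng.normal(0, 0.3, 2), rng.normal(0, 1, 30)]
                )
            )
            labels.append(cls)
    X = pd.DataFrame(rows, columns=[f"f{j}" for j in range(32)])
    X.index = [f"s{i}" for i in range(len(X))]
    return X, np.array(labels)


class TestTieredClassifier:
    def test_separable_classes_training_auc_one(self, rng):
        X, y = _separable_data(rng)
        model = TieredResponseClassifier(
            n_train_pr=8, n_train_pd=8, n_train_sd=10, n_reps=30, random_state=0
        ).fit(X, y)
        probs = model.predict_table(X.loc[model.training_sample_ids_])
        yt = pd.Series(y, index=X.index).loc[model.training_sample_ids_]
        for cls, col in (("PD", "p_pd"), ("SD", "p_sd"), ("PR", "p_pr")):
            auc, _, _ = roc_auc(probs[col].to_numpy(), (yt == cls).to_numpy())
            assert auc == 1.0

    def test_deterministic_given_seed(self, rng):
        X, y = _separable_data(rng)
        m1 = train_tiered(X, y, {"PR": 8, "PD": 8, "SD": 10},
                          {"n_reps": 20}, seed=4)
        m2 = train_tiered(X, y, {"PR": 8, "PD": 8, "SD": 10},
                          {"n_reps": 20}, seed=4)
        assert m1.features_a_ == m2.features_a_
        assert m1.features_b_ == m2.features_b_
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_probabilities_sum_to_one(self, rng):
        X, y = _separable_data(rng)
        model = TieredResponseClassifier(
            n_train_pr=8, n_train_pd=8, n_train_sd=10, n_reps=10, random_state=1
        ).fit(X, y)
        probs = model.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_prediction_invariant_under_column_permutation(self, rng):
        X, y = _separable_data(rng)
        model = TieredResponseClassifier(
            n_train_pr=8, n_train_pd=8, n_train_sd=10, n_reps=10, random_state=2
        ).fit(X, y)
        shuffled = X[list(rng.permutation(X.columns))]
        np.testing.assert_allclose(
            model.predict_proba(X), model.predict_proba(shuffled), atol=1e-12
        )

    def test_training_overlap_contract(self, rng):
        X, y = _separable_data(rng)
        model = TieredResponseClassifier(
            n_train_pr=8, n_train_pd=8, n_train_sd=10, n_reps=10, random_state=3
        ).fit(X, y)
        ys = pd.Series(y, index=X.index)
        train = model.training_sample_ids_
        assert len(train) == 26  # 8 PR + 8 PD + 10 SD
        assert (ys.loc[train].value_counts().to_dict()
                == {"SD": 10, "PR": 8, "PD": 8})
        assert set(model.held_out_ids_).isdisjoint(train)

    def test_insufficient_class_size_names_class(self, rng):
        X, y = _separable_data(rng, n_per=5)
        with pytest.raises(ValueError, match="SD"):
            TieredResponseClassifier(
                n_train_pr=4, n_train_pd=4, n_train_sd=8, random_state=0
            ).fit(X, y)


def test_label_permuted_training_gives_chance_auc(rng):
    """With labels shuffled against the features the held-out AUC hovers
    around 0.5 on average."""
    aucs = []
    for seed in range(5):
        local = np.random.default_rng(seed)
        X, y = _separable_data(local, n_per=14)
        y = local.permutation(y)
        model = TieredResponseClassifier(
            n_train_pr=8, n_train_pd=8, n_train_sd=10, n_reps=20,
            random_state=seed,
        ).fit(X, y)
        yv = pd.Series(y, index=X.index).loc[model.held_out_ids_]
        probs = model.predict_table(X.loc[model.held_out_ids_])
        for cls, col in (("PD", "p_pd"), ("SD", "p_sd"), ("PR", "p_pr")):
            if (yv == cls).nunique() == 2:
                auc, _, _ = roc_auc(probs[col].to_numpy(), (yv == cls).to_numpy())
                aucs.append(auc)
    assert abs(np.mean(aucs) - 0.5) <= 0.15
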