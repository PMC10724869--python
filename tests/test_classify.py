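"""Classification stage: split arithmetic, Kappa/NIR statistics, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from asymkit.classify import (
    ClassificationSummary,
    classify_index_table,
    cohen_kappa,
    evaluate_model,
    kappa_band,
    nir_test,
    rank_predictors,
    split_train_test,
    train_random_forest,
)


def _xy(n_per_class, n_features=5, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(0, 1, (2 * n_per_class, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    y = pd.Series(["male"] * n_per_class + ["female"] * n_per_class, index=X.index)
    X.iloc[:n_per_class] += shift
    return X, y


class TestSplit:
    def test_stratified_80_20_counts(self):
        X, y = _xy(50)
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, 0.8, seed=0)
        assert len(X_tr) == 80 and len(X_te) == 20
        assert (y_tr == "male").sum() == 40 and (y_te == "male").sum() == 10
        assert set(X_tr.index).isdisjoint(X_te.index)
        assert len(X_tr) + len(X_te) == len(X)

    def test_same_seed_same_partition(self):
        X, y = _xy(50)
        a = split_train_test(X, y, 0.8, seed=7)[0]
        b = split_train_test(X, y, 0.8, seed=7)[0]
        assert list(a.index) == list(b.index)

    def test_half_split_on_ten(self):
        X, y = _xy(5)
        X_tr, X_te, *_ = split_train_test(X, y, 0.5, seed=0)
        assert len(X_tr) == 5 and len(X_te) == 5

    def test_too_small_class_rejected(self):
        X, y = _xy(1)
        with pytest.raises(ValueError):
            split_train_test(X, y, 0.8, seed=0)


class TestKappa:
    def test_hand_computed_example(self):
        # p_o = 0.7, p_e = (50*60 + 50*40)/100^2 = 0.5 -> kappa = 0.4
        assert cohen_kappa([[40, 10], [20, 30]]) == pytest.approx(0.40, abs=1e-12)

    def test_perfect_diagonal(self):
        assert cohen_kappa([[25, 0], [0, 75]]) == pytest.approx(1.0)

    def test_majority_predictor_has_zero_kappa(self):
        assert cohen_kappa([[60, 40], [0, 0]]) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(0, 200), min_size=4, max_size=4))
    def test_matches_sklearn_on_random_matrices(self, counts):
        """Closed form (p_o-p_e)/(1-p_e) vs sklearn's independent computation."""
        a, b, c, d = counts
        if a + b + c + d == 0:
            return
        y_pred = ["m"] * (a + b) + ["f"] * (c + d)
        y_true = ["m"] * a + ["f"] * b + ["m"] * c + ["f"] * d
        marg = (a + b) * (a + c) + (c + d) * (b + d)
        if marg == (a + b + c + d) ** 2:  # degenerate p_e == 1
            return
        expected = cohen_kappa_score(y_true, y_pred)
        assert cohen_kappa([[a, b], [c, d]]) == pytest.approx(expected, abs=1e-12)

    def test_band_labels(self):
        assert kappa_band(-0.1) == "worse-than-chance"
        assert kappa_band(0.13) == "slight"
        assert kappa_band(0.25) == "fair"
        assert kappa_band(0.5) == "good"
        assert kappa_band(0.7) == "very good"


class TestNIRTest:
    def test_sixty_of_hundred_vs_direct_pmf_sum(self):
        expected = sum(stats.binom.pmf(k, 100, 0.5) for k in range(60, 101))
        p = nir_test(60, 100, 0.5)
        assert p == pytest.approx(expected, rel=1e-10)
        assert p == pytest.approx(0.0284, abs=5e-4)

    def test_at_null_center_not_significant(self):
        assert nir_test(50, 100, 0.5) > 0.4

    def test_all_correct_closed_form(self):
        assert nir_test(10, 10, 0.6) == pytest.approx(0.6**10, rel=1e-12)

    @pytest.mark.parametrize("nir", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_nir_rejected(self, nir):
        with pytest.raises(ValueError):
            nir_test(5, 10, nir)


class TestForest:
    def test_separable_predictor_gives_perfect_accuracy_and_top_rank(self):
        X, y = _xy(40, n_features=4, seed=1)
        X["signal"] = (y == "male").astype(float) * 2 - 1
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, 0.8, seed=0)
        model = train_random_forest(X_tr, y_tr, n_trees=100, seed=0)
        summary = evaluate_model(model, X_te, y_te)
        assert summary.accuracy == 1.0 and summary.kappa == 1.0
        ranking = rank_predictors(model, X_te, y_te, seed=0)
        assert ranking.iloc[0]["predictor"] == "signal"

    def test_duplicated_informative_columns_share_top_ranks(self):
        X, y = _xy(60, n_features=3, seed=2)
        signal = (y == "male").astype(float) + np.random.default_rng(0).normal(0, 0.3, len(y))
        X["sig_a"], X["sig_b"] = signal, signal.copy()
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, 0.8, seed=0)
        model = train_random_forest(X_tr, y_tr, n_trees=200, seed=0)
        ranking = rank_predictors(model, X_te, y_te, seed=0)
        assert {"sig_a", "sig_b"} <= set(ranking["predictor"].head(3))

    def test_pure_noise_accuracy_near_chance(self):
        accs = []
        for seed in range(6):
            X, y = _xy(60, n_features=10, seed=seed)
            X_tr, X_te, y_tr, y_te = split_train_test(X, y, 0.8, seed=seed)
            model = train_random_forest(X_tr, y_tr, n_trees=100, seed=seed)
            accs.append(evaluate_model(model, X_te, y_te).accuracy)
        # pooled over 6*24 = 144 test subjects, binomial 3-sigma band around 0.5
        assert abs(np.mean(accs) - 0.5) < 3 * np.sqrt(0.25 / 144)

    def test_constant_predictors_dropped_with_warning(self):
        X, y = _xy(20, n_features=3, seed=3)
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            model = train_random_forest(X, y, n_trees=20, seed=0)
        assert "flat" not in model.predictors
        with pytest.raises(ValueError, match="constant"):
            train_random_forest(X[["flat"]], y, n_trees=20, seed=0)

    def test_grid_search_selects_from_grid(self):
        X, y = _xy(30, n_features=6, seed=4, shift=1.0)
        model = train_random_forest(X, y, cv_folds=3, mtry_grid=(1, 3), n_trees=50, seed=0)
        assert model.best_mtry in (1, 3)

    def test_full_pipeline_deterministic(self, small_cohort):
        from asymkit.indices import compute_index_tables

        table = compute_index_tables(small_cohort.morphometry["volume"],
                                     kinds=("DI",))["DI"]
        a = classify_index_table(table.values, small_cohort.meta, seed=5,
                                 n_trees=50, importance_repeats=2)
        b = classify_index_table(table.values, small_cohort.meta, seed=5,
                                 n_trees=50, importance_repeats=2)
        assert a.confusion.equals(b.confusion)
        assert a.accuracy == b.accuracy
        pd.testing.assert_frame_equal(a.importances, b.importances)

    def test_confusion_layout_and_percentages(self):
        X, y = _xy(10, n_features=2, seed=0)
        X["signal"] = (y == "male").astype(float)
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, 0.5, seed=0)
        model = train_random_forest(X_tr, y_tr, n_trees=20, seed=0)
        s = evaluate_model(model, X_te, y_te)
        assert list(s.confusion.index) == ["male", "female"]       # prediction rows
        assert list(s.confusion.columns) == ["male", "female"]     # target columns
        assert s.confusion.to_numpy().sum() == len(X_te)
        assert s.nir == max((y_te == "male").mean(), (y_te == "female").mean())
        # column percentages sum to 100 within each target class
        np.testing.assert_allclose(s.col_pct.sum(axis=0), [100.0, 100.0])
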