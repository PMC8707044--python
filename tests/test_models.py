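import itertools

import numpy as np
import pandas as pd
import pytest

from wheatlai.evaluation import r_squared
from wheatlai.models import (
    SplitSpec,
    SvrGrid,
    adjusted_r2,
    best_subset_regression,
    fit_svr,
    predict,
    train_test_split,
)


class TestSplit:
    def test_48_samples_give_36_12(self):
        train, val = train_test_split(48, SplitSpec(0.75, seed=1))
        assert len(train) == 36 and len(val) == 12
        assert np.array_equal(np.sort(np.concatenate([train, val])), np.arange(48))

    def test_deterministic_under_seed(self):
        a = train_test_split(48, SplitSpec(0.75, seed=5))
        b = train_test_split(48, SplitSpec(0.75, seed=5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.5])
    def test_degenerate_fractions_rejected(self, frac):
        with pytest.raises(ValueError):
            SplitSpec(frac)


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(0.0, 10.0, 20, 3) == 1.0

    def test_null_model(self):
        # RSS = TSS with k = 0: the n-1 factors cancel
        assert adjusted_r2(10.0, 10.0, 25, 0) == pytest.approx(0.0, abs=1e-15)

    def test_hand_arithmetic(self):
        assert adjusted_r2(2.0, 10.0, 10, 2) == pytest.approx(
            1 - (2 / 7) / (10 / 9), abs=1e-12
        )

    def test_no_residual_dof(self):
        with pytest.raises(ValueError):
            adjusted_r2(1.0, 2.0, 5, 4)


def brute_force_best_subset(X: pd.DataFrame, y: np.ndarray):
    """Independent re-enumeration: raw normal-equation fits per subset."""
    n = len(y)
    tss = ((y - y.mean()) ** 2).sum()
    best_key, best_names = None, None
    for size in range(1, X.shape[1] + 1):
        for names in itertools.combinations(X.columns, size):
            A = np.column_stack([np.ones(n), X[list(names)].to_numpy()])
            beta = np.linalg.pinv(A) @ y
            rss = ((y - A @ beta) ** 2).sum()
            adj = 1 - (rss / (n - size - 1)) / (tss / (n - 1))
            key = (-adj, size, names)
            if best_key is None or key < best_key:
                best_key, best_names = key, names
    return best_names, -best_key[0]


class TestBestSubset:
    def test_exact_single_predictor_wins(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=30)
        X = pd.DataFrame(
            {"x1": x1, "n2": rng.normal(size=30), "n3": rng.normal(size=30)}
        )
        model = best_subset_regression(X, 3.0 * x1)
        assert model.feature_labels == ["x1"]
        assert model.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert model.coefficients[0] == pytest.approx(3.0, abs=1e-9)

    def test_evaluates_all_1023_subsets_for_10_candidates(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 10)),
                         columns=[f"f{i}" for i in range(10)])
        model = best_subset_regression(X, rng.normal(size=40))
        assert model.n_subsets_evaluated == 1023
        assert len(model.ranking) == 1023

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(25, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = X["f0"].to_numpy() + 0.5 * X["f3"].to_numpy() + rng.normal(0, 0.3, 25)
        model = best_subset_regression(X, y)
        names, adj = brute_force_best_subset(X, y)
        assert tuple(model.feature_labels) == names
        assert model.adj_r2 == pytest.approx(adj, abs=1e-9)

    def test_pure_noise_candidate_never_helps(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=40)
        y = 2.0 * x1 + rng.normal(0, 0.2, 40)
        base = best_subset_regression(pd.DataFrame({"x1": x1}), y)
        extended = best_subset_regression(
            pd.DataFrame({"x1": x1, "noise": rng.normal(size=40)}), y
        )
        assert extended.adj_r2 >= base.adj_r2 - 1e-12
        assert "x1" in extended.feature_labels

    def test_collinear_subsets_flagged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        model = best_subset_regression(X, x + rng.normal(0, 0.1, 20))
        assert ("a", "b") in model.collinear_flagged

    def test_candidate_bound_enforced(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(20, 16)))
        X.columns = [f"f{i}" for i in range(16)]
        with pytest.raises(ValueError, match="exceed"):
            best_subset_regression(X, rng.normal(size=20))


class TestSvr:
    def test_noise_free_linear_target_fits_tightly(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 48), "b": rng.uniform(0, 1, 48)})
        y = 1.0 + 2.0 * X["a"].to_numpy()
        model = fit_svr(X, y, seed=0)
        assert r_squared(y, predict(model, X)) >= 0.99

    def test_training_predictions_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = X["a"].to_numpy() - X["c"].to_numpy() + rng.normal(0, 0.05, 40)
        m1 = fit_svr(X, y, seed=3)
        m2 = fit_svr(X * [100.0, 0.01, 1.0], y, seed=3)
        np.testing.assert_allclose(
            predict(m1, X), predict(m2, X * [100.0, 0.01, 1.0]), atol=1e-6
        )

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=30), "flat": np.ones(30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_svr(X, X["a"].to_numpy(), seed=0)
        assert model.feature_labels == ["a"]

    def test_captures_nonlinearity_better_than_linear_fit(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lai = rng.uniform(1, 4, 48)
            feat = np.exp(-0.8 * lai) + rng.normal(0, 0.002, 48)
            X = pd.DataFrame({"z": feat})
            train, val = train_test_split(48, SplitSpec(0.75, seed))
            svr = fit_svr(X, lai, train, SvrGrid(), seed)
            lin = best_subset_regression(X, lai, train)
            r2_svr = r_squared(lai[val], predict(svr, X.iloc[val]))
            r2_lin = r_squared(lai[val], predict(lin, X.iloc[val]))
            wins += r2_svr >= r2_lin
        assert wins >= 3


class TestPredict:
    def test_subset_model_linear_form(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        model = best_subset_regression(X, 1.0 + 2.0 * X["x"].to_numpy())
        out = predict(model, pd.DataFrame({"x": [3.0]}))
        assert out[0] == pytest.approx(7.0, abs=1e-9)

    def test_prediction_is_label_keyed_not_positional(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        y = X["a"].to_numpy() + 2 * X["b"].to_numpy() + rng.normal(0, 0.01, 30)
        model = best_subset_regression(X, y)
        np.testing.assert_allclose(
            predict(model, X[["c", "b", "a"]]), predict(model, X), atol=1e-12
        )

    def test_missing_feature_column_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        model = best_subset_regression(X, X["x"].to_numpy() * 2)
        with pytest.raises(KeyError, match="missing"):
            predict(model, pd.DataFrame({"other": [1.0]}))
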