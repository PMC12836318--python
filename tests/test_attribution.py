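"""Shapley attribution: axioms, exact-vs-fast agreement, ranking, export."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor

from dabarrier.attribution import (
    correlation_matrix,
    exact_shapley,
    export_summary,
    fast_shapley,
    rank_features,
    shap_feature_reduction,
)
from dabarrier.model import BarrierModel, ModelConfig
from dabarrier.descriptors import REDUCED_FEATURES


def _random_forest(rng, n_features, n_trees=12, n_rows=80):
    X = rng.normal(size=(n_rows, n_features))
    y = X @ rng.normal(size=n_features) + rng.normal(size=n_rows) * 0.3
    if n_features >= 2:  # add an interaction so trees are not additive
        y = y + X[:, 0] * X[:, 1]
    model = RandomForestRegressor(
        n_estimators=n_trees, max_depth=4, random_state=int(rng.integers(2**31))
    ).fit(X, y)
    return model, X


class TestAxioms:
    def test_dummy_feature_gets_zero_attribution(self, rng):
        # model provably independent of feature 1
        def predict(X):
            return 2.0 * X[:, 0] + X[:, 2] ** 2

        X = rng.normal(size=(4, 3))
        Z = rng.normal(size=(20, 3))
        res = exact_shapley(predict, X, Z)
        assert np.allclose(res.phi[:, 1], 0.0, atol=1e-12)

    def test_additive_model_with_zero_mean_background(self):
        def predict(X):
            return X[:, 0] + X[:, 1]

        X = np.array([[2.0, -1.0]])
        Z = np.array([[1.0, -3.0], [-1.0, 3.0]])  # column means zero
        res = exact_shapley(predict, X, Z)
        assert res.phi[0] == pytest.approx([2.0, -1.0])
        assert res.base_value == pytest.approx(0.0)

    def test_symmetric_players_with_equal_values_split_equally(self, rng):
        def predict(X):
            return X[:, 0] * X[:, 1] + 0.5 * X[:, 2]

        X = np.array([[1.3, 1.3, 0.2]])
        # symmetry requires the value function, hence the background, to be
        # exchangeable in the two players: duplicate the background column
        Z = rng.normal(size=(30, 3))
        Z[:, 1] = Z[:, 0]
        res = exact_shapley(predict, X, Z)
        # f is symmetric in features 0, 1 and their values coincide
        assert res.phi[0, 0] == pytest.approx(res.phi[0, 1], abs=1e-10)

    def test_efficiency_holds_per_sample(self, rng):
        model, X = _random_forest(rng, 5)
        res = fast_shapley(model, X[:40], X[40:])
        assert np.abs(res.efficiency_residuals()).max() < 1e-6

    def test_three_feature_tree_matches_hand_expanded_coalition_sums(self):
        # depth-2 tree on binary inputs; coalition sums expanded manually
        X_fit = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0],
                          [0, 0, 1], [0, 1, 1], [1, 0, 1], [1, 1, 1]], float)
        y_fit = np.array([0.0, 0.0, 1.0, 3.0, 0.0, 0.0, 1.0, 3.0])
        tree = DecisionTreeRegressor(max_depth=2, random_state=0).fit(X_fit, y_fit)
        x = np.array([[1.0, 1.0, 1.0]])
        z = np.array([[0.0, 0.0, 0.0]])
        # v(S) over the single background row:
        # {}:0, {1}:0, {2}:0, {3}:0, {12}:3, {13}:1? -> predict directly
        def v(mask):
            h = z.copy()
            for j in range(3):
                if mask >> j & 1:
                    h[0, j] = x[0, j]
            return float(tree.predict(h)[0])

        phi_hand = np.zeros(3)
        import itertools, math

        for j in range(3):
            for mask in range(8):
                if mask >> j & 1:
                    continue
                s = bin(mask).count("1")
                w = math.factorial(s) * math.factorial(3 - s - 1) / math.factorial(3)
                phi_hand[j] += w * (v(mask | 1 << j) - v(mask))
        res = exact_shapley(tree, x, z)
        assert np.allclose(res.phi[0], phi_hand, atol=1e-12)
        fast = fast_shapley(tree, x, z)
        assert np.allclose(fast.phi[0], phi_hand, atol=1e-12)


class TestFastVsExact:
    def test_agreement_on_many_random_forests(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for case in range(30):
            k = int(rng.integers(3, 9))
            model, X = _random_forest(rng, k)
            xs, zs = X[:2], X[2:18]
            fast = fast_shapley(model, xs, zs)
            exact = exact_shapley(model, xs, zs)
            worst = max(worst, float(np.abs(fast.phi - exact.phi).max()))
        assert worst < 1e-4

    def test_agreement_for_gradient_boosting(self, rng):
        X = rng.normal(size=(60, 4))
        y = X[:, 0] - 2 * X[:, 2] + X[:, 1] * X[:, 3]
        model = GradientBoostingRegressor(n_estimators=40, random_state=0).fit(X, y)
        fast = fast_shapley(model, X[:3], X[10:30])
        exact = exact_shapley(model, X[:3], X[10:30])
        assert np.abs(fast.phi - exact.phi).max() < 1e-6
        assert np.abs(fast.efficiency_residuals()).max() < 1e-6

    def test_non_tree_model_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        model = LinearRegression().fit(X, X[:, 0])
        with pytest.raises(TypeError, match="tree"):
            fast_shapley(model, X[:2], X[5:])

    def test_exact_refuses_large_feature_sets(self, rng):
        X = rng.normal(size=(20, 13))
        with pytest.raises(ValueError, match="fast_shapley"):
            exact_shapley(lambda A: A[:, 0], X[:1], X[5:])

    def test_empty_background_rejected(self, rng):
        model, X = _random_forest(rng, 3)
        with pytest.raises(ValueError, match="background"):
            fast_shapley(model, X[:1], X[:0])


class TestRanking:
    def test_dominant_feature_ranks_first(self, rng):
        def predict(X):
            return 10.0 * X[:, 2] + 0.1 * X[:, 0]

        X = rng.normal(size=(8, 3))
        res = exact_shapley(predict, X, rng.normal(size=(25, 3)),
                            feature_names=["a", "b", "c"])
        assert rank_features(res)[0] == "c"
        assert rank_features(res)[-1] == "b"

    def test_ties_break_alphabetically(self):
        from dabarrier.attribution import AttributionResult

        res = AttributionResult(
            phi=np.array([[1.0, -1.0, 2.0]]),
            base_value=0.0,
            feature_values=np.zeros((1, 3)),
            feature_names=["zeta", "alpha", "mid"],
            predictions=np.array([2.0]),
        )
        assert rank_features(res) == ["mid", "alpha", "zeta"]

    def test_importance_invariant_to_sample_order(self, rng):
        model, X = _random_forest(rng, 5)
        a = fast_shapley(model, X[:30], X[40:]).global_importance
        b = fast_shapley(model, X[:30][::-1], X[40:]).global_importance
        for k in a:
            assert a[k] == pytest.approx(b[k])


class TestReductionAndExport:
    def test_injected_noise_decoys_are_dropped(self, default_dataset):
        df, _ = default_dataset
        rng = np.random.default_rng(0)
        X = df[list(REDUCED_FEATURES)].copy()
        for j in range(3):
            X[f"decoy_{j}"] = rng.normal(size=len(X))
        y = df["dg_act_min"].to_numpy()

        def fit_fn(Xf, yv):
            return RandomForestRegressor(n_estimators=60, random_state=0).fit(
                Xf.to_numpy(float), yv
            )

        kept, reduced_model, full_res, X_red = shap_feature_reduction(
            X, y, fit_fn, keep_k=13, n_explain=48, background_size=32, seed=0
        )
        assert not any(f.startswith("decoy") for f in kept)
        assert len(kept) == 13

    def test_zero_threshold_keeps_every_feature(self, default_dataset):
        df, _ = default_dataset
        X = df[list(REDUCED_FEATURES)].iloc[:300]
        y = df["dg_act_min"].to_numpy()[:300]

        def fit_fn(Xf, yv):
            return RandomForestRegressor(n_estimators=30, random_state=0).fit(
                Xf.to_numpy(float), yv
            )

        kept, model, _, _ = shap_feature_reduction(
            X, y, fit_fn, threshold=0.0, keep_k=None,
            n_explain=16, background_size=16, seed=0,
        )
        assert kept == list(X.columns)
        assert type(model).__name__ == "RandomForestRegressor"

    def test_reduction_below_two_features_raises(self, default_dataset):
        df, _ = default_dataset
        X = df[list(REDUCED_FEATURES)].iloc[:200]
        y = df["dg_act_min"].to_numpy()[:200]

        def fit_fn(Xf, yv):
            return RandomForestRegressor(n_estimators=20, random_state=0).fit(
                Xf.to_numpy(float), yv
            )

        with pytest.raises(ValueError, match=">= 2"):
            shap_feature_reduction(X, y, fit_fn, keep_k=1,
                                   n_explain=8, background_size=8, seed=0)

    def test_export_summary_shape_and_roundtrip(self, rng, tmp_path):
        model, X = _random_forest(rng, 4)
        res = fast_shapley(model, X[:10], X[20:40],
                           feature_names=["f1", "f2", "f3", "f4"])
        out = tmp_path / "summary.csv"
        frame = export_summary(res, out)
        assert len(frame) == 10 * 4
        back = pd.read_csv(out)
        pd.testing.assert_frame_equal(back, frame, check_dtype=False)

    def test_duplicated_feature_has_unit_correlation(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X["b"] = X["a"]
        X["c"] = rng.normal(size=50)
        corr = correlation_matrix(X)
        assert abs(corr.loc["a", "b"]) == pytest.approx(1.0)

    def test_sigma_p_attribution_sign_on_dienophile(self, default_dataset):
        # electron withdrawal at the dienophile (high sigma_p) shrinks the
        # normal gap and lowers the barrier: its attribution skews negative
        df, _ = default_dataset
        bm = BarrierModel(df, config=ModelConfig(n_trees=150))
        res = bm.fit(seed=0)
        attr = res.shapley_values(n_explain=120, background_size=40, seed=0)
        frame = export_summary(attr)
        j = attr.feature_names.index("sigma_p_C5")
        vals = attr.feature_values[:, j]
        phis = attr.phi[:, j]
        high = vals >= np.quantile(vals, 0.8)
        low = vals <= np.quantile(vals, 0.2)
        assert phis[high].mean() < phis[low].mean()

    def test_ranking_stable_across_disjoint_halves(self, default_dataset):
        from scipy.stats import spearmanr

        df, _ = default_dataset
        half = len(df) // 2
        ranks = []
        for part in (df.iloc[:half], df.iloc[half:]):
            bm = BarrierModel(part, config=ModelConfig(n_trees=150))
            res = bm.fit(seed=0)
            attr = res.shapley_values(n_explain=40, background_size=32, seed=0)
            imp = attr.global_importance
            ranks.append([imp[f] for f in sorted(imp)])
        rho = spearmanr(ranks[0], ranks[1]).statistic
        assert rho >= 0.8
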