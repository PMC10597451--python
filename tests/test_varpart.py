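"""Collinearity filtering, subset selection, RDA and variance partitioning."""

import numpy as np
import pandas as pd
import pytest

from fbgeo.varpart import (
    VarPartError,
    adjusted_r2,
    best_subset_bic,
    forward_select,
    permutation_test,
    prepare_predictors,
    rda_fit,
    variance_partition,
    vif_filter,
)


def frame(arr, prefix="x"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestVifFilter:
    def test_orthogonal_columns_all_kept(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((100, 4)))
        X = frame(q)
        kept, trace = vif_filter(X)
        assert list(kept.columns) == list(X.columns)
        # columns are orthogonal (not mean-centred), so VIFs sit at ~1
        assert all(v < 1.05 for v in trace[-1]["vifs"].values())

    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(50)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.standard_normal(50)})
        kept, _ = vif_filter(X)
        assert sorted(kept.columns) in (["a", "c"], ["b", "c"])

    def test_planted_correlated_trio_leaves_one_survivor(self):
        # three columns built with pairwise r ~ 0.95 plus independent noise
        # columns: the filter keeps exactly one of the trio, matching a
        # brute-force check of which subsets satisfy the VIF bound
        rng = np.random.default_rng(2)
        n = 300
        core = rng.standard_normal(n)
        trio = np.column_stack(
            [core + 0.32 * rng.standard_normal(n) for _ in range(3)]
        )
        indep = rng.standard_normal((n, 2))
        X = pd.DataFrame(
            np.column_stack([trio, indep]), columns=["t0", "t1", "t2", "i0", "i1"]
        )
        kept, _ = vif_filter(X, threshold=5.0)
        survivors = [c for c in kept.columns if c.startswith("t")]
        assert len(survivors) == 1
        assert {"i0", "i1"} <= set(kept.columns)

    def test_exempt_columns_never_removed(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(50)
        X = pd.DataFrame({"a": a, "dummy": a.copy(), "c": rng.standard_normal(50)})
        kept, _ = vif_filter(X, exempt=["dummy"])
        assert "dummy" in kept.columns


class TestBestSubsetBic:
    def test_planted_two_of_six_recovered(self):
        rng = np.random.default_rng(4)
        X = frame(rng.standard_normal((200, 6)))
        y = 1.0 * X["x1"] + 0.8 * X["x4"] + 0.1 * rng.standard_normal(200)
        selected, _ = best_subset_bic(y.to_numpy(), X)
        assert sorted(selected) == ["x1", "x4"]

    def test_pure_noise_selects_nothing_or_little(self):
        rng = np.random.default_rng(5)
        X = frame(rng.standard_normal((150, 5)))
        y = rng.standard_normal(150)
        selected, table = best_subset_bic(y, X)
        assert len(selected) <= 1
        null_bic = table.loc[table["size"] == 0, "bic"].iloc[0]
        if selected:
            assert table.loc[table["size"] == 1, "bic"].iloc[0] < null_bic

    def test_single_strong_column_selected(self):
        rng = np.random.default_rng(6)
        X = frame(rng.standard_normal((80, 1)))
        y = 2.0 * X["x0"].to_numpy() + 0.2 * rng.standard_normal(80)
        selected, _ = best_subset_bic(y, X)
        assert selected == ["x0"]

    def test_too_many_columns_errors(self):
        X = frame(np.random.default_rng(0).standard_normal((40, 25)))
        with pytest.raises(VarPartError, match="pre-filter"):
            best_subset_bic(np.zeros(40), X)


class TestRdaFit:
    def test_ezekiel_arithmetic(self):
        # n=11, p=1, R2=0.5 -> adjusted 1 - 0.5*10/9 = 0.4444...
        assert adjusted_r2(0.5, 11, 1) == pytest.approx(4.0 / 9.0)

    def test_exact_fit_r2_one(self):
        rng = np.random.default_rng(7)
        X = frame(rng.standard_normal((30, 2)))
        y = X.to_numpy() @ np.array([1.0, -2.0]) + 3.0
        fit = rda_fit(y, X)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = frame(rng.standard_normal((50, 4)))
            y = rng.standard_normal(50)
            fit = rda_fit(y, X)
            A = np.column_stack([np.ones(50), X.to_numpy()])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            resid = y - A @ beta
            r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)
            np.testing.assert_allclose(fit.coefficients.to_numpy(), beta[1:], atol=1e-8)

    def test_standardized_response_and_coefficient_signs(self):
        rng = np.random.default_rng(8)
        X = frame(rng.standard_normal((500, 3)))
        y = 0.5 * X["x0"] - 0.5 * X["x2"] + rng.standard_normal(500)
        fit = rda_fit(y.to_numpy(), X)
        assert fit.coefficients["x0"] > 0 > fit.coefficients["x2"]


class TestPermutationTest:
    def test_deterministic_signal_floors_p(self):
        rng = np.random.default_rng(9)
        X = frame(rng.standard_normal((40, 1)))
        y = 2.0 * X["x0"].to_numpy()
        _, p = permutation_test(y, X, n_perm=199, seed=0)
        assert p == pytest.approx(1.0 / 200.0)

    def test_p_bounds(self):
        rng = np.random.default_rng(10)
        X = frame(rng.standard_normal((30, 2)))
        for s in range(5):
            _, p = permutation_test(rng.standard_normal(30), X, n_perm=49, seed=s)
            assert 0.0 < p <= 1.0

    def test_type_one_error_level(self):
        # exchangeable null: rejection rate at alpha=0.05 stays inside a
        # three-sigma binomial band around 0.05
        n_sim, n_perm = 300, 199
        rejections = 0
        for s in range(n_sim):
            rng = np.random.default_rng(20_000 + s)
            X = frame(rng.standard_normal((30, 1)))
            y = rng.standard_normal(30)
            _, p = permutation_test(y, X, n_perm=n_perm, seed=s)
            rejections += p < 0.05
        rate = rejections / n_sim
        band = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < band + 0.005

    def test_conditioning_absorbs_covariate(self):
        rng = np.random.default_rng(11)
        Z = frame(rng.standard_normal((100, 1)), prefix="z")
        X = frame(rng.standard_normal((100, 1)))
        y = 2.0 * Z["z0"].to_numpy() + rng.standard_normal(100)
        _, p = permutation_test(y, X, Z=Z, n_perm=199, seed=1)
        assert p > 0.05

    def test_zero_perm_errors(self):
        with pytest.raises(VarPartError):
            permutation_test(np.zeros(10), frame(np.ones((10, 1))), n_perm=0)


class TestForwardSelect:
    def test_strong_predictor_first_and_noise_never_enters(self):
        hits = 0
        n_rep = 50
        for s in range(n_rep):
            rng = np.random.default_rng(30_000 + s)
            X = frame(rng.standard_normal((200, 5)))
            X.columns = ["X1", "X2", "n1", "n2", "n3"]
            y = X["X1"].to_numpy() + 0.5 * X["X2"].to_numpy() + 0.7 * rng.standard_normal(200)
            sel = forward_select(y, X, n_perm=199, seed=s)
            ok = (
                len(sel.selected) >= 1
                and sel.selected[0] == "X1"
                and not any(c.startswith("n") for c in sel.selected)
            )
            hits += ok
            if sel.fit is not None:
                assert sel.fit.adj_r_squared <= sel.full_adj_r2 + 1e-12
        assert hits >= 0.9 * n_rep

    def test_pure_noise_selects_nothing(self):
        empties = 0
        n_rep = 50
        for s in range(n_rep):
            rng = np.random.default_rng(40_000 + s)
            X = frame(rng.standard_normal((100, 4)))
            y = rng.standard_normal(100)
            sel = forward_select(y, X, n_perm=99, seed=s)
            empties += len(sel.selected) == 0
        assert empties >= 0.9 * n_rep

    def test_single_strong_predictor_floors_p(self):
        rng = np.random.default_rng(12)
        X = frame(rng.standard_normal((100, 1)))
        y = 3.0 * X["x0"].to_numpy() + 0.1 * rng.standard_normal(100)
        sel = forward_select(y, X, n_perm=199, seed=0)
        assert sel.selected == ["x0"]
        assert sel.p_values[0] == pytest.approx(1.0 / 200.0)


class TestVariancePartition:
    def test_orthogonal_groups_recover_planted_fractions(self):
        rng = np.random.default_rng(13)
        n = 2000
        g1 = frame(rng.standard_normal((n, 1)), prefix="a")
        g2 = frame(rng.standard_normal((n, 1)), prefix="b")
        y = (
            np.sqrt(0.2) * g1["a0"].to_numpy()
            + np.sqrt(0.2) * g2["b0"].to_numpy()
            + np.sqrt(0.6) * rng.standard_normal(n)
        )
        vp = variance_partition(y, {"g1": g1, "g2": g2}, n_perm=99, seed=0)
        assert vp.unique["g1"] == pytest.approx(0.2, abs=0.05)
        assert vp.unique["g2"] == pytest.approx(0.2, abs=0.05)
        assert vp.shared == pytest.approx(0.0, abs=0.05)

    def test_duplicated_group_shifts_effect_to_shared(self):
        rng = np.random.default_rng(14)
        n = 500
        g1 = frame(rng.standard_normal((n, 1)), prefix="a")
        g2 = g1.copy()
        g2.columns = ["b0"]
        y = 0.7 * g1["a0"].to_numpy() + rng.standard_normal(n)
        vp = variance_partition(y, {"g1": g1, "g2": g2}, n_perm=49, seed=0)
        assert abs(vp.unique["g1"]) < 0.02
        assert abs(vp.unique["g2"]) < 0.02
        assert vp.shared == pytest.approx(vp.total, abs=0.02)

    def test_decomposition_identity_any_input(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            groups = {
                "a": frame(rng.standard_normal((120, 3)), prefix="a"),
                "b": frame(rng.standard_normal((120, 2)), prefix="b"),
                "c": frame(rng.standard_normal((120, 4)), prefix="c"),
            }
            y = rng.standard_normal(120)
            vp = variance_partition(y, groups, n_perm=9, seed=seed)
            assert sum(vp.unique.values()) + vp.shared == pytest.approx(
                vp.total, abs=1e-10
            )

    def test_empty_group_errors(self):
        with pytest.raises(VarPartError):
            variance_partition(
                np.zeros(10),
                {"a": frame(np.ones((10, 1))), "b": pd.DataFrame(index=range(10))},
            )


class TestPreparePredictors:
    def test_standardization_and_dummies(self):
        df = pd.DataFrame(
            {
                "ph": [4.0, 5.0, 6.0, 7.0],
                "land": ["crop", "forest", "crop", "grass"],
            }
        )
        X, dummies = prepare_predictors(df, ["ph"], ["land"])
        assert X["ph"].mean() == pytest.approx(0.0, abs=1e-12)
        assert X["ph"].std(ddof=1) == pytest.approx(1.0)
        assert set(dummies) == {"land_forest", "land_grass"}
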