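"""Tests of screening, stepwise selection, LMG, VIF, bootstrap, partial
correlation and Moran's I."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import vscpipe as v
from vscpipe.drivers import _R2Cache
from vscpipe.registry import ALL_VARS, DEFAULT_SCREENED_VARS

from conftest import gaussian_env_table


class TestScreening:
    def test_exact_po2_pco2_collinearity_drops_pco2(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 13)), columns=list(ALL_VARS))
        df["PCO2"] = 2.0 * df["PO2"]
        rep = v.screen_variables(df)
        assert "PCO2" in rep.dropped
        assert "PO2" in rep.kept

    def test_orthogonal_predictors_nothing_dropped(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(3000, 13)), columns=list(ALL_VARS))
        rep = v.screen_variables(df)
        assert rep.dropped == {}
        assert rep.kept == list(ALL_VARS)

    def test_reported_correlation_structure_keeps_nine(self):
        df = gaussian_env_table(n=4000, seed=5)
        rep = v.screen_variables(df)
        assert rep.kept == list(DEFAULT_SCREENED_VARS)
        assert set(rep.dropped) == {"PCO2", "MAP", "T_coldest", "T_annual"}

    def test_constant_column_errors(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 13)), columns=list(ALL_VARS))
        df["Wind"] = 3.0
        with pytest.raises(ValueError, match="Wind"):
            v.screen_variables(df)


class TestStepwise:
    def test_pure_noise_rarely_keeps_predictors(self):
        """AIC-based selection on pure noise keeps few spurious predictors.

        Per predictor, AIC retains it roughly when its chi-square exceeds 2
        (probability ~0.157), so the expected number of selected noise
        predictors out of 5 is ~0.8 and the intercept-only model appears in
        roughly 40% of replicates.
        """
        rng = np.random.default_rng(123)
        n_sel = []
        for _ in range(60):
            X = pd.DataFrame(
                rng.normal(size=(500, 5)), columns=list("abcde")
            )
            y = rng.normal(size=500)
            m = v.stepwise_select(y, X)
            n_sel.append(len(m.selected_vars))
        n_sel = np.array(n_sel)
        assert n_sel.mean() < 1.5
        assert (n_sel == 0).mean() > 0.25

    def test_strong_predictor_always_retained(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=300)
            X = pd.DataFrame(
                {"signal": x, **{f"n{i}": rng.normal(size=300) for i in range(4)}}
            )
            y = 1.5 * x + rng.normal(scale=math.sqrt(1.5), size=300)  # R2 ~ 0.6
            m = v.stepwise_select(y, X)
            assert "signal" in m.selected_vars

    def test_minimal_model_returned_unchanged(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        X = pd.DataFrame({"x": x})
        y = 2.0 * x + rng.normal(scale=0.3, size=200)
        m = v.stepwise_select(y, X)
        assert m.selected_vars == ["x"]
        assert m.coefficients["x"] == pytest.approx(2.0, abs=0.1)

    def test_rank_deficient_design_names_aliased_column(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=100)})
        with pytest.raises(ValueError, match="b"):
            v.stepwise_select(rng.normal(size=100), X)

    def test_removing_predictor_never_increases_r2(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(150, 4))
        y = X @ np.array([1.0, 0.5, 0.0, -0.3]) + rng.normal(size=150)
        cache = _R2Cache(X, y)
        full = frozenset(range(4))
        for j in range(4):
            assert cache.r2(full - {j}) <= cache.r2(full) + 1e-12


def brute_force_lmg(X: pd.DataFrame, y: np.ndarray) -> dict[str, float]:
    """Average sequential R2 over all orderings, via statsmodels OLS."""
    cols = list(X.columns)
    shares = {c: 0.0 for c in cols}
    perms = list(itertools.permutations(cols))
    for perm in perms:
        prev_r2 = 0.0
        for i, c in enumerate(perm):
            design = sm.add_constant(X[list(perm[: i + 1])].to_numpy())
            r2 = sm.OLS(y, design).fit().rsquared
            shares[c] += r2 - prev_r2
            prev_r2 = r2
    return {c: s / len(perms) for c, s in shares.items()}


class TestRelativeImportance:
    def test_orthogonal_predictors_get_marginal_r2(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(size=(400, 2))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = pd.DataFrame(Q, columns=["x1", "x2"])
        y = 3.0 * Q[:, 0] + 2.0 * Q[:, 1] + rng.normal(size=400)
        shares = v.relative_importance(X, y)
        # orthogonality: each share equals the marginal R2 exactly
        for c in ("x1", "x2"):
            design = sm.add_constant(X[[c]].to_numpy())
            marg = sm.OLS(y, design).fit().rsquared
            assert shares[c] == pytest.approx(marg, abs=1e-10)

    def test_duplicated_predictor_splits_evenly(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        X = pd.DataFrame({"x1": x, "x2": x})
        y = x + rng.normal(scale=0.5, size=300)
        shares = v.relative_importance(X, y)
        full_r2 = _R2Cache(X.to_numpy()[:, :1], y).r2((0,))
        assert shares["x1"] == pytest.approx(shares["x2"], abs=1e-10)
        assert shares["x1"] + shares["x2"] == pytest.approx(full_r2, abs=1e-9)

    def test_matches_explicit_ordering_enumeration(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(120, 3))
        # correlated design
        X = pd.DataFrame(
            {"a": z[:, 0], "b": 0.6 * z[:, 0] + 0.8 * z[:, 1],
             "c": 0.3 * z[:, 1] + z[:, 2]}
        )
        y = 1.0 * X["a"] - 0.7 * X["b"] + 0.4 * X["c"] + rng.normal(size=120)
        shares = v.relative_importance(X, y.to_numpy())
        oracle = brute_force_lmg(X, y.to_numpy())
        for c in X.columns:
            assert shares[c] == pytest.approx(oracle[c], abs=1e-9)

    def test_shares_sum_to_model_r2(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(200, 5)),
                         columns=[f"v{i}" for i in range(5)])
        y = X.to_numpy() @ rng.normal(size=5) + rng.normal(size=200)
        shares = v.relative_importance(X, y)
        design = sm.add_constant(X.to_numpy())
        r2 = sm.OLS(y, design).fit().rsquared
        assert sum(shares.values()) == pytest.approx(r2, abs=1e-9)
        assert all(s >= -1e-12 for s in shares.values())

    def test_predictor_limit_enforced(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(50, 13)),
                         columns=[f"v{i}" for i in range(13)])
        with pytest.raises(ValueError, match="sampling"):
            v.relative_importance(X, rng.normal(size=50))


class TestVIF:
    def test_orthogonal_pair_is_one(self):
        raw = np.random.default_rng(12).normal(size=(300, 2))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        out = v.vif(pd.DataFrame(Q, columns=["a", "b"]))
        assert out["a"] == pytest.approx(1.0, abs=1e-9)
        assert out["b"] == pytest.approx(1.0, abs=1e-9)

    def test_near_collinearity_inflates(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=200)
        X = pd.DataFrame({"x1": x, "x2": x + rng.normal(scale=0.01, size=200)})
        out = v.vif(X)
        assert out["x1"] > 10 and out["x2"] > 10

    def test_matches_statsmodels_auxiliary_regressions(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        rng = np.random.default_rng(14)
        z = rng.normal(size=(150, 3))
        X = pd.DataFrame(
            {"a": z[:, 0], "b": 0.5 * z[:, 0] + z[:, 1], "c": z[:, 2]}
        )
        out = v.vif(X)
        design = sm.add_constant(X.to_numpy())
        for j, c in enumerate(X.columns):
            assert out[c] == pytest.approx(
                variance_inflation_factor(design, j + 1), rel=1e-8
            )

    def test_single_predictor_undefined(self):
        out = v.vif(pd.DataFrame({"only": np.arange(10.0)}))
        assert math.isnan(out["only"])


class TestResourceSplit:
    def test_pure_resource_model(self):
        assert v.resource_split({"AI": 0.4}) == (100.0, 0.0)

    def test_pure_nonresource_model(self):
        res, nonres = v.resource_split({"Wind": 0.2, "T_diurnal": 0.1})
        assert (res, nonres) == (0.0, 100.0)

    def test_shares_sum_to_100(self):
        res, nonres = v.resource_split({"AI": 0.3, "Wind": 0.1, "MAT": 0.05})
        assert res + nonres == pytest.approx(100.0, abs=1e-9)

    def test_unregistered_variable_errors(self):
        with pytest.raises(KeyError):
            v.resource_split({"mystery": 0.5})


class TestBootstrapMatch:
    @pytest.fixture(scope="class")
    def driver_data(self, small_survey):
        _, _, vsc, env = small_survey
        screen = v.screen_variables(env)
        return vsc.merge(env[["plot_id", *screen.kept]], on="plot_id"), screen.kept

    def test_full_size_single_rep_reproduces_unresampled_split(self, driver_data):
        data, kept = driver_data
        forest = data[data["veg_type"] == "forest"]
        boot = v.bootstrap_match(
            forest, "height_max", kept, n_target=len(forest), n_reps=1, seed=0,
            exclude=(),
        )
        direct = v.stepwise_select(
            forest["height_max"], forest[kept], response="height_max"
        )
        assert boot["resource_share"].iloc[0] == pytest.approx(
            direct.resource_share, abs=1e-9
        )

    def test_fixed_seed_reproducible(self, driver_data):
        data, kept = driver_data
        a = v.bootstrap_match(data, "height_max", kept, n_target=40, n_reps=3,
                              seed=5, exclude=("shrubland",))
        b = v.bootstrap_match(data, "height_max", kept, n_target=40, n_reps=3,
                              seed=5, exclude=("shrubland",))
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_target_errors(self, driver_data):
        data, kept = driver_data
        with pytest.raises(ValueError, match="n_target"):
            v.bootstrap_match(data, "height_max", kept, n_target=10**6,
                              n_reps=1, seed=0)


class TestPartialCorrelation:
    def test_closed_form_on_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        z = np.array([0.5, 1.0, 2.5, 2.0, 4.0])
        r_xy, r_p = v.partial_correlation(x, y, z)
        c = np.corrcoef(np.vstack([x, y, z]))
        expected = (c[0, 1] - c[0, 2] * c[1, 2]) / math.sqrt(
            (1 - c[0, 2] ** 2) * (1 - c[1, 2] ** 2)
        )
        assert r_xy == pytest.approx(c[0, 1])
        assert r_p == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(15)
        x, z = rng.normal(size=50), rng.normal(size=50)
        y = 0.5 * x + 0.7 * z + rng.normal(size=50)
        _, r_p = v.partial_correlation(x, y, z)
        out = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert r_p == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)

    def test_independent_control_leaves_correlation(self):
        rng = np.random.default_rng(16)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        r_xy, r_p = v.partial_correlation(x, y, z)
        assert abs(r_p - r_xy) < 0.02

    def test_control_equal_to_y_undefined(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        _, r_p = v.partial_correlation(x, y, y)
        assert math.isnan(r_p)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            v.partial_correlation([1, 1, 1, 1], [1, 2, 3, 4], [0, 1, 0, 1])


class TestMoransI:
    def test_checkerboard_rook_weights(self):
        values = np.array([1.0, -1.0, -1.0, 1.0])  # 2x2 grid, row-major
        W = np.array(
            [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]],
            dtype=float,
        )
        assert v.morans_i(values, weights=W) == pytest.approx(-1.0)

    def test_null_expectation_under_permutation(self):
        rng = np.random.default_rng(18)
        n = 40
        coords = rng.uniform(0, 10, size=(n, 2))
        values = rng.normal(size=n)
        sims = np.array([
            v.morans_i(rng.permutation(values), coords, geographic=False)
            for _ in range(1000)
        ])
        expected = -1.0 / (n - 1)
        se = sims.std(ddof=1) / math.sqrt(len(sims))
        assert abs(sims.mean() - expected) < 3 * se

    def test_smooth_gradient_is_positive(self):
        xy = np.array([(i, j) for i in range(6) for j in range(6)], dtype=float)
        values = xy[:, 0] + xy[:, 1]
        # inverse-distance weights include long-range pairs, so the
        # statistic is moderate but clearly above the null of -1/35
        assert v.morans_i(values, xy, geographic=False) > 0.2

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            v.morans_i([1.0, 1.0, 1.0], np.eye(3)[:, :2])

    def test_coincident_points_warn(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
        with pytest.warns(UserWarning, match="coincident"):
            v.morans_i([1.0, 2.0, 3.0, 0.5], coords, geographic=False)


class TestRegimeContrast:
    def test_forest_resource_dominates_and_desert_reverses(self, small_survey):
        _, _, vsc, env = small_survey
        screen = v.screen_variables(env)
        data = vsc.merge(env[["plot_id", *screen.kept]], on="plot_id")
        shares = {}
        for vt in ("forest", "desert"):
            sub = data[data["veg_type"] == vt]
            m = v.stepwise_select(sub["height_max"], sub[screen.kept])
            shares[vt] = m
        assert shares["forest"].resource_share > shares["forest"].nonresource_share
        assert shares["desert"].nonresource_share > shares["desert"].resource_share

    def test_residual_moran_near_null_for_correct_model(self, small_survey):
        """Residuals of a correctly specified model carry no spatial signal."""
        _, _, vsc, env = small_survey
        screen = v.screen_variables(env)
        data = vsc.merge(env[["plot_id", *screen.kept]], on="plot_id")
        sub = data[data["veg_type"] == "meadow"].reset_index(drop=True)
        coords = sub[["lat", "lon"]].to_numpy()
        m = v.stepwise_select(sub["height_max"], sub[screen.kept], coords=coords)
        n = len(sub)
        rng = np.random.default_rng(0)
        resid = m.residuals
        perms = np.array([
            v.morans_i(rng.permutation(resid), coords) for _ in range(200)
        ])
        se = perms.std(ddof=1)
        assert abs(m.residual_moran_i - (-1.0 / (n - 1))) < 3 * se
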