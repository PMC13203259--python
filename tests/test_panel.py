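import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from wepa import (
    coefficient_difference_test,
    collinearity_diagnostics,
    fe_regression,
    lead_outcome,
    minutes_equivalent,
    prepare_variables,
    relative_week_trajectory,
    semi_elasticity,
    sparsity_subsets,
    standardize,
    winsorize,
)
from wepa.synthetic import make_numeric_panel


class TestWinsorize:
    def test_pct_zero_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(winsorize(x, 0), x)

    def test_constant_sequence_unchanged(self):
        x = np.full(20, 3.0)
        np.testing.assert_array_equal(winsorize(x, 1), x)

    def test_extremes_clamp_to_percentile_oracle(self):
        x = np.arange(1, 1001, dtype=float)
        lo, hi = np.percentile(x, [1, 99])
        w = winsorize(x, 1)
        assert w.min() == lo and w.max() == hi
        np.testing.assert_array_equal(w, np.clip(x, lo, hi))

    def test_order_preserved(self, rng):
        x = rng.normal(size=100)
        w = winsorize(x, 5)
        interior = (x > np.percentile(x, 5)) & (x < np.percentile(x, 95))
        np.testing.assert_array_equal(w[interior], x[interior])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            winsorize([], 1)


class TestPrepareVariables:
    def _raw(self):
        return pd.DataFrame(
            {
                "user_id": ["u1"] * 3,
                "week_index": [0, 1, 2],
                "ex_minutes": [0.0, 10.0, 20.0],
                "soc_engage_raw": [1.0, 0.0, 3.0],
                "soc_feedback_raw": [0.0, 5.0, 2.0],
            }
        )

    def test_log1p_applied(self):
        df = prepare_variables(self._raw())
        assert df.loc[0, "ex_dur"] == 0.0
        assert df.loc[1, "ex_dur"] == pytest.approx(np.log(11))
        assert df.loc[2, "soc_engage"] == pytest.approx(np.log(4))

    def test_dur_chg_hand_computed(self):
        df = prepare_variables(self._raw())
        assert np.isnan(df.loc[0, "dur_chg"])
        assert df.loc[1, "dur_chg"] == pytest.approx(np.log(11))
        assert df.loc[2, "dur_chg"] == pytest.approx(np.log(21) - np.log(11))

    def test_dur_chg_undefined_across_week_gap(self):
        raw = self._raw()
        raw["week_index"] = [0, 2, 3]  # gap between weeks 0 and 2
        df = prepare_variables(raw)
        assert np.isnan(df.loc[1, "dur_chg"])
        assert np.isfinite(df.loc[2, "dur_chg"])

    def test_negative_counts_rejected(self):
        raw = self._raw()
        raw.loc[0, "ex_minutes"] = -1
        with pytest.raises(ValueError, match="ex_minutes"):
            prepare_variables(raw)


class TestStandardize:
    def test_mean_zero_sd_one(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 5, size=200)})
        out = standardize(df, ["a"], winsor_pct=1)
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-10)
        assert out["a"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(pd.DataFrame({"a": [1.0, 1.0]}), ["a"], 0)


class TestLeadOutcome:
    def _panel(self, weeks, uid="u1"):
        return pd.DataFrame(
            {
                "user_id": [uid] * len(weeks),
                "week_index": weeks,
                "ex_dur": np.arange(len(weeks), dtype=float),
            }
        )

    def test_consecutive_weeks_yield_rows(self):
        rows = lead_outcome(self._panel([1, 2, 3]))
        assert len(rows) == 2
        assert rows["ex_dur_lead"].tolist() == [1.0, 2.0]

    def test_gap_yields_no_row(self):
        assert len(lead_outcome(self._panel([1, 3]))) == 0

    def test_mixed_panel_matches_hand_enumeration(self):
        panel = pd.concat(
            [
                self._panel([0, 1, 2], "a"),   # 2 rows
                self._panel([0, 2, 3], "b"),   # 1 row (2->3)
                self._panel([5], "c"),         # 0 rows
            ]
        )
        assert len(lead_outcome(panel)) == 3


class TestFeRegression:
    def _sim(self, n_users=10, t=6, beta=0.7, seed=3):
        return make_numeric_panel(n_users, t, beta, seed=seed)

    def test_matches_dummy_variable_least_squares(self):
        """Within estimates equal LSDV (statsmodels OLS with user dummies)
        to 1e-8 on a small instance."""
        rows = self._sim(n_users=10)
        rows["w"] = np.random.default_rng(5).normal(size=len(rows))
        fit = fe_regression(rows, "y_lead", ["x", "w"])
        lsdv = smf.ols("y_lead ~ x + w + C(user_id)", data=rows).fit()
        assert fit.params["x"] == pytest.approx(lsdv.params["x"], abs=1e-8)
        assert fit.params["w"] == pytest.approx(lsdv.params["w"], abs=1e-8)

    def test_recovers_known_coefficient(self):
        rows = self._sim(n_users=300, t=8, beta=0.5, seed=11)
        fit = fe_regression(rows, "y_lead", ["x"])
        assert abs(fit.params["x"] - 0.5) < 3 * fit.clustered_se["x"]

    def test_user_constant_regressor_rejected_by_name(self):
        rows = self._sim()
        offsets = {u: 1e9 + i for i, u in enumerate(rows["user_id"].unique())}
        rows["const_within"] = rows["user_id"].map(offsets)
        with pytest.raises(ValueError, match="const_within"):
            fe_regression(rows, "y_lead", ["x", "const_within"])

    def test_fixed_effect_absorption(self):
        """Adding a user-level constant to a regressor leaves the within
        estimate unchanged."""
        rows = self._sim()
        fit1 = fe_regression(rows, "y_lead", ["x"])
        shifted = rows.copy()
        offsets = {u: i * 2.5 for i, u in enumerate(shifted["user_id"].unique())}
        shifted["x"] = shifted["x"] + shifted["user_id"].map(offsets)
        fit2 = fe_regression(shifted, "y_lead", ["x"])
        assert fit1.params["x"] == pytest.approx(fit2.params["x"], abs=1e-10)

    def test_within_r2_in_unit_interval(self):
        fit = fe_regression(self._sim(), "y_lead", ["x"])
        assert 0 <= fit.within_r2 <= 1

    def test_result_counts(self):
        rows = self._sim(n_users=10, t=6)
        fit = fe_regression(rows, "y_lead", ["x"])
        assert fit.n_users == 10
        assert fit.n_obs == 60


class TestEffectConversions:
    @pytest.mark.parametrize(
        "beta, expected",
        [(0.069, 7.1), (0.0, 0.0), (-0.231, -20.6), (0.019, 1.9), (-0.053, -5.2)],
    )
    def test_semi_elasticity(self, beta, expected):
        assert semi_elasticity(beta) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "beta, ref, expected",
        [(0.069, 15.61, 1.12), (0.0, 99.0, 0.0), (-0.231, 15.61, -3.22)],
    )
    def test_minutes_equivalent(self, beta, ref, expected):
        assert minutes_equivalent(beta, ref) == pytest.approx(expected, abs=0.005)

    def test_conversion_identity(self, rng):
        for beta in rng.normal(0, 0.3, size=5):
            m = rng.uniform(1, 100)
            assert minutes_equivalent(beta, m) == pytest.approx(
                m * semi_elasticity(beta) / 100, abs=1e-12
            )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            minutes_equivalent(0.1, 0)


class TestCollinearity:
    def test_orthonormal_standardized_columns(self):
        raw = np.random.default_rng(0).normal(size=(100, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered, orthonormal
        diag = collinearity_diagnostics(pd.DataFrame(q, columns=list("abcd")))
        np.testing.assert_allclose(diag["vif"], 1.0, atol=1e-8)
        assert diag["condition_indices"].max() == pytest.approx(1.0, abs=1e-8)

    def test_duplicated_column_flags_infinite_vif(self):
        x = np.random.default_rng(1).normal(size=50)
        diag = collinearity_diagnostics(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(diag["vif"]["a"])

    def test_vif_matches_auxiliary_regression_oracle(self, rng):
        n, k = 120, 5
        base = rng.normal(size=(n, k))
        base[:, 1] += 0.8 * base[:, 0]  # induce collinearity
        df = pd.DataFrame(base, columns=[f"c{i}" for i in range(k)])
        diag = collinearity_diagnostics(df)
        for j, col in enumerate(df.columns):
            others = df.drop(columns=col)
            aux = smf.ols(
                f"{col} ~ " + " + ".join(others.columns),
                data=df,
            ).fit()
            assert diag["vif"][col] == pytest.approx(
                1 / (1 - aux.rsquared), abs=1e-8
            )


class TestCoefficientDifference:
    def test_equal_coefficients(self):
        z, p = coefficient_difference_test(0.5, 0.1, 0.5, 0.2)
        assert z == 0.0 and p == 1.0

    def test_large_gap(self):
        z, p = coefficient_difference_test(1.0, 0.1, 0.0, 0.1)
        assert z == pytest.approx(7.071, abs=0.001)
        assert p < 1e-10

    def test_swap_flips_sign_not_p(self):
        z1, p1 = coefficient_difference_test(0.4, 0.05, 0.1, 0.07)
        z2, p2 = coefficient_difference_test(0.1, 0.07, 0.4, 0.05)
        assert z1 == -z2 and p1 == p2

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            coefficient_difference_test(1, 0, 1, 0.1)


class TestTrajectory:
    def _scores(self, week_means):
        rows = []
        for w, m in enumerate(week_means):
            for u in range(4):
                rows.append(
                    {"user_id": f"u{u}", "week_index": w,
                     "wepa_score": m + (u - 1.5) * 0.01}
                )
        return pd.DataFrame(rows)

    def test_smoothed_middle_is_window_mean(self):
        traj = relative_week_trajectory(self._scores([0, 3, 6]), "c")
        raw = traj["mean_standardized_score"].to_numpy()
        assert traj["smoothed_score"].iloc[1] == pytest.approx(raw.mean())

    def test_single_week_smoothed_equals_raw(self):
        traj = relative_week_trajectory(self._scores([2.0]), "c")
        assert traj["smoothed_score"].iloc[0] == pytest.approx(
            traj["mean_standardized_score"].iloc[0]
        )

    def test_group_means_match_bruteforce(self, rng):
        df = pd.DataFrame(
            {
                "user_id": rng.choice(["a", "b", "c"], size=60),
                "week_index": rng.integers(0, 6, size=60),
                "wepa_score": rng.normal(size=60),
            }
        )
        traj = relative_week_trajectory(df, "c")
        z = (df["wepa_score"] - df["wepa_score"].mean()) / df["wepa_score"].std(
            ddof=0
        )
        for w in sorted(df["week_index"].unique()):
            expected = z[df["week_index"] == w].mean()
            got = traj.loc[
                traj["relative_week"] == w, "mean_standardized_score"
            ].iloc[0]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame(
            {"user_id": ["a", "b"], "week_index": [0, 1], "wepa_score": [1.0, 1.0]}
        )
        with pytest.raises(ValueError):
            relative_week_trajectory(df, "c")


class TestSparsitySubsets:
    def test_boundaries_and_hand_tally(self):
        panel = pd.DataFrame(
            {"valid_str_len": [0, 3, 4, 5, 10, 19, 20, 25]}
        )
        subs = sparsity_subsets(panel)
        assert len(subs["ge5"]) == 5          # 5, 10, 19, 20, 25
        assert len(subs["short_0_20"]) == 5   # 3, 4, 5, 10, 19
        assert len(subs["ge20"]) == 2         # 20, 25
        assert 20 in subs["ge20"]["valid_str_len"].values
        assert 20 not in subs["short_0_20"]["valid_str_len"].values
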