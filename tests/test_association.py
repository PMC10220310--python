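"""Unit tests for screening, standardized regression and HRQoL scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actikid.association import (
    AssociationError,
    CollinearityWarning,
    fit_multivariable,
    hrqol_model,
    parent_action_model,
    pedsql_total,
    spearman_screen,
    standardize,
)


class TestStandardize:
    def test_unit_variance(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = standardize(df, ["x"])
        assert out.x.var(ddof=1) == pytest.approx(1.0)
        assert out.x.mean() == pytest.approx(0.0)

    def test_binary_column_scaled_like_numeric(self):
        df = pd.DataFrame({"sex": [0, 0, 1, 1, 1, 0]})
        out = standardize(df, ["sex"])
        assert out.sex.var(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self):
        df = pd.DataFrame({"x": np.random.default_rng(0).normal(3, 7, 40)})
        once = standardize(df, ["x"])
        twice = standardize(once, ["x"])
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_variance_named_in_error(self):
        df = pd.DataFrame({"flat": [2.0, 2.0, 2.0]})
        with pytest.raises(AssociationError, match="flat"):
            standardize(df, ["flat"])


class TestSpearmanScreen:
    def test_perfect_monotone_selected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"y": np.exp(x), "x": x})
        res = spearman_screen(df, "y", candidates=["x"])
        assert res.loc["x", "rho"] == pytest.approx(1.0)
        assert res.loc["x", "selected"]

    def test_antitone_gives_minus_one(self):
        x = np.arange(30.0)
        df = pd.DataFrame({"y": -x, "x": x})
        res = spearman_screen(df, "y", candidates=["x"])
        assert res.loc["x", "rho"] == pytest.approx(-1.0)

    def test_constant_excluded_with_warning(self):
        df = pd.DataFrame({"y": np.arange(20.0), "c": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            res = spearman_screen(df, "y", candidates=["c"])
        assert len(res) == 0

    def test_small_sample_uses_permutation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.normal(0, 1, 12), "x": rng.normal(0, 1, 12)})
        a = spearman_screen(df, "y", candidates=["x"], seed=0)
        b = spearman_screen(df, "y", candidates=["x"], seed=0)
        assert a.loc["x", "p"] == b.loc["x", "p"]  # seeded permutation test
        assert 0 < a.loc["x", "p"] <= 1


class TestMultivariable:
    def test_perfect_single_predictor(self):
        x = np.random.default_rng(0).normal(0, 2, 30)
        df = pd.DataFrame({"y": x, "x": x})
        res = fit_multivariable(df, "y", ["x"])
        assert res.table.loc["x", "beta"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.table.loc["x", "rs2"] == pytest.approx(1.0)
        assert res.condition_number == pytest.approx(1.0)

    def test_orthogonal_design_closed_form(self):
        """On an orthogonal standardized design the condition number is ~1,
        sum of squared betas equals R^2, and each structural coefficient
        equals beta_j^2 / R^2."""
        rng = np.random.default_rng(2)
        n = 400
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # orthogonalize
        y = 0.5 * x1 - 0.3 * x2 + rng.normal(0, 0.7, n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        res = fit_multivariable(df, "y", ["x1", "x2"])
        b = res.table.beta.to_numpy()
        assert res.condition_number == pytest.approx(1.0, abs=0.02)
        assert (b**2).sum() == pytest.approx(res.r_squared, abs=1e-3)
        for j, term in enumerate(["x1", "x2"]):
            assert res.table.loc[term, "rs2"] == pytest.approx(
                b[j] ** 2 / res.r_squared, abs=2e-3
            )

    def test_listwise_deletion_count_exact(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "y": rng.normal(size=50),
                "a": rng.normal(size=50),
                "b": rng.normal(size=50),
            }
        )
        df.loc[::7, "a"] = np.nan
        df.loc[1::9, "b"] = np.nan
        res = fit_multivariable(df, "y", ["a", "b"])
        assert res.n_used == df[["y", "a", "b"]].dropna().shape[0]

    def test_rank_deficiency_names_aliased(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        df = pd.DataFrame({"y": rng.normal(size=30), "a": x, "a_copy": 2 * x + 1})
        with pytest.raises(AssociationError, match="a_copy"):
            fit_multivariable(df, "y", ["a", "a_copy"])

    def test_near_collinear_warns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        df = pd.DataFrame(
            {"y": rng.normal(size=200), "x": x, "mobility": x + rng.normal(0, 1e-4, 200)}
        )
        with pytest.warns(CollinearityWarning):
            parent_action_model(df.rename(columns={"x": "parent_action_1"}),
                                "y", "parent_action_1")

    def test_planted_effect_recovered_with_adjustment(self):
        """A parent-action effect planted alongside a correlated mobility
        effect is recovered by the two-predictor adjusted model."""
        rng = np.random.default_rng(6)
        n = 300
        mob = rng.normal(0, 1, n)
        action = 0.4 * mob + np.sqrt(1 - 0.16) * rng.normal(0, 1, n)
        y = 0.5 * mob + 0.15 * action + rng.normal(0, 0.8, n)
        df = pd.DataFrame({"y": y, "mobility": mob, "parent_action_2": action})
        res = parent_action_model(df, "y", "parent_action_2")
        lo, hi = res.table.loc["parent_action_2", ["ci_low", "ci_high"]]
        assert lo < 0.15 / y.std(ddof=0) * action.std(ddof=0) < hi


class TestPedsql:
    def test_all_top_scores(self):
        assert pedsql_total(np.full(23, 4.0)) == 4.0

    def test_mean_of_contributing_items(self):
        items = np.full(23, np.nan)
        items[:4] = [0, 0, 4, 4]
        assert pedsql_total(items, min_answered=0.1) == pytest.approx(2.0)

    def test_too_few_items_gives_missing(self):
        items = np.full(23, np.nan)
        items[0] = 3.0
        with pytest.warns(UserWarning, match="items answered"):
            assert np.isnan(pedsql_total(items))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_total_bounded_by_item_range(self, seed):
        rng = np.random.default_rng(seed)
        items = rng.integers(0, 5, 23).astype(float)
        total = pedsql_total(items)
        assert items.min() <= total <= items.max()


class TestHrqolModel:
    def _table(self, n, rng, activity_beta=0.0):
        mob = rng.normal(0, 1, n)
        act = 0.5 * mob + rng.normal(0, 0.8, n)
        return pd.DataFrame(
            {
                "age_months": rng.integers(12, 37, n),
                "imd_decile": rng.integers(1, 11, n),
                "mobility": mob,
                "social_cognitive": 0.8 * mob + 0.6 * rng.normal(0, 1, n),
                "pathway": rng.integers(0, 2, n),
                "prop_active": act,
                "pedsql_total": np.clip(
                    1.0 + activity_beta * act + rng.normal(0, 0.5, n), 0, 4
                ),
            }
        )

    def test_null_activity_effect_ci_covers_zero(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            res = hrqol_model(self._table(150, rng, activity_beta=0.0))
            lo, hi = res.table.loc["prop_active", ["ci_low", "ci_high"]]
            hits += lo <= 0 <= hi
        assert hits / n_rep >= 0.9

    def test_requires_enough_children(self):
        rng = np.random.default_rng(8)
        tab = self._table(150, rng)
        tab.loc[10:, "pedsql_total"] = np.nan
        with pytest.raises(AssociationError, match="at least"):
            hrqol_model(tab)

    def test_aliased_age_copies_rejected(self):
        rng = np.random.default_rng(9)
        tab = self._table(100, rng)
        tab["social_cognitive"] = tab["age_months"] * 2.0
        with pytest.raises(AssociationError, match="aliased"):
            hrqol_model(tab)
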