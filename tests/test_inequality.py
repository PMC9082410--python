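"""Fractional ranks, concentration index/curve, Wagstaff decomposition,
horizontal inequity and subgroup analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from healthineq import DataError
from healthineq.inequality import (bootstrap_inequality, concentration_curve,
                                   concentration_index, fractional_rank,
                                   horizontal_inequity, subgroup_inequality,
                                   wagstaff_decomposition)

finite_vals = st.lists(st.floats(-100, 100), min_size=2, max_size=30)
pos_weights = st.floats(0.1, 10)


class TestFractionalRank:
    def test_equal_weights_distinct_values(self):
        np.testing.assert_allclose(fractional_rank([10, 20, 30, 40]),
                                   [0.125, 0.375, 0.625, 0.875], atol=1e-15)

    def test_all_tied_midpoint(self):
        np.testing.assert_allclose(fractional_rank([7, 7, 7]), [0.5] * 3)

    def test_tied_block_midpoint(self):
        np.testing.assert_allclose(fractional_rank([1, 1, 2]),
                                   [1 / 3, 1 / 3, 5 / 6], atol=1e-15)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(DataError):
            fractional_rank([1, 2, 3], [1.0, 0.0, 1.0])

    @given(st.lists(st.tuples(st.floats(-50, 50), pos_weights),
                    min_size=2, max_size=40))
    def test_weighted_mean_is_half_and_monotone(self, rows):
        x = np.array([r[0] for r in rows])
        w = np.array([r[1] for r in rows])
        R = fractional_rank(x, w)
        assert np.all((R > 0) & (R < 1))
        assert np.sum(w * R) / np.sum(w) == pytest.approx(0.5, abs=1e-10)
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(R[order]) >= -1e-15)


class TestConcentrationIndex:
    def test_constant_outcome_zero(self):
        assert concentration_index([3, 3, 3, 3], [1, 2, 3, 4]).ci == pytest.approx(0.0)

    def test_self_ranked_1234(self):
        assert concentration_index([1, 2, 3, 4], [1, 2, 3, 4]).ci == \
            pytest.approx(0.25, abs=1e-14)

    def test_antisymmetry_in_ranking(self, rng):
        y = rng.uniform(1, 5, size=25)
        r = rng.normal(size=25)
        a = concentration_index(y, r).ci
        b = concentration_index(y, -r).ci
        assert a == pytest.approx(-b, abs=1e-12)

    def test_scale_invariance_and_translation_formula(self, rng):
        y = rng.uniform(1, 5, size=40)
        r = rng.normal(size=40)
        base = concentration_index(y, r).ci
        assert concentration_index(7.0 * y, r).ci == pytest.approx(base, abs=1e-12)
        c, mu = 3.0, y.mean()
        shifted = concentration_index(y + c, r).ci
        assert shifted == pytest.approx(base * mu / (mu + c), abs=1e-12)

    def test_integer_weights_equal_replication(self, rng):
        y = rng.uniform(1, 4, size=10)
        r = rng.normal(size=10)
        w = rng.integers(1, 4, size=10).astype(float)
        a = concentration_index(y, r, w).ci
        yr = np.repeat(y, w.astype(int))
        rr = np.repeat(r, w.astype(int))
        b = concentration_index(yr, rr).ci
        assert a == pytest.approx(b, abs=1e-12)

    def test_maximal_concentration_bound(self):
        # all outcome on the top-ranked unit: CI = 1 - 1/n
        res = concentration_index([0, 0, 0, 10], [1, 2, 3, 4])
        assert res.ci == pytest.approx(0.75, abs=1e-14)

    @given(st.lists(st.floats(0, 100), min_size=3, max_size=30))
    def test_bounded_for_nonnegative_outcomes(self, y):
        y = np.asarray(y)
        if y.sum() <= 0:
            return
        r = np.arange(len(y), dtype=float)
        assert abs(concentration_index(y, r).ci) <= 1 + 1e-12

    def test_convenient_regression_slope_equals_ci(self, rng):
        # independent WLS slope computed from 2x2 normal equations
        y = rng.uniform(0.5, 6, size=30)
        r = rng.normal(size=30)
        w = rng.uniform(0.5, 2, size=30)
        res = concentration_index(y, r, w)
        R = fractional_rank(r, w)
        W = w.sum()
        var_R = np.sum(w * R**2) / W - (np.sum(w * R) / W) ** 2
        lhs = 2 * var_R * y / (np.sum(w * y) / W)
        sw, swx = W, np.sum(w * R)
        swxx, swy, swxy = np.sum(w * R**2), np.sum(w * lhs), np.sum(w * R * lhs)
        slope = (sw * swxy - swx * swy) / (sw * swxx - swx**2)
        assert slope == pytest.approx(res.ci, abs=1e-10)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DataError):
            concentration_index([-1, -2, 3], [1, 2, 3])

    def test_bounded_outcome_corrections(self, rng):
        y = rng.integers(0, 33, size=50).astype(float)
        r = rng.normal(size=50)
        plain = concentration_index(y, r)
        err = concentration_index(y, r, correction="erreygers", bounds=(0, 32))
        wag = concentration_index(y, r, correction="wagstaff", bounds=(0, 32))
        mu = y.mean()
        assert err.ci == pytest.approx(plain.ci * 4 * mu / 32, abs=1e-12)
        assert wag.ci == pytest.approx(
            plain.ci * 32 * mu / ((32 - mu) * mu), abs=1e-12)


class TestConcentrationCurve:
    def test_equal_outcome_is_diagonal(self):
        curve = concentration_curve([2, 2, 2, 2], [4, 3, 2, 1])
        np.testing.assert_allclose(curve[:, 0], curve[:, 1], atol=1e-14)

    def test_extreme_concentration(self):
        curve = concentration_curve([0, 0, 0, 5], [1, 2, 3, 4])
        assert curve[3, 0] == pytest.approx(0.75)
        assert curve[3, 1] == pytest.approx(0.0)
        np.testing.assert_allclose(curve[-1], [1, 1])

    def test_endpoints_and_monotone(self, rng):
        y = rng.uniform(0, 5, size=20)
        r = rng.normal(size=20)
        curve = concentration_curve(y, r)
        np.testing.assert_allclose(curve[0], [0, 0])
        np.testing.assert_allclose(curve[-1], [1, 1])
        assert np.all(np.diff(curve[:, 1]) >= -1e-14)


class TestWagstaffDecomposition:
    def test_perfect_single_factor(self, rng):
        y = rng.uniform(1, 5, size=30)
        dec = wagstaff_decomposition(y, y, pd.DataFrame({"x": y}))
        row = dec.table.iloc[0]
        assert row["elasticity"] == pytest.approx(1.0, abs=1e-10)
        assert row["contribution"] == pytest.approx(dec.ci, abs=1e-12)
        assert dec.residual == pytest.approx(0.0, abs=1e-12)

    def test_zero_coefficient_factor_contributes_nothing(self, rng):
        x1 = rng.uniform(0, 3, size=40)
        noise_col = rng.normal(size=40)
        y = 1.0 + 2.0 * x1  # exact: fitted coefficient on noise_col is 0
        r = rng.normal(size=40)
        d1 = wagstaff_decomposition(y, r, pd.DataFrame({"x1": x1}))
        d2 = wagstaff_decomposition(y, r, pd.DataFrame({"x1": x1, "z": noise_col}))
        t2 = d2.table.set_index("factor")
        assert t2.loc["z", "contribution"] == pytest.approx(0.0, abs=1e-10)
        assert t2.loc["x1", "contribution"] == pytest.approx(
            d1.table.set_index("factor").loc["x1", "contribution"], abs=1e-10)

    def test_brute_force_oracle_n6(self, rng):
        # independent recomputation: lstsq OLS + per-factor covariance
        n = 6
        F = pd.DataFrame({"a": rng.normal(size=n), "b": rng.uniform(0, 2, n),
                          "c": rng.integers(0, 3, n).astype(float)})
        y = rng.uniform(1, 8, size=n)
        r = rng.normal(size=n)
        dec = wagstaff_decomposition(y, r, F)

        R = fractional_rank(r)
        X = np.column_stack([np.ones(n), F.to_numpy()])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        mu = y.mean()
        ci = 2 * np.cov(y, R, bias=True)[0, 1] / mu
        tab = dec.table.set_index("factor")
        total = 0.0
        for j, name in enumerate(F.columns):
            contrib = 2 * beta[j + 1] * np.cov(F[name], R, bias=True)[0, 1] / mu
            assert tab.loc[name, "contribution"] == pytest.approx(contrib, abs=1e-10)
            total += contrib
        assert dec.residual == pytest.approx(ci - total, abs=1e-10)

    def test_adding_up_property(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 60))
            F = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            y = rng.uniform(0.5, 9, size=n)
            w = rng.uniform(0.2, 3, size=n)
            dec = wagstaff_decomposition(y, rng.normal(size=n), F, w)
            assert dec.table["contribution"].sum() + dec.residual == \
                pytest.approx(dec.ci, abs=1e-10)

    def test_constant_factor_rejected(self, rng):
        with pytest.raises(DataError, match="constant"):
            wagstaff_decomposition([1, 2, 3, 4], [1, 2, 3, 4],
                                   pd.DataFrame({"x": [2, 2, 2, 2]}))


class TestHorizontalInequity:
    def test_empty_need_set_reduces_to_ci(self, rng):
        F = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        dec = wagstaff_decomposition(rng.uniform(1, 5, 30), rng.normal(size=30), F)
        assert horizontal_inequity(dec, ()).hi == dec.ci

    def test_rank_independent_need_leaves_ci(self):
        # need factor symmetric in rank: its covariance with R is zero
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r = np.array([1.0, 2.0, 3.0, 4.0])
        need = np.array([1.0, 0.0, 0.0, 1.0])
        other = np.array([0.1, 0.9, 0.4, 0.8])
        dec = wagstaff_decomposition(y, r, pd.DataFrame({"need": need,
                                                         "other": other}))
        hi = horizontal_inequity(dec, ("need",))
        assert hi.hi == pytest.approx(dec.ci, abs=1e-12)

    def test_unknown_need_factor_rejected(self, rng):
        F = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        dec = wagstaff_decomposition(rng.uniform(1, 5, 20), rng.normal(size=20), F)
        with pytest.raises(DataError, match="zzz"):
            horizontal_inequity(dec, ("zzz",))


class TestSubgroups:
    def _frame(self, rng, n, stratum):
        return pd.DataFrame({
            "y": rng.uniform(1, 5, size=n),
            "rank_var": rng.normal(size=n),
            "a": rng.normal(size=n),
            "s": stratum,
            "w": np.ones(n),
        })

    def test_identical_strata_identical_ci(self, rng):
        base = self._frame(rng, 60, 1)
        twin = base.assign(s=2)
        df = pd.concat([base, twin], ignore_index=True)
        res = subgroup_inequality(df, "s", "y", "rank_var", ["a"],
                                  need_factors=(), weight_col="w")
        assert len(res) == 2
        assert res[0].concentration.ci == pytest.approx(
            res[1].concentration.ci, abs=1e-12)

    def test_constant_stratifier_matches_pooled(self, rng):
        df = self._frame(rng, 80, 1)
        res = subgroup_inequality(df, "s", "y", "rank_var", ["a"],
                                  need_factors=(), weight_col="w")
        pooled = concentration_index(df["y"], df["rank_var"], df["w"].to_numpy())
        assert len(res) == 1
        assert res[0].concentration.ci == pytest.approx(pooled.ci, abs=1e-12)

    def test_small_stratum_skipped(self, rng):
        df = pd.concat([self._frame(rng, 50, 1), self._frame(rng, 10, 2)],
                       ignore_index=True)
        res = subgroup_inequality(df, "s", "y", "rank_var", ["a"],
                                  need_factors=(), weight_col="w", min_rows=30)
        assert [r.stratum for r in res] == [1]

    def test_all_strata_below_floor_raises(self, rng):
        df = self._frame(rng, 20, 1)
        with pytest.raises(DataError):
            subgroup_inequality(df, "s", "y", "rank_var", ["a"],
                                need_factors=(), min_rows=30)


class TestBootstrap:
    def test_seeded_bootstrap_reproducible(self, rng):
        df = pd.DataFrame({
            "y": rng.uniform(1, 5, 80), "r": rng.normal(size=80),
            "a": rng.normal(size=80), "b": rng.normal(size=80),
        })
        kw = dict(outcome="y", ranking="r", factors=["a", "b"],
                  need_factors=["a"], n_boot=50, seed=7)
        r1 = bootstrap_inequality(df, **kw)
        r2 = bootstrap_inequality(df, **kw)
        assert r1 == r2
        assert r1["ci"]["se"] > 0
        assert r1["ci"]["p2.5"] < r1["ci"]["p97.5"]
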