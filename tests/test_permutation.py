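"""Sequential-SS linear models, permutation p-values, ANCOVA parallelism."""
import itertools

import numpy as np
import pandas as pd
import pytest

from roostcount.exceptions import DesignError
from roostcount.permutation import (
    ModelSpec,
    ancova_with_parallelism,
    fit_linear_model,
    permutation_test,
)

GROUP_SPEC = ModelSpec.build("y", ["g"], kinds={"g": "factor"})


def two_group_frame():
    return pd.DataFrame({"g": list("aaabbb"), "y": [1.0, 2, 3, 4, 5, 6]})


class TestFitLinearModel:
    def test_two_group_f_statistic_by_hand(self):
        # SSB = 13.5, SSW = 4 -> F = (13.5/1)/(4/4) = 13.5 on (1, 4) df
        fit = fit_linear_model(GROUP_SPEC, two_group_frame())
        term = fit.term("g")
        assert term.F == pytest.approx(13.5, abs=1e-10)
        assert term.df == (1, 4)

    def test_constant_response_gives_zero_f_and_r2(self):
        df = two_group_frame().assign(y=5.0)
        fit = fit_linear_model(GROUP_SPEC, df)
        assert fit.term("g").F == 0.0
        assert fit.r2 == 0.0

    def test_covariate_equal_to_response_gives_r2_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4]})
        spec = ModelSpec.build("y", ["x"], kinds={"x": "covariate"})
        assert fit_linear_model(spec, df).r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_projection_matrix_oracle_on_small_designs(self, seed):
        """Sequential SS agree with explicit hat-matrix projections (n <= 8)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 9)
        df = pd.DataFrame({
            "g": rng.choice(list("ab"), n),
            "x": rng.normal(size=n),
            "y": rng.normal(size=n),
        })
        if df["g"].nunique() < 2:
            df.loc[0, "g"] = "a"
            df.loc[1, "g"] = "b"
        spec = ModelSpec.build("y", ["g", "x"], kinds={"g": "factor", "x": "covariate"})
        fit = fit_linear_model(spec, df)

        # oracle: explicit projections via pseudo-inverse hat matrices
        y = df["y"].to_numpy()
        ones = np.ones((n, 1))
        Xg = np.column_stack([ones, (df["g"] == "b").to_numpy(float)])
        Xgx = np.column_stack([Xg, df["x"].to_numpy()])

        def rss(X):
            H = X @ np.linalg.pinv(X)
            r = y - H @ y
            return float(r @ r)

        rss0, rss1, rss2 = rss(ones), rss(Xg), rss(Xgx)
        df_resid = n - 3
        assert fit.term("g").F == pytest.approx((rss0 - rss1) / (rss2 / df_resid), rel=1e-9)
        assert fit.term("x").F == pytest.approx((rss1 - rss2) / (rss2 / df_resid), rel=1e-9)
        assert fit.r2 == pytest.approx(1 - rss2 / rss0, rel=1e-9)

    def test_matches_statsmodels_type_one_anova(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "g": list("abc") * 6,
            "x": rng.normal(size=18),
            "y": rng.normal(size=18),
        })
        df["y"] += df["g"].map({"a": 0, "b": 1, "c": 2}) + 0.5 * df["x"]
        spec = ModelSpec.build("y", ["g", "x"], kinds={"g": "factor", "x": "covariate"})
        fit = fit_linear_model(spec, df)
        table = anova_lm(smf.ols("y ~ C(g) + x", df).fit(), typ=1)
        assert fit.term("g").F == pytest.approx(table.loc["C(g)", "F"], rel=1e-9)
        assert fit.term("x").F == pytest.approx(table.loc["x", "F"], rel=1e-9)

    def test_aliased_term_raises_design_error(self):
        df = two_group_frame().assign(h=lambda d: d["g"])
        spec = ModelSpec.build("y", ["g", "h"], kinds={"g": "factor", "h": "factor"})
        with pytest.raises(DesignError, match="h"):
            fit_linear_model(spec, df)

    def test_single_level_factor_raises(self):
        df = pd.DataFrame({"g": ["a"] * 4, "y": [1.0, 2, 3, 4]})
        with pytest.raises(DesignError):
            fit_linear_model(GROUP_SPEC, df)


def _one_way_F(y, groups):
    """Independent one-way ANOVA F for the enumeration oracle."""
    y = np.asarray(y, float)
    gs = [y[groups == g] for g in np.unique(groups)]
    grand = y.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    k, n = len(gs), len(y)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"g": list("aaabbb"), "y": [2.0, 2, 2, 2, 2, 2]})
        res = permutation_test(GROUP_SPEC, df, n_perm=99, seed=0)
        assert res.term("g").p_perm == 1.0

    def test_monte_carlo_agrees_with_exhaustive_enumeration(self):
        """Six observations: all 720 relabellings versus seeded Monte Carlo."""
        y = np.array([0.8, 1.9, 3.1, 3.9, 5.2, 6.1])
        groups = np.array(list("aaabbb"))
        f_obs = _one_way_F(y, groups)
        exceed = sum(
            _one_way_F(np.array(p), groups) >= f_obs - 1e-12
            for p in itertools.permutations(y)
        )
        p_exact = exceed / 720.0
        df = pd.DataFrame({"g": groups, "y": y})
        res = permutation_test(GROUP_SPEC, df, n_perm=9999, seed=4)
        assert res.term("g").p_perm == pytest.approx(p_exact, abs=0.02)

    def test_p_floor_and_argument_validation(self):
        df = two_group_frame()
        with pytest.raises(ValueError, match="99"):
            permutation_test(GROUP_SPEC, df, n_perm=50, seed=0)
        res = permutation_test(GROUP_SPEC, df, n_perm=99, seed=0)
        assert res.term("g").p_perm >= 1.0 / 100.0

    def test_invariance_to_relabelling_and_shift(self):
        df = pd.DataFrame({"g": list("aabbcc"), "y": [1.0, 2, 5, 6, 9, 10]})
        res = permutation_test(GROUP_SPEC, df, n_perm=299, seed=7)
        relabelled = df.assign(g=df["g"].map({"a": "z", "b": "m", "c": "k"}))
        res2 = permutation_test(GROUP_SPEC, relabelled, n_perm=299, seed=7)
        res3 = permutation_test(GROUP_SPEC, df.assign(y=df["y"] + 40), n_perm=299, seed=7)
        assert res.term("g").p_perm == res2.term("g").p_perm == res3.term("g").p_perm

    def test_bit_reproducible_under_fixed_seed(self):
        df = two_group_frame()
        a = permutation_test(GROUP_SPEC, df, n_perm=199, seed=11)
        b = permutation_test(GROUP_SPEC, df, n_perm=199, seed=11)
        assert a == b

    def test_p_never_increases_with_effect_size(self):
        rng = np.random.default_rng(13)
        noise = rng.normal(0, 1, 12)
        ps = []
        for delta in (0.0, 1.0, 2.0, 4.0):
            y = noise + np.repeat([0.0, delta], 6)
            df = pd.DataFrame({"g": list("aaaaaabbbbbb"), "y": y})
            ps.append(permutation_test(GROUP_SPEC, df, n_perm=999, seed=3).term("g").p_perm)
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_main_effect_detected_despite_its_interaction_in_model(self):
        """The nuisance space for a main effect must not include interactions
        containing it, or the tested effect would be absorbed."""
        rng = np.random.default_rng(19)
        df = pd.DataFrame({
            "g": np.repeat(list("ab"), 24),
            "m": list("wxyz") * 12,
        })
        df["y"] = df["g"].map({"a": 0.0, "b": 5.0}) + rng.normal(0, 1, 48)
        spec = ModelSpec.build("y", ["g", "m", "g:m"],
                               kinds={"g": "factor", "m": "factor"})
        res = permutation_test(spec, df, n_perm=199, seed=0)
        assert res.term("g").p_perm <= 0.01

    def test_freedman_lane_nulls_are_calibrated(self):
        """Covariate term p-value is ~uniform under its null with a nuisance factor."""
        rng = np.random.default_rng(17)
        spec = ModelSpec.build("y", ["g", "x"], kinds={"g": "factor", "x": "covariate"})
        rejections = 0
        reps = 100
        for _ in range(reps):
            df = pd.DataFrame({
                "g": list("ab") * 10,
                "x": rng.normal(size=20),
                "y": rng.normal(size=20),
            })
            df["y"] += df["g"].map({"a": 0.0, "b": 2.0})  # nuisance effect only
            res = permutation_test(spec, df, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.term("x").p_perm < 0.05
        assert 0.0 <= rejections / reps <= 0.10


class TestAncova:
    @staticmethod
    def _frame(rng, slopes):
        rows = []
        for gi, (g, b) in enumerate(slopes.items()):
            x = np.arange(12, dtype=float)
            y = gi * 3.0 + b * x + rng.normal(0, 1.0, 12)
            rows.append(pd.DataFrame({"g": g, "x": x, "y": y}))
        return pd.concat(rows, ignore_index=True)

    def test_common_slope_usually_flagged_parallel(self):
        rng = np.random.default_rng(23)
        spec = ModelSpec.build("y", ["g", "x", "g:x"],
                               kinds={"g": "factor", "x": "covariate"})
        flags = []
        for _ in range(50):
            df = self._frame(rng, {"a": 1.0, "b": 1.0, "c": 1.0})
            res = ancova_with_parallelism(spec, df, alpha=0.05, n_perm=199,
                                          seed=int(rng.integers(2**31)))
            flags.append(res.parallel)
        assert np.mean(flags) >= 0.9

    def test_strong_interaction_flagged_non_parallel(self):
        rng = np.random.default_rng(29)
        spec = ModelSpec.build("y", ["g", "x", "g:x"],
                               kinds={"g": "factor", "x": "covariate"})
        df = self._frame(rng, {"a": 1.0, "b": -1.0})
        res = ancova_with_parallelism(spec, df, alpha=0.05, n_perm=499, seed=1)
        assert not res.parallel
        assert res.flag == "non-parallel"

    def test_single_group_is_a_design_error(self):
        rng = np.random.default_rng(31)
        spec = ModelSpec.build("y", ["g", "x", "g:x"],
                               kinds={"g": "factor", "x": "covariate"})
        df = self._frame(rng, {"a": 1.0})
        with pytest.raises(DesignError):
            ancova_with_parallelism(spec, df, n_perm=199, seed=0)

    def test_parallel_fit_drops_interaction_term(self):
        rng = np.random.default_rng(37)
        spec = ModelSpec.build("y", ["g", "x", "g:x"],
                               kinds={"g": "factor", "x": "covariate"})
        df = self._frame(rng, {"a": 1.0, "b": 1.0})
        res = ancova_with_parallelism(spec, df, alpha=1e-6, n_perm=199, seed=2)
        names = [t.name for t in res.final.terms]
        assert res.parallel and "g:x" not in names


def test_model_spec_formula_parsing():
    spec = ModelSpec.from_formula("all_parrots ~ roost * month")
    assert [t.name for t in spec.terms] == ["roost", "month", "roost:month"]
    with pytest.raises(ValueError, match="undeclared"):
        ModelSpec.build("y", ["a:b"])
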