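import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from spatstar.descriptives import (
    DesignError,
    design_chisq,
    fit_logistic_ml,
    screen_covariates,
    weighted_prevalence,
)


def make_df(y, w=None, stratum=None, psu=None, **cols):
    n = len(y)
    return pd.DataFrame({
        "outcome": y,
        "weight": w if w is not None else np.ones(n),
        "stratum": stratum if stratum is not None else ["s0"] * n,
        "psu": psu if psu is not None else [f"p{i}" for i in range(n)],
        **cols,
    })


class TestWeightedPrevalence:
    def test_equal_weights_single_stratum(self):
        df = make_df([1, 1, 0, 0], psu=["p0", "p0", "p1", "p1"])
        est = weighted_prevalence(df)
        assert est.proportion == pytest.approx(0.5)

    def test_weighted_point_estimate(self):
        df = make_df([1, 0, 0, 0], w=[3, 1, 1, 1], psu=["p0", "p0", "p1", "p1"])
        assert weighted_prevalence(df).proportion == pytest.approx(0.5)

    def test_equal_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40)
        df = make_df(y, psu=[f"p{i % 8}" for i in range(40)])
        assert weighted_prevalence(df).proportion == pytest.approx(y.mean(), abs=1e-15)

    def test_matches_independent_linearization_oracle(self):
        """Two-stratum toy design checked against a from-scratch coding of
        the standard Taylor linearisation + logit-Wald interval."""
        df = make_df(
            y=[1, 0, 1, 1, 0, 0, 1, 0, 1, 1],
            w=[2, 1, 1, 3, 1, 2, 1, 1, 2, 1],
            stratum=["a"] * 6 + ["b"] * 4,
            psu=["a1", "a1", "a2", "a2", "a3", "a3", "b1", "b1", "b2", "b2"],
        )
        y, w = df["outcome"].to_numpy(float), df["weight"].to_numpy(float)
        p = (w * y).sum() / w.sum()
        u = w * (y - p) / w.sum()
        var = 0.0
        for s in ("a", "b"):
            tot = np.array([u[(df.stratum == s) & (df.psu == c)].sum()
                            for c in sorted(df.loc[df.stratum == s, "psu"].unique())])
            var += len(tot) / (len(tot) - 1) * ((tot - tot.mean()) ** 2).sum()
        se = np.sqrt(var)
        z = norm.ppf(0.975)
        logit = np.log(p / (1 - p))
        half = z * se / (p * (1 - p))
        lo, hi = 1 / (1 + np.exp(-(logit - half))), 1 / (1 + np.exp(-(logit + half)))
        est = weighted_prevalence(df)
        assert est.proportion == pytest.approx(p, abs=1e-10)
        assert est.ci_low == pytest.approx(lo, abs=1e-10)
        assert est.ci_high == pytest.approx(hi, abs=1e-10)

    def test_ci_respects_unit_interval_near_boundary(self):
        n = 50
        y = np.zeros(n)
        y[0] = 1  # p-hat = 1/n
        df = make_df(y, psu=[f"p{i % 10}" for i in range(n)])
        est = weighted_prevalence(df)
        assert 0.0 < est.ci_low <= est.proportion <= est.ci_high < 1.0

    def test_single_psu_stratum_errors_with_name(self):
        df = make_df([1, 0, 1, 0], stratum=["a", "a", "b", "b"],
                     psu=["a1", "a2", "b1", "b1"])
        with pytest.raises(DesignError, match="'b'"):
            weighted_prevalence(df)
        est = weighted_prevalence(df, single_psu="certainty")
        assert est.proportion == pytest.approx(0.5)


class TestDesignChisq:
    @staticmethod
    def toy_table_df():
        # 2x2 cell counts [[10, 20], [5, 40]] (outcome x factor)
        rows = ([(1, "f0")] * 10 + [(1, "f1")] * 20 + [(0, "f0")] * 5 + [(0, "f1")] * 40)
        y, f = zip(*rows)
        return make_df(list(y), f=list(f))

    def test_classical_pearson_on_toy_table(self):
        r = design_chisq(self.toy_table_df(), "outcome", "f")
        # closed form n(ad-bc)^2 / (r1 r2 c1 c2) on the 2x2 table
        expected = 75 * (10 * 40 - 20 * 5) ** 2 / (30 * 45 * 15 * 60)
        assert expected == pytest.approx(50 / 9)
        assert r.pearson == pytest.approx(expected, abs=1e-10)
        assert r.statistic == pytest.approx(expected, abs=1e-10)  # trivial design
        assert r.df == 1

    def test_reduces_to_pearson_under_trivial_design(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 300)
        f = rng.choice(list("abc"), 300)
        r = design_chisq(make_df(y, f=f), "outcome", "f")
        assert r.statistic == pytest.approx(r.pearson, abs=1e-10)
        assert r.design_correction == pytest.approx(1.0, abs=1e-10)

    def test_single_level_factor_degenerate(self):
        df = make_df([0, 1, 0, 1], f=["x"] * 4)
        with pytest.raises(DesignError, match="degenerate"):
            design_chisq(df, "outcome", "f")

    def test_type_one_error_rate(self):
        """Independent factor/outcome: rejection at alpha=0.05 stays nominal."""
        rng = np.random.default_rng(11)
        rejections = 0
        n, reps = 200, 1000
        for _ in range(reps):
            y = rng.integers(0, 2, n)
            f = rng.choice(["u", "v"], n)
            try:
                r = design_chisq(make_df(y, f=f), "outcome", "f")
            except DesignError:
                continue
            rejections += r.p_value <= 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestLogisticML:
    def test_saturated_two_by_two_or(self):
        rows = ([(1, "e1")] * 10 + [(1, "e0")] * 20 + [(0, "e1")] * 5 + [(0, "e0")] * 40)
        y, x = zip(*rows)
        out = fit_logistic_ml(make_df(list(y), x=list(x)), "outcome", ["x"])
        est = out.loc[out.term == "x", "odds_ratio"].iloc[0]
        assert est == pytest.approx(4.0, rel=1e-5)

    def test_null_covariate_rank_deficient(self):
        df = make_df([0, 1, 0, 1], x=["same"] * 4)
        with pytest.raises((DesignError, ValueError)):
            fit_logistic_ml(df, "outcome", ["x"])

    def test_collinear_columns_named(self):
        df = make_df([0, 1, 0, 1] * 10, x=["a", "b"] * 20, x2=["a", "b"] * 20)
        with pytest.raises(DesignError, match="collinear"):
            fit_logistic_ml(df, "outcome", ["x", "x2"])

    def test_separation_flagged(self):
        df = make_df([0] * 20 + [1] * 20, x=["a"] * 20 + ["b"] * 20)
        out = fit_logistic_ml(df, "outcome", ["x"])
        assert out.loc[out.term == "x", "separation_flag"].iloc[0]

    def test_consistency_at_moderate_n(self):
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.integers(0, 2, n)
        eta = -0.5 + np.log(3.0) * x
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        out = fit_logistic_ml(make_df(y.astype(int), x=np.where(x, "b", "a")),
                              "outcome", ["x"])
        assert out.loc[out.term == "x", "odds_ratio"].iloc[0] == pytest.approx(3.0, abs=0.3)


class TestScreening:
    @staticmethod
    def sim_df(seed=0, n=600):
        rng = np.random.default_rng(seed)
        strong = rng.integers(0, 2, n)
        noise = rng.choice(["a", "b"], n)
        eta = -0.2 + 1.0 * strong
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return make_df(y, strong=np.where(strong, "y", "n"), noise=noise)

    def test_threshold_rule_exact(self):
        """A term is kept iff its minimum Wald p is <= alpha."""
        df = self.sim_df(3)
        table = fit_logistic_ml(df, "outcome", ["strong", "noise"])
        p_noise = table.loc[table.term == "noise", "p_value"].min()
        just_above = min(p_noise * 1.01, 1.0)
        kept = screen_covariates(df, "outcome", ["strong", "noise"], alpha=just_above)
        assert "noise" in kept
        kept = screen_covariates(df, "outcome", ["strong", "noise"], alpha=p_noise * 0.99)
        assert "noise" not in kept and "strong" in kept

    def test_always_keep_bypasses_threshold(self):
        df = self.sim_df(4)
        kept = screen_covariates(df, "outcome", ["strong", "noise"], alpha=1e-12,
                                 always_keep=["noise"])
        assert "noise" in kept

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            screen_covariates(self.sim_df(), "outcome", [])
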