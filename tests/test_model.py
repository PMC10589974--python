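import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from spatstar.graph import make_lattice
from spatstar.model import (
    FitResult,
    McmcConfig,
    ModelSpec,
    StructuredAdditiveLogit,
    compute_dic,
    fit_star,
    posterior_odds_table,
    predicted_district_prevalence,
    variance_decomposition,
)
from spatstar.pg import pg_draw, pg_mean, seed_pg
from spatstar.simulate import CovariateSpec, SimulationConfig, simulate_survey

from conftest import FIXED_TERMS, true_coefs


class TestPolyaGamma:
    @pytest.mark.parametrize("z", [0.0, 0.5, 2.0, 6.0, -3.0])
    def test_mean_matches_closed_form(self, z):
        seed_pg(123)
        draws = pg_draw(np.full(60000, z))
        m = pg_mean(1.0, np.array([z]))[0]
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - m) < 4 * se

    def test_variance_at_zero(self):
        # Var PG(1, 0) = 1/24
        seed_pg(5)
        draws = pg_draw(np.zeros(60000))
        assert draws.var() == pytest.approx(1 / 24, rel=0.03)


class TestVarianceDecomposition:
    def test_worked_structured_share(self):
        assert variance_decomposition(0.132, 0.074).structured_pct == 64.1

    def test_worked_unstructured_share(self):
        assert variance_decomposition(0.130, 0.211).unstructured_pct == 61.9

    def test_symmetry(self):
        d = variance_decomposition(0.2, 0.2)
        assert d.structured_pct == 50.0 and d.unstructured_pct == 50.0

    def test_both_zero_flagged(self):
        assert variance_decomposition(0.0, 0.0).undefined


def degenerate_fit(eta_value=0.3, n=10, n_draws=20):
    """A FitResult whose draws are all identical (no posterior uncertainty)."""
    y = np.array([1, 0] * (n // 2), dtype=float)
    d = np.ones((n, 1))
    beta = np.full((n_draws, 1), eta_value)
    return FitResult(
        coef_names=[("intercept", "")], beta=beta, f_str=None, f_unstr=None,
        tau2={}, chain=np.zeros(n_draws), district_labels=(), dist_idx=None,
        design=d, y=y, smooths={}, term_levels={},
    )


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self):
        r = compute_dic(degenerate_fit())
        assert r.p_d == pytest.approx(0.0, abs=1e-10)
        assert r.dic == pytest.approx(r.mean_deviance, abs=1e-10)

    def test_pd_positive_on_genuine_posterior(self, women_fit):
        assert women_fit.dic_.p_d > 0


class TestOddsTable:
    def test_constant_draws_give_exact_interval(self):
        fit = degenerate_fit()
        fit.coef_names = [("intercept", ""), ("x", "b")]
        fit.term_levels = {"x": ["a", "b"]}
        fit.beta = np.column_stack([np.zeros(20), np.full(20, np.log(2.0))])
        t = posterior_odds_table(fit)
        row = t[(t.term == "x") & (t.level == "b")].iloc[0]
        assert (row.aOR, row.ci_low, row.ci_high) == (2.0, 2.0, 2.0)

    def test_reference_level_row(self, women_fit):
        t = posterior_odds_table(women_fit.result_)
        ref = t[t.reference]
        assert (ref.aOR == 1.0).all()
        assert ref.ci_low.isna().all()
        # first level of each term is the reference
        assert set(ref.level) == {"not_together", "poorest", "no"}

    def test_recovers_generating_aor(self, women_fit):
        """True controlling-behaviour odds ratio 5.80 at n~2000: the
        posterior aOR must land inside the replicate sampling band."""
        t = posterior_odds_table(women_fit.result_)
        aor = t[(t.term == "controlling") & (t.level == "yes")].aOR.iloc[0]
        assert 4.0 <= aor <= 8.4


class TestFittedModel:
    def test_fstr_sums_to_zero_every_draw(self, women_fit):
        s = women_fit.result_.f_str.sum(axis=1)
        assert np.abs(s).max() < 1e-8

    def test_credible_bounds_ordered(self, women_fit):
        s = women_fit.result_.summaries
        assert (s.q025 <= s.q975).all()

    def test_diagnostics_present(self, women_fit):
        d = women_fit.result_.diagnostics
        assert "rhat_intercept" in d and np.isfinite(d["rhat_intercept"])

    def test_smooth_curve_centered(self, women_fit):
        curve = women_fit.result_.smooth_curve("age")
        assert abs(curve["mean"].mean()) < 1e-8
        assert ((curve.q025 <= curve["mean"]) & (curve["mean"] <= curve.q975)).all()

    def test_predict_proba_shape_and_range(self, women_fit, women_data):
        ds, _ = women_data
        p = women_fit.predict_proba(ds.records.head(50))
        assert p.shape == (50, 2)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_non_binary_outcome_rejected(self, women_data):
        ds, cfg = women_data
        df = ds.records.copy()
        df.loc[df.index[0], "outcome"] = 2
        with pytest.raises(ValueError, match="binary"):
            StructuredAdditiveLogit(fixed=("controlling",), graph=cfg.graph,
                                    n_iter=20, burn_in=10).fit(df)

    def test_unmatched_district_listed(self, women_data):
        ds, cfg = women_data
        df = ds.records.copy()
        df["district"] = df["district"].astype(str)
        df.loc[df.index[0], "district"] = "atlantis"
        with pytest.raises(ValueError, match="atlantis"):
            StructuredAdditiveLogit(fixed=("controlling",), graph=cfg.graph,
                                    n_iter=20, burn_in=10).fit(df)


class TestDistrictPrevalence:
    def test_geometric_mean_one_and_monotone(self, women_fit):
        t = predicted_district_prevalence(women_fit.result_)
        assert np.exp(np.log(t.district_odds).mean()) == pytest.approx(1.0, abs=1e-8)
        order_odds = t.district_odds.rank()
        res = women_fit.result_
        total = res.f_str.mean(axis=0) + res.f_unstr.mean(axis=0)
        assert (order_odds.to_numpy() == pd.Series(total).rank().to_numpy()).all()

    def test_empty_district_flagged(self, women_data):
        ds, cfg = women_data
        df = ds.records[ds.records["district"].astype(str) != "r0c0"]
        est = StructuredAdditiveLogit(fixed=("controlling",), graph=cfg.graph,
                                      n_iter=400, burn_in=100, thin=1,
                                      n_chains=1, seed=2).fit(df)
        t = predicted_district_prevalence(est.result_)
        row = t[t.district == "r0c0"].iloc[0]
        assert row.no_individuals and np.isnan(row.predicted_prevalence)
        assert np.isfinite(row.district_odds)


def small_sim(n=400, seed=0, tau2_str=0.0, tau2_unstr=0.0, intercept=0.0):
    cfg = SimulationConfig(
        n_individuals=n, graph=make_lattice(5, 6),
        covariates=[CovariateSpec("x", ("a", "b"), (0.5, 0.5))],
        fixed_effects={"x": {"b": 0.7}}, intercept=intercept,
        tau2_str=tau2_str, tau2_unstr=tau2_unstr, seed=seed,
    )
    return simulate_survey(cfg)


def test_record_order_invariance():
    """Permuting the input rows leaves every posterior summary unchanged
    (inputs are canonically sorted before sampling)."""
    ds = small_sim(n=300, seed=8, tau2_unstr=0.2)
    kw = dict(fixed=("x",), graph=ds.graph, n_iter=300, burn_in=100, thin=1,
              n_chains=1, seed=4)
    a = StructuredAdditiveLogit(**kw).fit(ds.records).result_.summaries
    shuffled = ds.records.sample(frac=1.0, random_state=99).reset_index(drop=True)
    b = StructuredAdditiveLogit(**kw).fit(shuffled).result_.summaries
    pd.testing.assert_frame_equal(a, b)


def test_null_spatial_field_shrinks():
    """Data generated with no spatial effects: both spatial variance
    posteriors concentrate near zero at n=5000 over 30 districts."""
    ds = small_sim(n=5000, seed=12)
    est = StructuredAdditiveLogit(fixed=("x",), graph=ds.graph,
                                  n_iter=2000, burn_in=500, thin=2,
                                  n_chains=1, seed=3).fit(ds.records)
    assert np.median(est.result_.tau2["tau2_str"]) < 0.05
    assert np.median(est.result_.tau2["tau2_unstr"]) < 0.05


def test_null_spatial_district_odds_shrink_toward_one():
    """Under a null spatial field the posterior district effects are pulled
    hard toward zero: far narrower than the raw per-district deviations of
    the empirical log-odds, and close to one in absolute terms."""
    ds = small_sim(n=5000, seed=21)
    est = StructuredAdditiveLogit(fixed=("x",), graph=ds.graph,
                                  n_iter=1500, burn_in=500, thin=2,
                                  n_chains=1, seed=6).fit(ds.records)
    t = predicted_district_prevalence(est.result_)
    assert t.district_odds.between(0.75, 1.33).all()
    df = ds.records
    raw = df.groupby("district", observed=True)["outcome"].mean().clip(0.01, 0.99)
    raw_logit = np.log(raw / (1 - raw))
    raw_spread = raw_logit - raw_logit.mean()
    fitted_spread = t.set_index("district").spatial_effect
    assert fitted_spread.abs().max() < 0.5 * np.abs(raw_spread).max()


def test_fit_star_wrapper_matches_estimator(women_data):
    ds, cfg = women_data
    spec = ModelSpec(fixed_terms=["controlling"], graph=cfg.graph)
    res = fit_star(ds.records, spec, McmcConfig(n_iter=200, burn_in=50, thin=1,
                                                n_chains=1, seed=9))
    est = StructuredAdditiveLogit(fixed=("controlling",), graph=cfg.graph,
                                  n_iter=200, burn_in=50, thin=1,
                                  n_chains=1, seed=9).fit(ds.records)
    pd.testing.assert_frame_equal(res.summaries, est.result_.summaries)


def test_weighted_pseudo_likelihood_option():
    """The survey-weighted fit runs and recovers the effect direction."""
    ds = small_sim(n=800, seed=15)
    df = ds.records.copy()
    rng = np.random.default_rng(0)
    df["weight"] = rng.gamma(4.0, 0.25, len(df))
    est = StructuredAdditiveLogit(fixed=("x",), structured=False,
                                  unstructured=False, weighted=True,
                                  n_iter=600, burn_in=200, thin=1,
                                  n_chains=1, seed=5).fit(df)
    t = posterior_odds_table(est.result_)
    aor = t[(t.term == "x") & (t.level == "b")].aOR.iloc[0]
    assert 1.2 <= aor <= 3.5  # truth exp(0.7) ~ 2.01


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        McmcConfig(thin=0)
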