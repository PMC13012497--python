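"""Mixed-model engine: oracle agreement, Wald identities, channel-wise fits."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dreamdepth as dd
from dreamdepth.glme import BRAIN, ModelSpec, _Kernel, fit_lmm


def _toy_df(seed=0, n_sub=18, per=25, tau=0.6, sigma=0.8):
    rng = np.random.default_rng(seed)
    sub = np.repeat(np.arange(n_sub), per)
    n = len(sub)
    b = rng.normal(0, tau, n_sub)[sub]
    x = rng.normal(size=n)
    t = rng.uniform(-1, 7.5, n)
    y = 3 + 0.3 * x + 0.127 * t + b + rng.normal(0, sigma, n)
    return pd.DataFrame(
        {"participant_id": sub, "x": x, "time": t,
         "night": rng.integers(1, 5, n), "experiment": (sub % 2) + 1, "y": y}
    )


class TestAgainstStatsmodels:
    """Independent oracle: statsmodels MixedLM on identical designs."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reml_estimates_match(self, seed):
        from statsmodels.regression.mixed_linear_model import MixedLM

        df = _toy_df(seed)
        fit = fit_lmm(df, ModelSpec(outcome="y", predictors=("x",)))
        X = pd.DataFrame(
            {"const": 1.0, "x": df.x, "time": df.time,
             "e2": (df.experiment == 2).astype(float)}
        )
        for nt in (2, 3, 4):
            X[f"n{nt}"] = (df.night == nt).astype(float)
        sm_fit = MixedLM(df.y, X, groups=df.participant_id).fit(reml=True)
        assert fit.coef("x").estimate == pytest.approx(sm_fit.params["x"],
                                                       rel=1e-5)
        # statsmodels reports Hessian-based SEs that deviate ~0.2% from the
        # exact GLS covariance; agreement at that level is the oracle check
        assert fit.coef("x").se == pytest.approx(sm_fit.bse["x"], rel=5e-3)
        assert fit.tau2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]),
                                         rel=1e-3)
        sm_ml = MixedLM(df.y, X, groups=df.participant_id).fit(reml=False)
        assert fit.loglik_ml == pytest.approx(sm_ml.llf, abs=1e-4)

    def test_ols_limit_when_group_variance_zero(self):
        # iid data on a seed where the variance ratio hits the boundary:
        # the mixed fit must coincide with ordinary least squares
        df = _toy_df(3, tau=0.0)
        fit = fit_lmm(df, ModelSpec(outcome="y", predictors=("x",),
                                    nuisance=("time",)))
        X = np.column_stack([np.ones(len(df)), df.x, df.time])
        beta_ols = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)[0]
        assert fit.tau2 == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(
            fit.params["estimate"].to_numpy(), beta_ols, atol=1e-6
        )


class TestFitBasics:
    def test_noiseless_linear_time_effect_recovered_exactly(self, simple_records):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(
                simple_records,
                ModelSpec(outcome="sleep_depth", predictors=("time",),
                          nuisance=()),
            )
        assert fit.coef("time").estimate == pytest.approx(0.127, abs=1e-6)

    def test_constant_outcome_rejected(self, simple_records):
        df = simple_records.assign(sleep_depth=3.0)
        with pytest.raises(ValueError, match="constant"):
            fit_lmm(df, ModelSpec(outcome="sleep_depth", predictors=("time",),
                                  nuisance=()))

    def test_single_group_rejected(self, simple_records):
        df = simple_records[simple_records.participant_id == "P01"]
        with pytest.raises(ValueError, match="groups"):
            fit_lmm(df, ModelSpec(outcome="sleep_depth", predictors=("time",),
                                  nuisance=()))

    def test_intercept_shift_only_moves_intercept(self):
        df = _toy_df(4)
        spec = ModelSpec(outcome="y", predictors=("x",), nuisance=("time",))
        f1 = fit_lmm(df, spec)
        f2 = fit_lmm(df.assign(y=df.y + 10), spec)
        assert f2.coef("intercept").estimate == pytest.approx(
            f1.coef("intercept").estimate + 10, abs=1e-8
        )
        for name in ("x", "time"):
            assert f2.coef(name).estimate == pytest.approx(
                f1.coef(name).estimate, abs=1e-8
            )

    def test_ci_and_wald_identities(self):
        df = _toy_df(5)
        fit = fit_lmm(df, ModelSpec(outcome="y", predictors=("x",)))
        c = fit.params
        np.testing.assert_allclose(
            c["wald"], (c["estimate"] / c["se"]) ** 2, rtol=1e-9
        )
        np.testing.assert_allclose(
            c["ci_high"] - c["estimate"], 1.959964 * c["se"], rtol=1e-5
        )
        # AIC/BIC consistent with the ML log-likelihood and parameter count
        assert fit.aic == pytest.approx(-2 * fit.loglik_ml + 2 * fit.k)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik_ml + fit.k * np.log(fit.n)
        )


class TestWaldStatistic:
    @pytest.mark.parametrize(
        "beta, se, w, p",
        [
            (2.0, 1.0, 4.0, sps.chi2.sf(4.0, 1)),
            (0.0, 1.0, 0.0, 1.0),
            (1.96, 1.0, 1.96**2, 0.05),
        ],
    )
    def test_examples(self, beta, se, w, p):
        W, pv = dd.wald_statistic(beta, se)
        assert W == pytest.approx(w, abs=1e-12)
        assert pv == pytest.approx(p, abs=5e-4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            dd.wald_statistic(1.0, 0.0)


class TestChannelwise:
    def test_injected_electrodes_have_largest_wald(self):
        topo = np.zeros(16)
        topo[:6] = 2.0
        cfg = dd.SimConfig(
            n_participants=16, n_channels=16, effect_topography=topo,
            fixed_effects={"depth_brain": -0.6},
            feature_spatial_sd=0.1, feature_white_sd=0.3, seed=9,
        )
        ds = dd.generate_cohort(cfg)
        spec = ModelSpec(outcome="sleep_depth", predictors=(BRAIN,))
        fits = dd.channelwise_fit(ds.features["gamma"], ds.records, spec)
        W = pd.Series({ch: f.coef(BRAIN).wald for ch, f in fits.items()})
        top6 = set(W.nlargest(6).index)
        assert top6 == set(ds.features["gamma"].columns[:6])

    def test_identical_columns_give_identical_results(self, small_cohort):
        feats = small_cohort.features["gamma"].iloc[:, :1]
        feats = pd.concat([feats, feats.rename(columns={feats.columns[0]: "dup"})],
                          axis=1)
        spec = ModelSpec(outcome="sleep_depth", predictors=(BRAIN,))
        fits = dd.channelwise_fit(feats, small_cohort.records, spec)
        a, b = (fits[c].params for c in feats.columns)
        pd.testing.assert_frame_equal(a, b)

    def test_row_order_invariance(self, small_cohort):
        feats = small_cohort.features["gamma"].iloc[:, :3]
        spec = ModelSpec(outcome="sleep_depth", predictors=(BRAIN,))
        f1 = dd.channelwise_fit(feats, small_cohort.records, spec)
        shuffled = feats.sample(frac=1.0, random_state=0)
        f2 = dd.channelwise_fit(shuffled, small_cohort.records, spec)
        for ch in feats.columns:
            pd.testing.assert_frame_equal(f1[ch].params, f2[ch].params)

    def test_id_mismatch_raises(self, small_cohort):
        feats = small_cohort.features["gamma"].iloc[1:, :3]
        spec = ModelSpec(outcome="sleep_depth", predictors=(BRAIN,))
        with pytest.raises(ValueError, match="missing"):
            dd.channelwise_fit(feats, small_cohort.records, spec)

    def test_engine_matches_scalar_path(self, small_cohort):
        spec = ModelSpec(outcome="sleep_depth", predictors=(BRAIN,))
        feats = small_cohort.features["ratio"].iloc[:, :5]
        eng = dd.ChannelwiseWaldEngine(small_cohort.records, feats, spec)
        tab = eng.wald_table()
        fits = dd.channelwise_fit(feats, small_cohort.records, spec)
        for ch in feats.columns:
            c = fits[ch].coef(BRAIN)
            assert tab.loc[ch, "beta"] == pytest.approx(c.estimate, rel=1e-6)
            assert tab.loc[ch, "wald"] == pytest.approx(c.wald, rel=1e-5)

    def test_outcome_mode_matches_scalar_path(self, small_cohort):
        # brain activity as the outcome (time-trend models on EEG indices)
        spec = ModelSpec(outcome=BRAIN, predictors=("time",),
                         nuisance=("experiment", "night"))
        feats = small_cohort.features["delta"].iloc[:, :4]
        eng = dd.ChannelwiseWaldEngine(small_cohort.records, feats, spec,
                                       term="time")
        tab = eng.wald_table()
        for ch in feats.columns:
            df = small_cohort.records.assign(
                **{BRAIN: feats.loc[small_cohort.records.record_id, ch].to_numpy()}
            )
            fit = fit_lmm(df, spec)
            assert tab.loc[ch, "beta"] == pytest.approx(
                fit.coef("time").estimate, rel=1e-6
            )


class TestCompareModels:
    def test_identity_nesting(self):
        df = _toy_df(6)
        spec = ModelSpec(outcome="y", predictors=("x",))
        fit = fit_lmm(df, spec)
        res = dd.compare_models(fit, fit)
        assert res["lrt_stat"] == 0.0
        assert res["lrt_p"] == 1.0
        assert res["delta_aic"] == pytest.approx(0.0)

    def test_strong_effect_has_tiny_lrt_p(self):
        df = _toy_df(7)
        full = fit_lmm(df, ModelSpec(outcome="y", predictors=("x",)))
        red = fit_lmm(df, ModelSpec(outcome="y", predictors=()))
        res = dd.compare_models(full, red)
        assert res["df"] == 1
        assert res["lrt_p"] < 1e-4
        assert res["delta_aic"] > 0  # full model preferred

    def test_chi2_critical_value(self):
        # df = 1 and LRT stat 3.84 sit exactly at the 5% point
        assert sps.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=1e-3)

    def test_unequal_n_rejected(self):
        df = _toy_df(8)
        f1 = fit_lmm(df, ModelSpec(outcome="y", predictors=("x",)))
        f2 = fit_lmm(df.iloc[:-10], ModelSpec(outcome="y", predictors=("x",)))
        with pytest.raises(ValueError, match="different n"):
            dd.compare_models(f1, f2)


class TestTiedRank:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([10, 20, 20, 40], [1, 2.5, 2.5, 4]),
            ([5, 5, 5], [2, 2, 2]),
            ([1, 2, 3, 4], [1, 2, 3, 4]),
        ],
    )
    def test_examples(self, values, expected):
        np.testing.assert_allclose(dd.tied_rank(values), expected)

    def test_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        r1, r2 = dd.tied_rank(x), dd.tied_rank(np.exp(x))
        np.testing.assert_allclose(r1, r2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dd.tied_rank([])


def test_ci_coverage_at_moderate_n():
    """95% Wald CIs cover the generating slope at ~nominal rate."""
    hits = 0
    R = 100
    for r in range(R):
        df = _toy_df(1000 + r, n_sub=12, per=15)
        fit = fit_lmm(df, ModelSpec(outcome="y", predictors=("x",),
                                    nuisance=("time",)))
        c = fit.coef("x")
        hits += c.ci_low <= 0.3 <= c.ci_high
    assert 0.91 - 0.04 <= hits / R <= 0.99
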