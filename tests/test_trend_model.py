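import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from delivcov import synthetic_data as sd
from delivcov import trend_model as tm
from delivcov.registry_io import CovariateRow, SurveyPoint


def _point(**kw):
    base = dict(country_iso="S00", region="South Asia", survey_year=2000,
                source="SYNTH", stratum="national", outcome="INSD",
                coverage=0.6, n_effective=100.0)
    base.update(kw)
    return SurveyPoint(**base)


class TestLink:
    def test_closed_form_values(self):
        assert tm.logit_transform(0.5) == 0.0
        assert tm.inverse_logit(0.0) == 0.5
        assert tm.logit_transform(0.8) == pytest.approx(math.log(4.0), abs=1e-9)

    def test_boundary_rejected(self):
        for p in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                tm.logit_transform(p)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_mutually_inverse_and_bounded(self, p):
        x = tm.logit_transform(p)
        q = tm.inverse_logit(x)
        assert 0.0 < q < 1.0
        assert q == pytest.approx(p, rel=1e-9, abs=1e-12)

    @given(st.floats(min_value=-30, max_value=30),
           st.floats(min_value=-30, max_value=30))
    def test_inverse_logit_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert tm.inverse_logit(lo) <= tm.inverse_logit(hi)


def _flat_params(alpha, beta=0.0, sigma=1e6):
    return tm.TrendParameters(
        countries=["S00"], alpha=np.array([alpha]), beta=np.array([beta]),
        mu_alpha=0.0, mu_beta=0.0, sigma_alpha=sigma, sigma_beta=sigma,
    )


class TestLogPosterior:
    def test_empty_data_is_prior_only(self):
        cfg = tm.McmcConfig(use_covariates=False)
        p0 = _flat_params(0.0, sigma=1.0)
        p1 = _flat_params(1.0, sigma=1.0)
        # prior-only difference: N(alpha | mu=0, 1) plus flat hyper terms
        diff = tm.log_posterior(p1, [], config=cfg) - tm.log_posterior(p0, [], config=cfg)
        assert diff == pytest.approx(-0.5, abs=1e-9)

    def test_flat_prior_maximizer_is_empirical_logit(self):
        """1-D grid search over the intercept vs the analytic optimum."""
        cfg = tm.McmcConfig(use_covariates=False, prior_scale_fixed=1e6)
        obs = [_point(coverage=0.7, n_effective=50.0)]
        target = tm.logit_transform(0.7)
        grid = np.arange(target - 0.5, target + 0.5, 1e-4)
        vals = [tm.log_posterior(_flat_params(a), obs, config=cfg) for a in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(target, abs=1e-3)

    def test_binomial_symmetry_under_outcome_flip(self):
        cfg = tm.McmcConfig(use_covariates=False)
        obs = [_point(coverage=0.3, n_effective=80.0)]
        flipped = [dataclasses.replace(obs[0], coverage=0.7)]
        lp = tm.log_posterior(_flat_params(1.2, sigma=3.0), obs, config=cfg)
        lp_flip = tm.log_posterior(_flat_params(-1.2, sigma=3.0), flipped, config=cfg)
        assert lp == pytest.approx(lp_flip, abs=1e-9)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            tm.log_posterior(_flat_params(np.nan), [_point()],
                             config=tm.McmcConfig(use_covariates=False))

    def test_missing_covariate_row_reported(self):
        cfg = tm.McmcConfig(use_covariates=True)
        covs = [CovariateRow("S00", 1999, 0.5, 1.0)]
        with pytest.raises(ValueError, match="missing covariate"):
            tm.log_posterior(_flat_params(0.0), [_point()], covs, cfg)


class TestConfig:
    def test_defaults_match_production_run(self):
        cfg = tm.McmcConfig()
        assert (cfg.n_iter, cfg.n_chains, cfg.thin, cfg.burn_in) == (10000, 3, 10, 500)
        assert cfg.draws_per_chain == 950

    @pytest.mark.parametrize("bad", [
        dict(n_iter=100, burn_in=100),
        dict(thin=0),
        dict(n_chains=1),
        dict(prior_family_sd="lognormal"),
        dict(prior_scale_sd=-1.0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            tm.McmcConfig(**bad).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = tm.McmcConfig(n_iter=2000, burn_in=100, seed=42,
                            prior_family_sd="uniform", use_covariates=False)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert tm.McmcConfig.from_yaml(path) == cfg


class TestFit:
    def test_draw_count_contract_and_determinism(self):
        obs = [_point(survey_year=y, coverage=0.5 + 0.02 * (y - 2000))
               for y in range(2000, 2008)]
        cfg = tm.McmcConfig(n_iter=400, burn_in=100, thin=3, seed=5,
                            use_covariates=False)
        d1 = tm.fit(obs, None, cfg)
        d2 = tm.fit(obs, None, cfg)
        assert d1.n_draws == (400 - 100) // 3
        for name in d1.params:
            np.testing.assert_array_equal(d1.params[name], d2.params[name])
        d3 = tm.fit(obs, None, dataclasses.replace(cfg, seed=6))
        assert not np.array_equal(d3.params["alpha"], d1.params["alpha"])

    def test_single_country_slope_recovery(self):
        """True slope 1.0/decade, 8 surveys of n_eff 2000."""
        spec = sd.GeneratorSpec(
            n_countries=1, surveys_per_country=8, mu_beta=1.0, sigma_beta=1e-6,
            mu_alpha=-1.0, sigma_alpha=1e-6, gamma_sdi=0.0, gamma_hrh=0.0,
            n_respondents=4000, design_effect=2.0, outcomes=("INSD",), seed=21,
        )
        truth = sd.generate_trajectories(spec)
        pts = sd.generate_surveys(truth)
        cfg = tm.McmcConfig(n_iter=3000, burn_in=500, thin=5, seed=13,
                            use_covariates=False)
        draws = tm.fit(pts, None, cfg)
        beta_hat = draws.flat("beta", 0).mean()
        assert beta_hat == pytest.approx(truth.beta["INSD"][0], abs=0.15)

    def test_identical_countries_exchangeable(self):
        obs = []
        for c in ("S00", "S01"):
            for y in (2002, 2008, 2014):
                obs.append(_point(country_iso=c, survey_year=y,
                                  coverage=0.55, n_effective=800.0))
        cfg = tm.McmcConfig(n_iter=4000, burn_in=500, thin=5, seed=2,
                            use_covariates=False)
        draws = tm.fit(obs, None, cfg)
        a0, a1 = draws.flat("alpha", 0), draws.flat("alpha", 1)
        mcse = np.sqrt(a0.var() / (a0.size / 5) + a1.var() / (a1.size / 5))
        assert abs(a0.mean() - a1.mean()) < 3 * mcse

    def test_unobserved_country_shrinks_to_hypermean(self):
        obs = [_point(country_iso=f"S{i:02d}", survey_year=y,
                      coverage=0.5 + 0.03 * i, n_effective=1000.0)
               for i in range(6) for y in (2003, 2013)]
        cfg = tm.McmcConfig(n_iter=4000, burn_in=500, thin=5, seed=3,
                            use_covariates=False)
        draws = tm.fit(obs, None, cfg, countries=[f"S{i:02d}" for i in range(7)])
        k = draws.countries.index("S06")
        a_new = draws.flat("alpha", k)
        mu = draws.flat("mu_alpha")
        mcse = 3 * np.sqrt(a_new.var() / (a_new.size / 5))
        assert abs(a_new.mean() - mu.mean()) < max(mcse, 0.1)

    def test_mixed_outcomes_rejected(self):
        obs = [_point(), _point(outcome="SBA", survey_year=2005)]
        with pytest.raises(ValueError, match="single outcome"):
            tm.fit(obs, None, tm.McmcConfig(n_iter=200, burn_in=50,
                                            use_covariates=False))


def _constant_draws(alpha, beta, years_country="S00"):
    nc, nd = 3, 20
    params = {
        "alpha": np.full((nc, nd, 1), alpha),
        "beta": np.full((nc, nd, 1), beta),
        "mu_alpha": np.full((nc, nd), alpha),
        "mu_beta": np.full((nc, nd), beta),
        "sigma_alpha": np.full((nc, nd), 0.5),
        "sigma_beta": np.full((nc, nd), 0.5),
    }
    return tm.PosteriorDraws(
        params=params, countries=[years_country], outcome="INSD",
        stratum="national", config=tm.McmcConfig(use_covariates=False),
        cov_mean=np.zeros(2), cov_sd=np.ones(2),
    )


class TestProject:
    def test_zero_slope_gives_flat_trajectory(self):
        traj = tm.project(_constant_draws(alpha=0.3, beta=0.0))
        assert traj["mean"].nunique() == 1
        assert len(traj) == 31

    def test_increasing_draws_give_increasing_mean(self, recovery_setup):
        *_, draws = recovery_setup
        traj = tm.project(draws)
        assert ((traj["cri_low"] <= traj["mean"])
                & (traj["mean"] <= traj["cri_high"])).all()
        assert ((traj["mean"] > 0) & (traj["mean"] < 100)).all()
        # positive slope draws for every country in this dataset
        beta = np.concatenate(draws.params["beta"], axis=0)
        rising = (beta > 0).all(axis=0)
        for k, c in enumerate(draws.countries):
            if rising[k]:
                m = traj[traj.country_iso == c].sort_values("year")["mean"].to_numpy()
                assert (np.diff(m) > 0).all()

    def test_missing_projection_covariates(self):
        obs = [_point(survey_year=y, coverage=0.6, n_effective=500.0)
               for y in (2001, 2006, 2011, 2016)]
        covs = [CovariateRow("S00", y, 0.4 + 0.004 * (y - 2000), 1.0)
                for y in range(2000, 2020)]
        cfg = tm.McmcConfig(n_iter=600, burn_in=100, thin=5, seed=4)
        draws = tm.fit(obs, covs, cfg)
        with pytest.raises(ValueError, match="missing covariates"):
            tm.project(draws, covs)
        traj = tm.project(draws, covs, extrapolate=True)
        assert set(traj["year"]) == set(range(2000, 2031))


class TestSensitivity:
    def test_self_comparison_is_zero(self):
        traj = tm.project(_constant_draws(0.2, 0.1))
        diff = tm.median_absolute_difference(traj, traj)
        assert (diff["median_abs_diff"] == 0.0).all()

    def test_constant_shift_recovered_exactly(self):
        traj = tm.project(_constant_draws(0.2, 0.1))
        shifted = traj.copy()
        shifted["mean"] = shifted["mean"] + 2.0
        diff = tm.median_absolute_difference(traj, shifted)
        np.testing.assert_allclose(diff["median_abs_diff"], 2.0, atol=1e-12)

    def test_misaligned_frames_rejected(self):
        traj = tm.project(_constant_draws(0.2, 0.1))
        with pytest.raises(ValueError, match="align"):
            tm.median_absolute_difference(traj, traj.iloc[:-3])
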