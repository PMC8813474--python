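import numpy as np
import pytest
import statsmodels.api as sm

from delivcov import determinants as det
from delivcov import synthetic_data as sd
from delivcov.registry_io import IndividualRecord
from delivcov.trend_model import McmcConfig


def _record(**kw):
    base = dict(country_iso="S00", outcome_insd=1, outcome_sba=0,
                hh_head_age="<30", hh_head_sex="male", education="none",
                parity="1", anc_visits="0", media="none",
                wealth_quintile="Q1", residence="urban")
    base.update(kw)
    return IndividualRecord(**base)


class TestEncodeDesign:
    def test_reference_record_is_all_zero(self):
        x, y, cidx, countries, cols = det.encode_design([_record()])
        assert x.shape == (1, 21)
        assert not x.any()
        assert y.tolist() == [1.0]

    def test_twenty_one_non_reference_columns(self):
        assert len(det.design_columns()) == 21
        # 3 age + 1 sex + 3 education + 3 parity + 4 ANC + 2 media
        # + 4 wealth + 1 residence
        prefixes = [c.split(":")[0] for c in det.design_columns()]
        counts = {p: prefixes.count(p) for p in set(prefixes)}
        assert counts == {"hh_head_age": 3, "hh_head_sex": 1, "education": 3,
                          "parity": 3, "anc_visits": 4, "media": 2,
                          "wealth_quintile": 4, "residence": 1}

    def test_single_level_sets_single_column(self):
        x, *_ , cols = det.encode_design([_record(education="higher")])
        assert x.sum() == 1.0
        assert x[0, cols.index("education:higher")] == 1.0

    def test_outcome_selection_and_row_count(self):
        recs = [_record(), _record(country_iso="S01", outcome_sba=1)]
        x, y, cidx, countries, _ = det.encode_design(recs, outcome="SBA")
        assert x.shape == (2, 21)
        assert y.tolist() == [0.0, 1.0]
        assert countries == ["S00", "S01"]

    def test_invalid_category_rejected(self):
        bad = IndividualRecord("S00", 1, 0, "<30", "male", "phd", "1", "0",
                               "none", "Q1", "urban")
        with pytest.raises(Exception):
            det.encode_design([bad])


class TestFitContracts:
    def test_separation_reported(self):
        rng = np.random.Generator(np.random.PCG64(0))
        recs = []
        for i in range(200):
            rural = bool(rng.integers(2))
            y = 1 if rural else int(rng.integers(2))  # rural => always 1
            recs.append(_record(country_iso=f"S{i % 3}",
                                residence="rural" if rural else "urban",
                                outcome_insd=y))
        with pytest.raises(det.SeparationError, match="residence:rural"):
            det.fit_determinants(recs, McmcConfig(n_iter=200, burn_in=50))

    def test_constant_outcome_rejected(self):
        recs = [_record(country_iso=f"S{i % 2}") for i in range(20)]
        with pytest.raises(ValueError, match="identical"):
            det.fit_determinants(recs, McmcConfig(n_iter=200, burn_in=50))

    def test_single_country_needs_no_random_intercept(self):
        recs = [_record(outcome_insd=i % 2) for i in range(40)]
        with pytest.raises(ValueError, match="2 countries"):
            det.fit_determinants(recs, McmcConfig(n_iter=200, burn_in=50))

    def test_seed_determinism(self):
        truth = sd.DeterminantTruth(intercept=0.0, sigma2_u0=0.5)
        spec = sd.GeneratorSpec(n_countries=3, determinant_truth=truth, seed=5)
        recs = sd.generate_individuals(spec, n_per_country=300)
        cfg = McmcConfig(n_iter=400, burn_in=100, thin=2, seed=77)
        d1 = det.fit_determinants(recs, cfg)
        d2 = det.fit_determinants(recs, cfg)
        np.testing.assert_array_equal(d1.params["beta"], d2.params["beta"])


class TestOrTable:
    def _draws(self, beta_value):
        nc, nd, p = 2, 10, 22
        params = {"beta": np.full((nc, nd, p), beta_value)}
        return det.DeterminantDraws(
            params=params, columns=det.design_columns(), countries=["S00", "S01"],
            outcome="INSD", config=McmcConfig(), acceptance={},
        )

    def test_zero_coefficients_give_unit_ors(self):
        tab = det.or_table(self._draws(0.0))
        non_ref = tab[~tab.reference & (tab.characteristic != "random_intercept")]
        assert (non_ref["estimate"] == 1.0).all()

    def test_constant_log2_draws_give_or_two(self):
        tab = det.or_table(self._draws(np.log(2.0)))
        non_ref = tab[~tab.reference & (tab.characteristic != "random_intercept")]
        assert np.allclose(non_ref["estimate"], 2.0)
        assert np.allclose(non_ref["cri_low"], non_ref["cri_high"])

    def test_row_layout_matches_published_schema(self, determinant_setup):
        *_, draws = determinant_setup
        tab = det.or_table(draws)
        # 29 covariate rows (8 reference + 21 levels) + the variance line
        assert len(tab) == 30
        refs = tab[tab.reference]
        assert len(refs) == 8
        assert (refs["estimate"] == 1.0).all()
        assert tab.iloc[-1]["level"] == "sigma2_u0"
        labels = list(tab["characteristic"].unique())
        assert labels == ["hh_head_age", "hh_head_sex", "education", "parity",
                          "anc_visits", "media", "wealth_quintile", "residence",
                          "random_intercept"]


class TestRecovery:
    def test_outcome_swap_negates_coefficients(self):
        truth = sd.DeterminantTruth(
            intercept=0.2, coefficients={"residence:rural": 0.8}, sigma2_u0=0.3)
        spec = sd.GeneratorSpec(n_countries=4, determinant_truth=truth, seed=15)
        recs = sd.generate_individuals(spec, n_per_country=1200)
        flipped = [IndividualRecord(
            r.country_iso, 1 - r.outcome_insd, r.outcome_sba, r.hh_head_age,
            r.hh_head_sex, r.education, r.parity, r.anc_visits, r.media,
            r.wealth_quintile, r.residence) for r in recs]
        cfg = McmcConfig(n_iter=2500, burn_in=500, thin=4, seed=31)
        b = det.fit_determinants(recs, cfg).coefficient_draws("residence:rural")
        b_flip = det.fit_determinants(flipped, cfg).coefficient_draws(
            "residence:rural")
        assert b.mean() == pytest.approx(-b_flip.mean(), abs=0.1)

    def test_single_country_matches_ml_oracle(self):
        """Without the random intercept, posterior means track the MLE."""
        truth = sd.DeterminantTruth(
            intercept=-0.3,
            coefficients={"residence:rural": -0.5, "education:higher": 0.9,
                          "anc_visits:>=4": 1.2},
            sigma2_u0=1e-6,
        )
        spec = sd.GeneratorSpec(n_countries=1, determinant_truth=truth, seed=23)
        recs = sd.generate_individuals(spec, n_per_country=8000)
        cfg = McmcConfig(n_iter=6000, burn_in=1000, thin=5, seed=41)
        draws = det.fit_determinants(recs, cfg, include_random_intercept=False)
        x, y, *_ = det.encode_design(recs)
        xd = np.column_stack([np.ones(len(y)), x])
        mle = np.asarray(sm.Logit(y, xd).fit(disp=0).params)
        post_mean = np.concatenate(draws.params["beta"], axis=0).mean(axis=0)
        assert np.max(np.abs(post_mean - mle)) < 0.05
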