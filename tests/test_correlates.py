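"""Misdiagnosis-correlate multilevel Poisson model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import bpscreen as b
from bpscreen.correlates import FIXED_TERMS, fit_poisson_glmm, _design


def simulate(n=8000, n_countries=8, n_regions=4, seed=0,
             beta=(-3.2, -0.1, 0.01, 0.03, 1.0), sd_country=0.0, sd_region=0.0):
    """Binary outcome with log-link prevalence model.

    beta = (intercept, female, age, bmi, risk); covariates on native scales.
    """
    rng = np.random.default_rng(seed)
    country = rng.integers(0, n_countries, n)
    region = country % n_regions
    female = rng.random(n) < 0.5
    age = rng.uniform(18, 69, n)
    bmi = rng.normal(25.5, 4.0, n)
    risk = rng.uniform(0.0, 0.3, n)
    u_c = rng.normal(0, sd_country, n_countries)
    u_r = rng.normal(0, sd_region, n_regions)
    lp = (beta[0] + beta[1] * female + beta[2] * (age - 43.5)
          + beta[3] * (bmi - 25.5) + beta[4] * risk
          + u_c[country] + u_r[region])
    y = (rng.random(n) < np.minimum(np.exp(lp), 1.0)).astype(float)
    records = pd.DataFrame({
        "sex": np.where(female, "female", "male"), "age": age, "bmi": bmi,
        "country": [f"C{c}" for c in country],
        "region": [f"R{r}" for r in region],
    })
    return y, records, risk


class TestPreconditions:
    def test_single_region_is_degenerate(self):
        y, rec, risk = simulate(n=500)
        rec["region"] = "R0"
        with pytest.raises(b.DegenerateDesignError, match="region"):
            fit_poisson_glmm(y, _design(rec, risk), rec["country"], rec["region"])

    def test_single_country_per_region_is_degenerate(self):
        y, rec, risk = simulate(n=500)
        rec["country"] = rec["region"]  # one country per region
        with pytest.raises(b.DegenerateDesignError, match="countries"):
            fit_poisson_glmm(y, _design(rec, risk), rec["country"], rec["region"])

    def test_zero_events_is_explicit(self):
        y, rec, risk = simulate(n=500)
        with pytest.raises(b.NoEventsError):
            fit_poisson_glmm(np.zeros_like(y), _design(rec, risk),
                             rec["country"], rec["region"])


class TestEstimates:
    def test_zero_variance_oracle_plain_poisson(self):
        """With no random-effect variance the multilevel fit must agree
        with an ordinary Poisson regression to 2 significant figures."""
        y, rec, risk = simulate(n=20_000, seed=3)
        X = _design(rec, risk)
        est = fit_poisson_glmm(y, X, rec["country"], rec["region"])
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        for i, term in enumerate(FIXED_TERMS):
            pr_glm = np.exp(glm.params[i + 1])
            assert est.terms[term].pr == pytest.approx(pr_glm, rel=5e-3), term
        assert est.var_country_in_region < 0.01
        assert est.var_region < 0.01

    def test_invariant_pr_positive_ci_ordered(self):
        y, rec, risk = simulate(n=6000, sd_country=0.3, seed=5)
        est = fit_poisson_glmm(y, _design(rec, risk), rec["country"], rec["region"])
        for t in est.terms.values():
            assert t.pr > 0
            assert t.ci_low <= t.pr <= t.ci_high
            assert 0 <= t.p_value <= 1
        assert est.var_country_in_region >= 0 and est.var_region >= 0
        assert est.n_obs == 6000

    def test_null_cis_cover_unity(self):
        """Null model (all covariate effects 0, no random variance):
        each PR's 95% CI covers 1 in at least 90 of 100 replicates."""
        hits = {t: 0 for t in FIXED_TERMS}
        for rep in range(100):
            y, rec, risk = simulate(n=2000, seed=100 + rep,
                                    beta=(-2.8, 0.0, 0.0, 0.0, 0.0))
            est = fit_poisson_glmm(y, _design(rec, risk), rec["country"], rec["region"])
            for t, term in est.terms.items():
                hits[t] += term.ci_low <= 1.0 <= term.ci_high
        for t, n_cover in hits.items():
            assert n_cover >= 90, (t, n_cover)


class TestCrossCheck:
    def test_agrees_with_statsmodels_map_fitter(self):
        """Independent route: statsmodels' Bayesian mixed-GLM MAP fit
        (different objective, optimizer and code path) must give the
        same prevalence ratios to within 2%."""
        from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

        y, rec, risk = simulate(n=8000, sd_country=0.3, seed=11)
        X = _design(rec, risk)
        est = fit_poisson_glmm(y, X, rec["country"], rec["region"])

        mu, sd = X[:, 1:].mean(0), X[:, 1:].std(0)
        Xs = X.copy()
        Xs[:, 1:] = (X[:, 1:] - mu) / sd
        c = pd.Categorical(rec["country"]).codes
        r = pd.Categorical(rec["region"]).codes
        n_c, n_r = c.max() + 1, r.max() + 1
        vc = np.zeros((len(y), n_c + n_r))
        vc[np.arange(len(y)), c] = 1
        vc[np.arange(len(y)), n_c + r] = 1
        ident = np.array([0] * n_c + [1] * n_r)
        state = np.random.get_state()
        try:
            np.random.seed(1)
            fit = PoissonBayesMixedGLM(y, Xs, vc, ident, fe_p=5).fit_map()
        finally:
            np.random.set_state(state)
        prs = np.exp(np.asarray(fit.fe_mean)[1:] / sd)
        for j, term in enumerate(FIXED_TERMS):
            assert est.terms[term].pr == pytest.approx(prs[j], rel=0.02), term


class TestMissedModel:
    def test_fit_missed_model_end_to_end(self, eligible_cohort):
        risk = b.score(eligible_cohort)["risk"]
        est = b.fit_missed_model(eligible_cohort, "second", risk)
        assert set(est.terms) == set(FIXED_TERMS)
        assert est.n_obs == len(eligible_cohort)
        assert est.n_events > 0
        frame = est.to_frame()
        assert {"approach_id", "term", "pr", "ci_low", "ci_high"} <= set(frame.columns)

    def test_rows_with_missing_risk_excluded(self, eligible_cohort):
        risk = b.score(eligible_cohort)["risk"].copy()
        drop_country = eligible_cohort["country"].iloc[0]
        risk[eligible_cohort["country"] == drop_country] = np.nan
        est = b.fit_missed_model(eligible_cohort, "second", risk)
        assert est.n_obs == int((eligible_cohort["country"] != drop_country).sum())
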