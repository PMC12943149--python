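import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from reference_impls import weighted_mean_se_ref
from tdp.survey import (
    ConvergenceError,
    SurveyDesign,
    SurveyLogit,
    rao_scott_chisq,
    weighted_mean_se,
)


def iid_design(n, weights=None):
    """Degenerate design: one stratum, each row its own PSU."""
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    return SurveyDesign(np.zeros(n, dtype=int), np.arange(n), w)


def clustered_design(rng, n, n_strata=5, psus_per_stratum=4, weight_sd=0.3):
    psu = np.arange(n) % (n_strata * psus_per_stratum)
    strata = psu // psus_per_stratum
    w = np.exp(rng.normal(0, weight_sd, n))
    return SurveyDesign(strata, psu % psus_per_stratum, w)


class TestDesign:
    def test_validation(self):
        with pytest.raises(ValueError):
            SurveyDesign([0, 0], [0, 1], [1.0, -2.0])
        with pytest.raises(ValueError):
            SurveyDesign([0], [0, 1], [1.0, 1.0])

    def test_df_design(self, rng):
        d = clustered_design(rng, 100)
        assert d.df_design == 20 - 5

    def test_psu_keys_scoped_by_stratum(self):
        # PSU label "0" in two strata = two distinct PSUs
        d = SurveyDesign([0, 0, 1, 1], [0, 1, 0, 1], np.ones(4))
        assert d.n_psus == 4 and d.df_design == 2


class TestWeightedMean:
    def test_degenerate_matches_classical(self, rng):
        y = rng.normal(size=40)
        mean, se = weighted_mean_se(y, iid_design(40))
        assert mean == pytest.approx(y.mean(), abs=1e-12)
        assert se == pytest.approx(y.std(ddof=1) / np.sqrt(40), abs=1e-12)

    def test_hand_weighted_example(self):
        mean, _ = weighted_mean_se([1.0, 4.0], iid_design(2, weights=[2.0, 1.0]))
        assert mean == pytest.approx(2.0)

    def test_matches_textbook_reference(self, rng):
        d = clustered_design(rng, 200)
        y = rng.normal(2.0, 1.0, 200)
        mean, se = weighted_mean_se(y, d)
        ref_mean, ref_se = weighted_mean_se_ref(
            y, d.weights, d.strata.tolist(), list(zip(d.strata, d.psu)))
        assert mean == pytest.approx(ref_mean, abs=1e-10)
        assert se == pytest.approx(ref_se, abs=1e-10)

    def test_weight_scale_invariance(self, rng):
        d = clustered_design(rng, 100)
        y = rng.normal(size=100)
        m1, s1 = weighted_mean_se(y, d)
        d2 = SurveyDesign(d.strata, d.psu, 2.0 * d.weights)
        m2, s2 = weighted_mean_se(y, d2)
        assert m1 == pytest.approx(m2, abs=1e-12)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_singleton_stratum_policy(self, rng):
        strata = np.array([0] * 10 + [1])
        psu = np.array(list(range(5)) * 2 + [0])
        d = SurveyDesign(strata, psu, np.ones(11), lonely_psu="error")
        with pytest.raises(ValueError, match="single PSU"):
            weighted_mean_se(rng.normal(size=11), d)
        d_adj = SurveyDesign(strata, psu, np.ones(11), lonely_psu="adjust")
        _, se = weighted_mean_se(rng.normal(size=11), d_adj)
        assert np.isfinite(se)


class TestRaoScott:
    def test_degenerate_equals_pearson(self, rng):
        a = rng.integers(0, 3, 300)
        b = rng.integers(0, 2, 300)
        stat, df, p = rao_scott_chisq(a, b, iid_design(300))
        tab = np.zeros((3, 2))
        np.add.at(tab, (a, b), 1)
        pearson = stats.chi2_contingency(tab, correction=False)[0]
        assert stat == pytest.approx(pearson, abs=1e-9)
        assert df == 2

    def test_perfect_association(self):
        a = np.repeat([0, 1], 50)
        stat, _, p = rao_scott_chisq(a, a, iid_design(100))
        assert p < 1e-6

    def test_null_pvalues_uniform(self, rng):
        """Calibration: p-values under independence pass a KS test."""
        pvals = []
        for _ in range(200):
            a = rng.integers(0, 2, 1000)
            b = rng.integers(0, 3, 1000)
            pvals.append(rao_scott_chisq(a, b, iid_design(1000))[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_level_rejected(self, rng):
        a = np.zeros(50, dtype=int)
        b = rng.integers(0, 2, 50)
        with pytest.raises(ValueError):
            rao_scott_chisq(a, b, iid_design(50))


def simulate_logit(rng, n, beta, design):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, len(beta) - 1))])
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    return X, y


class TestSurveyLogit:
    def test_degenerate_matches_classical_mle(self, rng):
        import statsmodels.api as sm

        X, y = simulate_logit(rng, 500, np.array([-0.5, 0.8, -0.3]), None)
        fit = SurveyLogit(y, X, iid_design(500)).fit()
        classical = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.params, classical.params, atol=1e-6)

    def test_weighted_estimates_match_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        n = 400
        X, y = simulate_logit(rng, n, np.array([-0.2, 0.5]), None)
        w = np.exp(rng.normal(0, 0.4, n))
        fit = SurveyLogit(y, X, iid_design(n, weights=w)).fit()
        glm = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        assert np.allclose(fit.params, glm.params, atol=1e-6)

    def test_weight_doubling_invariance(self, rng):
        d = clustered_design(rng, 300)
        X, y = simulate_logit(rng, 300, np.array([0.0, 0.4]), d)
        f1 = SurveyLogit(y, X, d).fit()
        f2 = SurveyLogit(y, X, SurveyDesign(d.strata, d.psu, 2 * d.weights)).fit()
        assert np.allclose(f1.params, f2.params, atol=1e-10)
        assert np.allclose(f1.bse, f2.bse, atol=1e-10)

    def test_odds_ratio_and_ci_shape(self, rng):
        d = clustered_design(rng, 300)
        X, y = simulate_logit(rng, 300, np.array([-0.3, 0.6]), d)
        res = SurveyLogit(y, X, d, exog_names=["const", "x"]).fit()
        or_tab = res.odds_ratios()
        assert np.allclose(or_tab["OR"], np.exp(res.params))
        assert (or_tab["ci_low"] < or_tab["OR"]).all()
        assert (or_tab["OR"] < or_tab["ci_high"]).all()
        assert res.df_design == d.df_design
        assert "Survey-weighted logistic" in res.summary()

    def test_covariance_is_psd(self, rng):
        d = clustered_design(rng, 400)
        X, y = simulate_logit(rng, 400, np.array([-0.3, 0.6, 0.2]), d)
        res = SurveyLogit(y, X, d).fit()
        assert np.linalg.eigvalsh(res.cov_params)[0] >= -1e-12

    def test_separation_detected(self):
        X = np.column_stack([np.ones(40), np.r_[np.zeros(20), np.ones(20)]])
        y = X[:, 1].copy()
        with pytest.raises(ConvergenceError):
            SurveyLogit(y, X, iid_design(40)).fit()

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError):
            SurveyLogit(np.array([0.0, 2.0]), np.ones((2, 1)), iid_design(2))

    def test_from_formula(self, rng):
        import pandas as pd

        n = 200
        df = pd.DataFrame({"y": rng.integers(0, 2, n).astype(float),
                           "x": rng.normal(size=n),
                           "g": rng.choice(["a", "b"], n)})
        model = SurveyLogit.from_formula("y ~ x + C(g)", df, iid_design(n))
        res = model.fit()
        assert len(res.params) == 3
        assert any("g" in nm for nm in res.exog_names)
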