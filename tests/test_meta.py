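import numpy as np
import pytest
from scipy import stats
from scipy.integrate import cumulative_trapezoid, trapezoid

import trialbayes as tb
from trialbayes import datasets
from trialbayes.errors import InvalidInputError


def brute_force_2d(studies, mu_prior_sd=1.0, hn_sd=0.5, mu_span=4.0, tau_span=5.0):
    """Independent oracle: direct 2D grid integration of the joint posterior."""
    y = np.array([s.y for s in studies])
    sig = np.array([s.sigma for s in studies])
    mu = np.linspace(-mu_span, mu_span, 1601)
    tau = np.linspace(0, tau_span, 1201)
    MU, TAU = np.meshgrid(mu, tau, indexing="ij")
    lp = stats.norm.logpdf(MU, 0, mu_prior_sd) + stats.halfnorm.logpdf(TAU, scale=hn_sd)
    for yi, si in zip(y, sig):
        lp += stats.norm.logpdf(yi, MU, np.sqrt(si**2 + TAU**2))
    w = np.exp(lp - lp.max())
    Z = trapezoid(trapezoid(w, tau, axis=1), mu)
    mu_marg = trapezoid(w, tau, axis=1) / Z
    tau_marg = trapezoid(w, mu, axis=0) / Z
    return mu, mu_marg, tau, tau_marg


class TestPublishedFit:
    def test_mu_summary(self, packaged_fit):
        mu = tb.posterior_summary(packaged_fit, "mu")
        assert mu["estimate"] == pytest.approx(-0.06, abs=0.02)
        mean = tb.posterior_summary(packaged_fit, "mu", kind="mean")
        assert mean["estimate"] == pytest.approx(mu["estimate"], abs=0.02)

    def test_tau_summary(self, packaged_fit):
        tau = tb.posterior_summary(packaged_fit, "tau")
        assert tau["estimate"] == pytest.approx(0.33, abs=0.05)
        assert tau["cri_lower"] == pytest.approx(0.0, abs=0.05)
        assert tau["cri_upper"] == pytest.approx(0.88, abs=0.05)

    def test_jeffreys_increases_heterogeneity(self, packaged_fit, packaged_fit_jeffreys):
        tau_hn = tb.posterior_summary(packaged_fit, "tau")["estimate"]
        tau_j = tb.posterior_summary(packaged_fit_jeffreys, "tau")
        assert tau_j["estimate"] == pytest.approx(0.59, abs=0.07)
        assert tau_j["cri_upper"] == pytest.approx(2.76, abs=0.15)
        assert tau_j["estimate"] > tau_hn

    def test_matches_brute_force_2d(self, packaged_fit):
        mu, mu_marg, tau, tau_marg = brute_force_2d(datasets.meta_studies())
        cdf_m = cumulative_trapezoid(mu_marg, mu, initial=0)
        cdf_t = cumulative_trapezoid(tau_marg, tau, initial=0)
        assert tb.posterior_summary(packaged_fit, "mu")["estimate"] == pytest.approx(
            np.interp(0.5, cdf_m, mu), abs=1e-3
        )
        assert tb.posterior_summary(packaged_fit, "tau")["estimate"] == pytest.approx(
            np.interp(0.5, cdf_t, tau), abs=1e-3
        )

    def test_wider_mu_prior_barely_moves_estimate(self, packaged_fit):
        wide = tb.fit_nnhm(datasets.meta_studies(), mu_prior_sd=4.0)
        a = tb.posterior_summary(packaged_fit, "mu")["estimate"]
        b = tb.posterior_summary(wide, "mu")["estimate"]
        assert abs(a - b) < 0.02


class TestBayesFactors:
    def test_published_bf_against_global_null(self, packaged_fit):
        assert tb.bf10_meta(packaged_fit)["bf10"] == pytest.approx(0.26, abs=0.02)

    def test_savage_dickey_equals_marginal_likelihood_route(self, packaged_fit):
        sd = tb.bf10_meta(packaged_fit, null="mu_zero", method="savage_dickey")
        ml = tb.bf10_meta(packaged_fit, null="mu_zero", method="marginal_likelihood")
        assert sd["bf10"] == pytest.approx(ml["bf10"], rel=1e-4)

    def test_savage_dickey_against_brute_force(self, packaged_fit):
        mu, mu_marg, _, _ = brute_force_2d(datasets.meta_studies())
        post0 = np.interp(0.0, mu, mu_marg)
        expected = stats.norm.pdf(0, 0, 1) / post0
        got = tb.bf10_meta(packaged_fit, null="mu_zero")["bf10"]
        assert got == pytest.approx(expected, rel=1e-3)

    def test_null_data_favour_null(self):
        studies = [tb.StudyInput(f"s{i}", 0.0, 0.05) for i in range(4)]
        fit = tb.fit_nnhm(studies)
        assert tb.bf10_meta(fit)["bf10"] < 0.05
        assert tb.bf10_meta(fit, null="mu_zero")["bf10"] < 0.2

    def test_bf01_reciprocal(self, packaged_fit):
        r = tb.bf10_meta(packaged_fit)
        assert r["bf10"] * r["bf01"] == pytest.approx(1.0, abs=1e-12)


class TestConjugateLimits:
    def test_single_study_tau_zero_matches_closed_form(self):
        y, sigma, prior_sd = 0.3, 0.4, 1.0
        fit = tb.fit_nnhm(
            [tb.StudyInput("only", y, sigma)],
            mu_prior_sd=prior_sd,
            tau_prior=tb.half_normal_prior(1e-8),
        )
        prec = 1 / sigma**2 + 1 / prior_sd**2
        mean, sd = (y / sigma**2) / prec, np.sqrt(1 / prec)
        mu = tb.posterior_summary(fit, "mu")
        assert mu["estimate"] == pytest.approx(mean, abs=1e-6)
        assert mu["cri_lower"] == pytest.approx(mean - 1.959964 * sd, abs=1e-5)
        assert mu["cri_upper"] == pytest.approx(mean + 1.959964 * sd, abs=1e-5)

    def test_two_studies_tau_zero_is_precision_weighted(self):
        studies = [tb.StudyInput("a", -0.4, 0.3), tb.StudyInput("b", 0.3, 0.31)]
        fit = tb.fit_nnhm(studies, tau_prior=tb.half_normal_prior(1e-8))
        prec = 1 / 0.3**2 + 1 / 0.31**2 + 1.0
        mean = (-0.4 / 0.3**2 + 0.3 / 0.31**2) / prec
        assert tb.posterior_summary(fit, "mu")["estimate"] == pytest.approx(mean, abs=1e-6)

    def test_symmetric_null_study_centers_at_zero(self):
        fit = tb.fit_nnhm([tb.StudyInput("a", 0.0, 0.5)])
        assert tb.posterior_summary(fit, "mu", kind="mean")["estimate"] == pytest.approx(
            0.0, abs=1e-9
        )


class TestPosteriorNormalization:
    def test_tau_density_integrates_to_one(self, packaged_fit, packaged_fit_jeffreys):
        for fit in (packaged_fit, packaged_fit_jeffreys):
            mass = trapezoid(fit.tau_density, fit.tau_grid)
            assert mass == pytest.approx(1.0, abs=1e-4)

    def test_mu_mixture_integrates_to_one(self, packaged_fit):
        x = np.linspace(-8, 8, 4001)
        mass = trapezoid(packaged_fit.mu_mixture_pdf(x), x)
        assert mass == pytest.approx(1.0, abs=1e-4)

    def test_infinitely_noisy_study_is_ignored(self, packaged_fit):
        studies = datasets.meta_studies() + [tb.StudyInput("noise", 5.0, 1e6)]
        fit = tb.fit_nnhm(studies)
        for param in ("mu", "tau"):
            a = tb.posterior_summary(packaged_fit, param)["estimate"]
            b = tb.posterior_summary(fit, param)["estimate"]
            assert b == pytest.approx(a, abs=1e-6)


class TestShrinkageAndPrediction:
    def test_shrinkage_lies_between_direct_and_pooled(self, packaged_fit):
        pooled = tb.posterior_summary(packaged_fit, "mu")["estimate"]
        for i, s in enumerate(packaged_fit.studies):
            est = tb.shrinkage(packaged_fit, i)["estimate"]
            lo, hi = sorted((s.y, pooled))
            assert lo < est < hi

    def test_complete_pooling_limit(self):
        studies = [tb.StudyInput("a", -0.4, 0.3), tb.StudyInput("b", 0.3, 0.31)]
        fit = tb.fit_nnhm(studies, tau_prior=tb.half_normal_prior(1e-8))
        mu = tb.posterior_summary(fit, "mu")
        for i in range(2):
            sh = tb.shrinkage(fit, i)
            assert sh["estimate"] == pytest.approx(mu["estimate"], abs=1e-6)

    def test_no_pooling_limit(self):
        # strongly heterogeneous data under a very wide tau prior: posterior
        # tau is large, so each study keeps its direct estimate
        studies = [tb.StudyInput("a", -5.0, 0.1), tb.StudyInput("b", 5.0, 0.1)]
        fit = tb.fit_nnhm(studies, mu_prior_sd=10.0, tau_prior=tb.half_normal_prior(50.0))
        for i, s in enumerate(studies):
            sh = tb.shrinkage(fit, i)
            assert sh["estimate"] == pytest.approx(s.y, abs=0.05)

    def test_index_out_of_range(self, packaged_fit):
        with pytest.raises(InvalidInputError):
            tb.shrinkage(packaged_fit, 5)

    def test_prediction_wider_than_mu_and_covers_zero(self, packaged_fit):
        mu = tb.posterior_summary(packaged_fit, "mu")
        pred = tb.predictive(packaged_fit)
        assert pred["cri_lower"] < mu["cri_lower"]
        assert pred["cri_upper"] > mu["cri_upper"]
        assert pred["cri_lower"] < 0 < pred["cri_upper"]

    def test_degenerate_tau_prediction_equals_mu(self):
        fit = tb.fit_nnhm(
            [tb.StudyInput("a", 0.2, 0.4)], tau_prior=tb.half_normal_prior(1e-8)
        )
        mu = tb.posterior_summary(fit, "mu")
        pred = tb.predictive(fit)
        assert pred["estimate"] == pytest.approx(mu["estimate"], abs=1e-6)
        assert pred["cri_upper"] == pytest.approx(mu["cri_upper"], abs=1e-5)


class TestValidation:
    def test_no_studies_rejected(self):
        with pytest.raises(InvalidInputError):
            tb.fit_nnhm([])

    def test_bad_cri_level(self, packaged_fit):
        with pytest.raises(InvalidInputError):
            tb.posterior_summary(packaged_fit, "mu", cri_level=1.5)

    def test_bad_priors(self):
        with pytest.raises(InvalidInputError):
            tb.half_normal_prior(-1.0)
        with pytest.raises(InvalidInputError):
            tb.HeterogeneityPrior(family="lognormal")
        with pytest.raises(InvalidInputError):
            tb.StudyInput("x", 0.1, 0.0)

    def test_forest_data_rows(self, packaged_fit):
        frame = tb.forest_data(packaged_fit)
        assert list(frame["label"])[-2:] == ["overall effect", "prediction"]
        assert len(frame) == len(packaged_fit.studies) + 2
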