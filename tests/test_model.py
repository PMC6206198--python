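"""Bayesian model fitting: diagnostics, conjugate oracles, temporal variant."""

import numpy as np
import pytest

import bandfec as bf
from bandfec.sampler import rhat
from bandfec.simulate import ReplicateParams, SimConfig, simulate_dataset

from conftest import JUNCO, mcse


class TestRhat:
    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(4, 5000))
        assert abs(rhat(draws) - 1.0) < 0.02

    def test_offset_chains_diverge(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(2, 500))
        draws[1] += 50.0
        assert rhat(draws) > 10

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(42)
        draws = rng.normal(size=(2, 100))
        # independently coded between/within variance ratio
        n = 100
        means = [draws[0].mean(), draws[1].mean()]
        W = (np.var(draws[0], ddof=1) + np.var(draws[1], ddof=1)) / 2
        B = n * np.var(means, ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat(draws) == pytest.approx(expected, rel=1e-12)

    def test_single_chain_errors(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestSettings:
    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            bf.MCMCSettings(n_iter=100, n_burn=100)

    def test_thin_positive(self):
        with pytest.raises(ValueError):
            bf.MCMCSettings(thin=0)

    def test_sparse_schedule_is_tenfold(self):
        s, base = bf.MCMCSettings.sparse(), bf.MCMCSettings()
        assert s.n_iter == 10 * base.n_iter and s.n_burn == 10 * base.n_burn


class TestConjugateFactorization:
    """The recapture/age-composition binomials share no parameters with the
    recovery multinomials, so under Uniform(0,1) priors their marginal
    posteriors are exactly Beta; MCMC must agree within Monte Carlo error."""

    def test_capture_probability_marginals(self, junco_fit):
        for name, f2, M in (("p_j", JUNCO["f2_j"], JUNCO["M_j"]),
                            ("p_a", JUNCO["f2_a"], JUNCO["M_a"])):
            a, b = f2 + 1, M - f2 + 1
            exact_mean = a / (a + b)
            exact_sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
            draws = junco_fit.quantities[name]
            err = mcse(draws)
            assert abs(draws.mean() - exact_mean) < 3 * err
            assert abs(draws.std(ddof=1) - exact_sd) < 0.1 * exact_sd

    def test_age_composition_marginal(self, junco_fit):
        a, b = JUNCO["M_j"] + 1, JUNCO["M_a"] + 1
        draws = junco_fit.quantities["c_j"]
        assert abs(draws.mean() - a / (a + b)) < 3 * mcse(draws)

    def test_derived_vulnerability_closed_form(self, junco_fit):
        # E[V] = E[p_j] * E[1/p_a] by posterior independence
        a_j, b_j = JUNCO["f2_j"] + 1, JUNCO["M_j"] - JUNCO["f2_j"] + 1
        a_a, b_a = JUNCO["f2_a"] + 1, JUNCO["M_a"] - JUNCO["f2_a"] + 1
        exact = (a_j / (a_j + b_j)) * ((a_a + b_a - 1) / (a_a - 1))
        draws = junco_fit.quantities["V"]
        assert abs(draws.mean() - exact) < 3 * mcse(draws)

    def test_derived_fecundity_closed_form(self, junco_fit):
        # E[F] = E[c/(1-c)] * E[p_a] * E[1/p_j]
        exact = (
            (JUNCO["M_j"] + 1) / JUNCO["M_a"]
            * (JUNCO["f2_a"] + 1) / (JUNCO["M_a"] + 2)
            * (JUNCO["M_j"] + 1) / JUNCO["f2_j"]
        )
        draws = junco_fit.quantities["F"]
        assert abs(draws.mean() - exact) < 3 * mcse(draws)

    def test_age_ratio_posterior_mean_table_value(self, junco_fit):
        # posterior mean of c/(1-c) has closed form (M_j+1)/M_a = 2.305
        draws = junco_fit.quantities["age_ratio"]
        assert draws.mean() == pytest.approx((JUNCO["M_j"] + 1) / JUNCO["M_a"], abs=5e-4)
        assert round(float(draws.mean()), 3) == 2.305

    def test_adult_capture_probability_table_value(self, junco_fit):
        # rounds to 0.00015 at two significant figures
        mean = float(junco_fit.quantities["p_a"].mean())
        assert f"{mean:.1e}" == "1.5e-04"


class TestNoInformationLimit:
    def test_flat_prior_recovered_without_recoveries(self):
        T = 3
        empty = np.zeros((T, T), int)
        ds = bf.BandingDataset(
            juvenile=bf.MArray("juvenile", np.arange(T), np.zeros(T, int), empty),
            adult=bf.MArray("adult", np.arange(T), np.zeros(T, int), empty),
            recaptures=bf.RecaptureSummary.from_counts(50, 5, 40, 4),
        )
        res = bf.TagRecoveryModel(ds).fit(
            bf.MCMCSettings(3, 6000, 1000, 2, 500, seed=3)
        )
        for name in ("S_j", "S_a", "r_j", "r_a"):
            draws = res.draws(name)
            assert abs(draws.mean() - 0.5) < 0.03  # Uniform(0,1) prior mean
            assert abs(draws.std(ddof=1) - np.sqrt(1 / 12)) < 0.03


class TestSummaries:
    def test_degenerate_draws_zero_sd_cv(self, junco_fit):
        res = junco_fit
        saved = res.quantities
        try:
            res.quantities = {"p_j": np.full((3, 50), 0.25)}
            row = res.summary().loc["p.juv"]
            assert row["sd"] == 0.0 and row["cv"] == 0.0
        finally:
            res.quantities = saved

    def test_summary_layout(self, junco_fit):
        s = junco_fit.summary()
        assert list(s.columns) == ["mean", "sd", "q5", "q95", "cv", "sd_t", "rhat"]
        assert {"p.juv", "p.ad", "V", "Mj/Ma", "F"} <= set(s.index)
        # CV = SD/mean to within rounding
        np.testing.assert_allclose(s["cv"], s["sd"] / s["mean"], rtol=1e-12)
        # CRI bounds are the empirical 5%/95% pooled quantiles
        v = junco_fit.draws("V")
        assert s.loc["V", "q5"] == pytest.approx(np.quantile(v, 0.05))
        assert s.loc["V", "q95"] == pytest.approx(np.quantile(v, 0.95))

    def test_monte_carlo_error_shrinks_with_chain_length(self, junco_recaptures):
        """Ten-fold more retained draws shrink the MC error of the posterior
        mean by about sqrt(10)."""
        model = bf.TagRecoveryModel(bf.BandingDataset(recaptures=junco_recaptures))
        means = {10: [], 100: []}
        for mult in (10, 100):
            for seed in range(6):
                res = model.fit(
                    bf.MCMCSettings(1, 60 * mult, 30 * mult, 1, 25, seed=100 + seed)
                )
                means[mult].append(float(res.draws("V").mean()))
        sd_small = np.std(means[10], ddof=1)
        sd_large = np.std(means[100], ddof=1)
        ratio = sd_small / sd_large
        assert 1.5 < ratio < 7.0  # ~sqrt(10), wide band for 6 replicates


@pytest.fixture(scope="module")
def temporal_fit():
    cfg = SimConfig(n_replicates=1, n_years=6, seed=5)
    params = ReplicateParams(r_j=0.15, r_a=0.12, p_a=0.012, V=1.2)
    rng = np.random.default_rng(55)
    rep = simulate_dataset(params, cfg, rng)
    model = bf.TagRecoveryModel(rep.dataset, temporal=("S_a", "c_j"))
    return model.fit(bf.MCMCSettings(3, 5000, 1500, 4, 1200, seed=5))


class TestTemporalModel:
    def test_constant_truth_gives_small_annual_variation(self, temporal_fit):
        assert temporal_fit.sd_t("S_a") < 0.05
        assert temporal_fit.sd_t("S_a", method="hyper") < 0.5

    def test_lambda_identity_every_draw(self, temporal_fit):
        q = temporal_fit.quantities
        lam = q["lambda"]
        expect = q["S_a"] + q["F"] * q["S_j"][..., None]
        np.testing.assert_array_equal(lam, expect)

    def test_annual_summary_and_correlation(self, temporal_fit):
        ann = temporal_fit.annual_summary("F")
        assert len(ann) == 6
        r = temporal_fit.corr_lambda_F()
        assert -1.0 <= r <= 1.0

    def test_single_cohort_temporal_rejected(self, junco_recaptures):
        ds = bf.BandingDataset(recaptures=junco_recaptures)
        with pytest.raises(ValueError, match=">=2 cohorts|uncollapsed"):
            bf.TagRecoveryModel(ds, temporal=("S_a",))

    def test_collapsed_temporal_rejected(self, toy_marray):
        c = bf.collapse_marray(toy_marray)
        ds = bf.BandingDataset(adult=c)
        with pytest.raises(ValueError, match="uncollapsed"):
            bf.TagRecoveryModel(ds, temporal=("S_a",))


class TestMLE:
    def test_mle_close_to_truth_on_rich_data(self):
        cfg = SimConfig(n_replicates=1, n_years=10, seed=9)
        params = ReplicateParams(r_j=0.2, r_a=0.1, p_a=0.015, V=1.1)
        rng = np.random.default_rng(99)
        rep = simulate_dataset(params, cfg, rng)
        est = bf.TagRecoveryModel(rep.dataset).fit_mle()
        assert est["S_a"] == pytest.approx(0.6, abs=0.05)
        assert est["F"] == pytest.approx(0.8, abs=0.1)
        assert est["lambda"] == pytest.approx(1.0, abs=0.1)

    def test_temporal_mle_unsupported(self, toy_marray):
        ds = bf.BandingDataset(
            adult=toy_marray,
            juvenile=bf.MArray("juvenile", [1, 2, 3], [4, 4, 0], np.zeros((3, 3), int)),
        )
        with pytest.raises(ValueError, match="time-constant"):
            bf.TagRecoveryModel(ds, temporal=("S_a",)).fit_mle()
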