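"""Growth model: recursion oracles, likelihood identities, fit behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graylinggrowth as gg
from graylinggrowth.growth import (
    GrowthParams,
    baseline_lengths,
    growth_loglik,
    map_fit,
    marginal_effect,
    expected_length_series,
)
from graylinggrowth.mcmc import McmcSettings
from graylinggrowth.simulate import SyntheticTruth, generate_lengths


class TestRecursionOracle:
    """Hand-arithmetic checks of the expected-length equations."""

    def test_juvenile_baseline(self, published_params):
        # 347.61 * (1 - exp(-0.14 * (1 + 2.27)))
        expected = 347.61 * (1 - np.exp(-0.14 * 3.27))
        got = gg.juvenile_expected_length(published_params)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(127.7, abs=0.1)

    def test_increment_chain(self, published_params):
        mu1 = gg.juvenile_expected_length(published_params)
        mu2 = gg.update_expected_length(published_params, mu1, 2)
        mu3 = gg.update_expected_length(published_params, mu2, 3)
        # mu2 = mu1 + (347.61 - mu1) * (1 - exp(-0.14 * 4.27))
        assert mu2 == pytest.approx(mu1 + (347.61 - mu1) * (1 - np.exp(-0.14 * 4.27)))
        assert mu2 == pytest.approx(226.7, abs=0.1)
        assert mu3 == pytest.approx(289.8, abs=0.1)

    def test_literal_equation_variant_drops_carryover(self, published_params):
        mu1 = gg.juvenile_expected_length(published_params)
        lit = gg.update_expected_length(published_params, mu1, 2, literal_form=True)
        inc = gg.update_expected_length(published_params, mu1, 2)
        assert lit == pytest.approx(inc - mu1)

    def test_covariate_multiplier_doubles_juvenile_length(self, published_params):
        p = GrowthParams(
            linf=347.61, k=0.14, t0=-2.27, sigma=10, theta={1: [np.log(2.0)]}
        )
        base = gg.juvenile_expected_length(published_params)
        assert gg.juvenile_expected_length(p, np.array([1.0])) == pytest.approx(
            2 * base
        )

    def test_zero_covariates_reduce_to_plain_vb(self, published_params):
        p = GrowthParams(
            linf=347.61,
            k=0.14,
            t0=-2.27,
            sigma=10,
            theta={1: [0.5, -0.2], 2: [0.3], 3: [-0.4]},
        )
        x0 = np.zeros(2)
        assert gg.juvenile_expected_length(p, x0) == pytest.approx(
            gg.juvenile_expected_length(published_params)
        )

    def test_at_asymptote_increment_vanishes(self, published_params):
        linf = published_params.linf
        assert gg.update_expected_length(published_params, linf, 3) == pytest.approx(linf)

    def test_nonpositive_previous_length_rejected(self, published_params):
        with pytest.raises(ValueError, match="positive"):
            gg.update_expected_length(published_params, -5.0, 2)

    @settings(deadline=None, max_examples=40)
    @given(
        linf=st.floats(200, 600),
        k=st.floats(0.05, 0.6),
        t0=st.floats(-4.0, 0.5),
    )
    def test_chain_monotone_and_bounded_by_linf(self, linf, k, t0):
        p = GrowthParams(linf=linf, k=k, t0=t0, sigma=1.0)
        mus = baseline_lengths(p)
        assert np.all(np.diff(mus) > 0)
        assert np.all(mus < linf)
        # geometric approach: increments shrink toward the asymptote
        gaps = linf - mus
        assert np.all(np.diff(gaps) < 0)


class TestLoglik:
    def _params(self, small_study):
        base = baseline_lengths(GrowthParams(350, 0.15, -2, 1))
        sets = small_study["covariates"].stage_sets
        return GrowthParams(
            linf=350.0,
            k=0.15,
            t0=-2.0,
            sigma=15.0,
            theta={l: np.zeros(len(sets[l])) for l in (1, 2, 3)},
            mu_init=np.tile(base[1:], (3, 1)),
        )

    def test_total_equals_sum_of_pointwise(self, small_study):
        p = self._params(small_study)
        total, pointwise = growth_loglik(
            p, small_study["lengths"], small_study["covariates"]
        )
        assert total == pytest.approx(pointwise.sum(), abs=1e-9)
        assert len(pointwise) == len(small_study["lengths"])

    def test_record_at_its_mode_scores_normal_peak(self, small_study):
        p = self._params(small_study)
        data = small_study["lengths"].iloc[:1].copy()
        mu1 = gg.juvenile_expected_length(
            p,
            np.zeros(len(small_study["covariates"].stage_sets[1])),
        )
        data["age_class"] = 1
        data["fork_length_mm"] = mu1
        _, pw = growth_loglik(p, data, small_study["covariates"])
        assert pw[0] == pytest.approx(-0.5 * np.log(2 * np.pi * 15.0**2))

    def test_doubling_sigma_changes_terms_by_closed_form(self, small_study):
        p1 = self._params(small_study)
        p2 = self._params(small_study)
        p2.sigma = 2 * p1.sigma
        _, pw1 = growth_loglik(p1, small_study["lengths"], small_study["covariates"])
        _, pw2 = growth_loglik(p2, small_study["lengths"], small_study["covariates"])
        # lp(2s) = -log 2 - 0.5 log(2 pi s^2) - r^2/(8 s^2)
        resid_term = pw1 + 0.5 * np.log(2 * np.pi * p1.sigma**2)  # = -r^2 / (2 s^2)
        expected = -np.log(2.0) - 0.5 * np.log(2 * np.pi * p1.sigma**2) + resid_term / 4
        np.testing.assert_allclose(pw2, expected, atol=1e-10)

    def test_noise_free_map_recovers_expected_lengths(self, small_study):
        truth = SyntheticTruth(n_years=10, n_sites=3, total_lengths=900)
        truth.growth = GrowthParams(350.0, 0.15, -2.0, sigma=1e-9)
        truth.theta = {1: {}, 2: {}, 3: {}}  # plain VB recursion
        data = generate_lengths(truth, small_study["covariates"], seed=3)
        # a small fixed sigma sharpens the noise-free objective so the
        # optimiser resolves the (L_inf, K, t0) ridge to sub-0.1 mm
        fit = map_fit(
            data,
            small_study["covariates"],
            sigma_fixed=0.1,
        )
        mus_true = baseline_lengths(GrowthParams(350.0, 0.15, -2.0, 1.0))
        mus_fit = baseline_lengths(fit)
        np.testing.assert_allclose(mus_fit, mus_true, atol=0.1)


class TestFit:
    def test_posterior_covers_truth_and_converges(self, small_fit):
        s = small_fit.summary
        assert small_fit.converged
        assert s.loc["Linf", "lo95"] < 350 < s.loc["Linf", "hi95"]
        assert s.loc["K", "lo95"] < 0.15 < s.loc["K", "hi95"]
        assert s.loc["t0", "lo95"] < -2.0 < s.loc["t0", "hi95"]

    def test_pointwise_loglik_shape(self, small_fit, small_study):
        pw = small_fit.pointwise_loglik
        pooled = small_fit.pooled()
        assert pw.shape == (pooled.shape[0], len(small_study["lengths"]))
        assert np.all(np.isfinite(pw))

    def test_same_seed_is_deterministic(self, small_study):
        sett = McmcSettings(2, 1200, 600, 10, seed=99)
        p1 = gg.fit_growth(small_study["lengths"], small_study["covariates"], settings=sett)
        p2 = gg.fit_growth(small_study["lengths"], small_study["covariates"], settings=sett)
        np.testing.assert_array_equal(p1.draws, p2.draws)

    def test_age_class_out_of_range_rejected(self, small_study):
        bad = small_study["lengths"].copy()
        bad.loc[bad.index[0], "age_class"] = 7
        with pytest.raises(ValueError, match="1..6"):
            gg.fit_growth(bad, small_study["covariates"])

    def test_recapture_exclusion_drops_records(self, small_study):
        sett = McmcSettings(2, 1200, 600, 10, seed=99)
        post = gg.fit_growth(
            small_study["lengths"],
            small_study["covariates"],
            settings=sett,
            exclude_recaptures=True,
        )
        n_kept = int((~small_study["lengths"]["recapture"]).sum())
        assert post.pointwise_loglik.shape[1] == n_kept


class TestDerivedSummaries:
    def test_expected_length_series_shape_and_intervals(self, small_fit, small_study):
        series, trend = expected_length_series(small_fit)
        years = small_study["covariates"].years
        assert len(series) == len(years) * 6
        assert (series["lo95"] <= series["mean"]).all()
        assert (series["mean"] <= series["hi95"]).all()
        assert len(trend) == 6

    def test_marginal_effect_centre_matches_baseline(self, small_fit, small_study):
        table = small_study["covariates"]
        var = "meanT_SA"
        mean, _sd = table.scales[var]
        curve = marginal_effect(small_fit, table, var, stage=1, grid=np.array([mean]))
        linf = small_fit.param("Linf")
        kk = small_fit.param("K")
        tt0 = small_fit.param("t0")
        baseline = (linf * (1 - np.exp(-kk * (1 - tt0)))).mean()
        assert curve["mean"].iloc[0] == pytest.approx(baseline, rel=1e-9)

    def test_marginal_effect_plus_minus_one_sd_algebra(self, small_fit, small_study):
        table = small_study["covariates"]
        var = "meanT_SA"
        mean, sd = table.scales[var]
        grid = np.array([mean - sd, mean, mean + sd])
        curve = marginal_effect(small_fit, table, var, stage=1, grid=grid)
        th = small_fit.param(f"theta[1,{var}]")
        linf = small_fit.param("Linf")
        kk = small_fit.param("K")
        tt0 = small_fit.param("t0")
        per_draw_base = linf * (1 - np.exp(-kk * (1 - tt0)))
        np.testing.assert_allclose(
            curve["mean"].to_numpy(),
            [
                (per_draw_base * np.exp(-th)).mean(),
                per_draw_base.mean(),
                (per_draw_base * np.exp(th)).mean(),
            ],
            rtol=1e-9,
        )

    def test_negative_coefficient_gives_decreasing_curve(self, small_fit, small_study):
        table = small_study["covariates"]
        # truth: high-flow days depress juvenile growth
        var = "highflow_days"
        mean, sd = table.scales[var]
        grid = np.linspace(mean - 2 * sd, mean + 2 * sd, 7)
        curve = marginal_effect(small_fit, table, var, stage=1, grid=grid)
        assert np.all(np.diff(curve["mean"]) < 0)

    def test_unretained_variable_rejected(self, small_fit, small_study):
        with pytest.raises(ValueError, match="not retained"):
            marginal_effect(
                small_fit, small_study["covariates"], "meanT_AW", stage=1, grid=np.r_[5.0]
            )
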