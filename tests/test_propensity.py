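"""The twinning LPM, country rates, posterior draws and meta-analysis."""

import numpy as np
import pandas as pd
import pytest

import twinproj as tp
from twinproj.ages import AGE_GROUPS_5YR
from twinproj.propensity import AgeEffectPosterior, LpmFit, MetaResult

from helpers import brute_force_lpm, dl_pool


def test_lpm_matches_brute_force_oracle(deliveries_small):
    fit = tp.fit_lpm(deliveries_small)
    oracle = brute_force_lpm(deliveries_small)
    for c, v in oracle["country"].items():
        np.testing.assert_allclose(fit.country_effects[c], v, rtol=1e-10)
    for a, v in oracle["age"].items():
        np.testing.assert_allclose(fit.age_coefficients[a], v, rtol=1e-10, atol=1e-14)


def test_reference_category_is_zero(deliveries_small):
    fit = tp.fit_lpm(deliveries_small)
    assert fit.age_coefficients["15-19"] == 0.0


def test_fitted_mean_equals_sample_twin_fraction(deliveries_small):
    est = tp.TwinningPropensityLPM().fit(deliveries_small)
    fitted = est.predict(deliveries_small)
    assert np.mean(fitted) == pytest.approx(deliveries_small["twin"].mean(), abs=1e-12)


def test_null_age_effects_recovered_as_zero():
    params = tp.SynthParams(
        n_countries=2,
        mothers_per_country=15000,
        age_effects={a: 0.0 for a in AGE_GROUPS_5YR},
        seed=5,
    )
    dl = tp.collapse_to_deliveries(tp.generate_birth_histories(params))
    fit = tp.fit_lpm(dl)
    for a in AGE_GROUPS_5YR[1:]:
        se = np.sqrt(fit.coefficient_covariance.loc[f"age:{a}", f"age:{a}"])
        assert abs(fit.age_coefficients[a]) < 3 * se


def test_large_sample_recovers_truth(lpm_large, params_large):
    for a in AGE_GROUPS_5YR[1:]:
        se = np.sqrt(lpm_large.coefficient_covariance.loc[f"age:{a}", f"age:{a}"])
        assert abs(lpm_large.age_coefficients[a] - params_large.age_effects[a]) < 3 * se
    for c, base in params_large.country_baselines.items():
        se = np.sqrt(lpm_large.coefficient_covariance.loc[f"country:{c}", f"country:{c}"])
        assert abs(lpm_large.country_effects[c] - base) < 3 * se


def test_age_profile_peaks_in_late_thirties():
    # truth rises to 35-39 then declines; the estimated profile must peak there
    effects = {"15-19": 0.0, "20-24": 0.003, "25-29": 0.006, "30-34": 0.010,
               "35-39": 0.013, "40-44": 0.007, "45-49": 0.004}
    params = tp.SynthParams(
        n_countries=3, mothers_per_country=20000, age_effects=effects, seed=17
    )
    dl = tp.collapse_to_deliveries(tp.generate_birth_histories(params))
    fit = tp.fit_lpm(dl)
    assert fit.age_coefficients.idxmax() == "35-39"


def test_one_country_effect_equals_reference_cell_mean():
    params = tp.SynthParams(
        n_countries=1, mothers_per_country=5000,
        country_baselines={"AAA": 0.02},
        age_effects={a: 0.0 for a in AGE_GROUPS_5YR}, seed=2,
    )
    dl = tp.collapse_to_deliveries(tp.generate_birth_histories(params))
    fit = tp.fit_lpm(dl)
    ref_mean = dl.loc[dl["age_category"] == "15-19", "twin"].mean()
    # saturated one-way design: the intercept is exactly the reference mean
    assert fit.country_effects["AAA"] == pytest.approx(ref_mean, abs=1e-12)


def test_covariance_modes_run(deliveries_small):
    classical = tp.fit_lpm(deliveries_small, covariance="classical")
    cluster = tp.fit_lpm(deliveries_small, covariance="cluster")
    robust = tp.fit_lpm(deliveries_small, covariance="robust")
    # same point estimates under every covariance mode
    pd.testing.assert_series_equal(classical.age_coefficients, robust.age_coefficients)
    pd.testing.assert_series_equal(cluster.age_coefficients, robust.age_coefficients)
    assert not classical.coefficient_covariance.equals(robust.coefficient_covariance)


def test_year_effects_option_runs(deliveries_small):
    fit = tp.fit_lpm(deliveries_small, year_effects=True)
    assert any(name.startswith("period:") for name in fit.param_names)


def test_too_few_age_categories_raises():
    dl = pd.DataFrame(
        {"country": ["A"] * 10, "age_category": ["20-24"] * 10,
         "twin": [0] * 9 + [1], "mother_id": range(10)}
    )
    with pytest.raises(ValueError, match="age categories"):
        tp.fit_lpm(dl)


# -- country rates ------------------------------------------------------------

def test_country_rate_point_is_observed_fraction():
    dl = pd.DataFrame(
        {"country": ["A"] * 4000, "twin": [1] * 60 + [0] * 3940}
    )
    post = tp.fit_country_rates(dl, n_draws=100, seed=0)
    assert post.point["A"] == pytest.approx(0.015, abs=1e-15)
    assert post.per_1000()["A"] == pytest.approx(15.0, abs=1e-12)


def test_country_rates_match_observed_rates(deliveries_small):
    post = tp.fit_country_rates(deliveries_small, n_draws=10, seed=0)
    pd.testing.assert_series_equal(
        1000.0 * post.point,
        tp.twinning_rate_per_1000(deliveries_small),
        check_names=False,
    )


def test_zero_twin_country_degenerate():
    dl = pd.DataFrame({"country": ["A"] * 100, "twin": [0] * 100})
    post = tp.fit_country_rates(dl, n_draws=50, seed=1)
    assert post.point["A"] == 0.0
    assert (post.rate_draws("A") >= 0).all()  # truncated at consumption


def test_country_order_permutation_invariant(deliveries_small):
    shuffled = deliveries_small.sample(frac=1.0, random_state=3)
    a = tp.fit_country_rates(deliveries_small, n_draws=10, seed=0).point
    b = tp.fit_country_rates(shuffled, n_draws=10, seed=0).point
    pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


# -- posterior draws ----------------------------------------------------------

def test_draws_reproducible_and_centred(deliveries_small):
    fit = tp.fit_lpm(deliveries_small)
    a = tp.draw_posterior(fit, n_draws=200, seed=11)
    b = tp.draw_posterior(fit, n_draws=200, seed=11)
    pd.testing.assert_frame_equal(a.draws, b.draws)

    big = tp.draw_posterior(fit, n_draws=50000, seed=12)
    point = fit.point_vector()
    for name in fit.param_names:
        sd = np.sqrt(fit.coefficient_covariance.loc[name, name])
        mc_se = sd / np.sqrt(50000)
        # 4 MC SE: nine simultaneous comparisons, so a per-parameter 3 SE
        # band would reject a correct sampler ~2% of the time
        assert abs(big.draws[name].mean() - point[name]) < 4 * mc_se


def test_zero_covariance_draws_equal_point(deliveries_small):
    fit = tp.fit_lpm(deliveries_small)
    zero = LpmFit(
        age_scheme=fit.age_scheme,
        age_coefficients=fit.age_coefficients,
        country_effects=fit.country_effects,
        residual_variance=0.0,
        coefficient_covariance=fit.coefficient_covariance * 0.0,
        n_deliveries=fit.n_deliveries,
        reference_category=fit.reference_category,
    )
    post = tp.draw_posterior(zero, n_draws=20, seed=0)
    np.testing.assert_allclose(
        post.draws.to_numpy(), np.tile(fit.point_vector().to_numpy(), (20, 1)),
        atol=1e-12,
    )


def test_non_psd_covariance_repaired(deliveries_small, caplog):
    fit = tp.fit_lpm(deliveries_small)
    cov = fit.coefficient_covariance.copy()
    cov.iloc[0, 1] = cov.iloc[1, 0] = 10.0 * np.sqrt(cov.iloc[0, 0] * cov.iloc[1, 1])
    broken = LpmFit(
        age_scheme=fit.age_scheme,
        age_coefficients=fit.age_coefficients,
        country_effects=fit.country_effects,
        residual_variance=fit.residual_variance,
        coefficient_covariance=cov,
        n_deliveries=fit.n_deliveries,
        reference_category=fit.reference_category,
    )
    with caplog.at_level("WARNING"):
        post = tp.draw_posterior(broken, n_draws=10, seed=0)
    assert "repaired" in caplog.text
    assert np.isfinite(post.draws.to_numpy()).all()


def test_probability_draws_clip_only_at_consumption(deliveries_small):
    fit = tp.fit_lpm(deliveries_small)
    post = tp.draw_posterior(fit, n_draws=500, seed=4)
    raw = post.probability_draws("S00", clip=False)
    clipped = post.probability_draws("S00", clip=True)
    assert (clipped.to_numpy() >= 0).all() and (clipped.to_numpy() <= 1).all()
    # stored draws unchanged by clipping at consumption
    assert raw.shape == clipped.shape


# -- per-country fits and meta-analysis ---------------------------------------

def test_single_country_fit_matches_pooled(deliveries_small):
    one = deliveries_small[deliveries_small["country"] == "S01"]
    meta = tp.fit_per_country(one)
    fit = tp.fit_lpm(one)
    row = meta.per_country_coefficients.loc["S01"].dropna()
    for a, v in row.items():
        np.testing.assert_allclose(v, fit.age_coefficients[a], rtol=1e-10, atol=1e-14)


def test_identical_countries_identical_rows(deliveries_small):
    one = deliveries_small[deliveries_small["country"] == "S00"].copy()
    two = one.copy()
    two["country"] = "ZZZ"
    meta = tp.fit_per_country(pd.concat([one, two], ignore_index=True))
    pd.testing.assert_series_equal(
        meta.per_country_coefficients.loc["S00"],
        meta.per_country_coefficients.loc["ZZZ"],
        check_names=False,
    )


def test_per_country_recovers_heterogeneous_truth():
    params = tp.SynthParams(
        country_baselines={"LOW": 0.007, "HIGH": 0.026},
        mothers_per_country=25000,
        seed=21,
    )
    dl = tp.collapse_to_deliveries(tp.generate_birth_histories(params))
    meta = tp.fit_per_country(dl)
    for country in ("LOW", "HIGH"):
        for a in AGE_GROUPS_5YR[1:]:
            est = meta.per_country_coefficients.loc[country, a]
            se = meta.per_country_se.loc[country, a]
            assert abs(est - params.age_effects[a]) < 3 * se, (country, a)


def _toy_meta(effects_by_country, ses_by_country):
    cats = list(AGE_GROUPS_5YR)
    coefs = pd.DataFrame(effects_by_country).T.reindex(columns=cats)
    ses = pd.DataFrame(ses_by_country).T.reindex(columns=cats)
    return MetaResult(age_scheme="5-year", per_country_coefficients=coefs,
                      per_country_se=ses)


def test_meta_identical_estimates_zero_heterogeneity():
    eff = {c: {"15-19": 0.0, "35-39": 0.01} for c in "ABC"}
    se = {c: {"15-19": 0.0, "35-39": 0.002} for c in "ABC"}
    pooled = tp.meta_analyze(_toy_meta(eff, se)).pooled
    assert pooled.loc["35-39", "estimate"] == pytest.approx(0.01, abs=1e-14)
    assert pooled.loc["35-39", "tau2"] == pytest.approx(0.0, abs=1e-14)


def test_meta_equal_se_average():
    eff = {"A": {"15-19": 0.0, "35-39": 0.0}, "B": {"15-19": 0.0, "35-39": 0.02}}
    se = {c: {"15-19": 0.0, "35-39": 0.005} for c in "AB"}
    pooled = tp.meta_analyze(_toy_meta(eff, se)).pooled
    assert pooled.loc["35-39", "estimate"] == pytest.approx(0.01, abs=1e-12)


def test_meta_matches_hand_rolled_oracle():
    eff = {"A": {"15-19": 0.0, "35-39": 0.004}, "B": {"15-19": 0.0, "35-39": 0.013},
           "C": {"15-19": 0.0, "35-39": 0.009}}
    se = {"A": {"15-19": 0.0, "35-39": 0.001}, "B": {"15-19": 0.0, "35-39": 0.002},
          "C": {"15-19": 0.0, "35-39": 0.0015}}
    pooled = tp.meta_analyze(_toy_meta(eff, se)).pooled
    est, pse, tau2 = dl_pool([0.004, 0.013, 0.009], [0.001, 0.002, 0.0015])
    np.testing.assert_allclose(pooled.loc["35-39", "estimate"], est, rtol=1e-10)
    np.testing.assert_allclose(pooled.loc["35-39", "se"], pse, rtol=1e-10)
    np.testing.assert_allclose(pooled.loc["35-39", "tau2"], tau2, rtol=1e-10)


def test_meta_single_country_category_flagged():
    eff = {"A": {"15-19": 0.0, "35-39": 0.004, "40-44": 0.01},
           "B": {"15-19": 0.0, "35-39": 0.013, "40-44": np.nan}}
    se = {"A": {"15-19": 0.0, "35-39": 0.001, "40-44": 0.002},
          "B": {"15-19": 0.0, "35-39": 0.002, "40-44": np.nan}}
    pooled = tp.meta_analyze(_toy_meta(eff, se)).pooled
    assert bool(pooled.loc["40-44", "single_country"])
    assert pooled.loc["40-44", "estimate"] == pytest.approx(0.01)


def test_pooled_within_convex_hull_when_homogeneous():
    eff = {"A": {"15-19": 0.0, "35-39": 0.006}, "B": {"15-19": 0.0, "35-39": 0.012},
           "C": {"15-19": 0.0, "35-39": 0.009}}
    se = {c: {"15-19": 0.0, "35-39": 0.004} for c in "ABC"}
    pooled = tp.meta_analyze(_toy_meta(eff, se)).pooled
    assert 0.006 <= pooled.loc["35-39", "estimate"] <= 0.012
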