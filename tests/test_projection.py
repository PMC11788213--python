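"""Projection identities, scenarios, the sibling metric and decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twinproj as tp
from twinproj.ages import AGE_GROUPS_5YR
from twinproj.propensity import AgeEffectPosterior, CountryRatePosterior
from twinproj.projection import age_probabilities


def _uniform_shares():
    return pd.Series(1.0 / 7, index=AGE_GROUPS_5YR)


def _toy_posterior(gamma=0.010, beta=None, n_draws=50, gamma_sd=0.0, country="AAA"):
    """Degenerate (or jittered) posterior with known parameters."""
    rng = np.random.default_rng(0)
    beta = beta or {}
    cols = {f"country:{country}": gamma + rng.normal(0, gamma_sd, n_draws)}
    for a in AGE_GROUPS_5YR[1:]:
        cols[f"age:{a}"] = np.full(n_draws, float(beta.get(a, 0.0)))
    age_post = AgeEffectPosterior(
        draws=pd.DataFrame(cols), seed=0, n_draws=n_draws, reference_category="15-19"
    )
    shares = _uniform_shares()
    tr_point = float(sum(shares[a] * (gamma + beta.get(a, 0.0)) for a in AGE_GROUPS_5YR))
    rate_post = CountryRatePosterior(
        draws=pd.DataFrame({country: np.full(n_draws, tr_point)}),
        point=pd.Series({country: tr_point}),
    )
    return tp.PosteriorBundle(rate_post, age_post)


def _input(country="AAA", year=2010, births=1000.0, shares=None, women=None, asfr=None):
    return tp.ProjectionInput(
        country=country, year=year, births=births,
        age_shares=shares if shares is not None else _uniform_shares(),
        women=women, asfr=asfr,
    )


# -- elemental identities -------------------------------------------------------

def test_deliveries_from_births_no_twins():
    assert tp.deliveries_from_births(1000.0, 0.0) == pytest.approx(1000.0)


def test_deliveries_from_births_solves_identity():
    d = tp.deliveries_from_births(1015.0, 0.015)
    assert d == pytest.approx(1000.0, rel=1e-12)
    assert d + d * 0.015 == pytest.approx(1015.0, rel=1e-12)


def test_deliveries_from_births_rejects_bad_rate():
    with pytest.raises(ValueError):
        tp.deliveries_from_births(100.0, 1.0)
    with pytest.raises(ValueError):
        tp.deliveries_from_births(-1.0, 0.01)


def test_partition_uniform_and_degenerate():
    d_a = tp.partition_deliveries(700.0, np.full(7, 1 / 7))
    np.testing.assert_allclose(d_a, 100.0)
    one = np.zeros(7)
    one[3] = 1.0
    np.testing.assert_allclose(tp.partition_deliveries(42.0, one)[3], 42.0)


def test_partition_rejects_negative_share():
    s = np.full(7, 1 / 7)
    s[0] = -s[0]
    s[1] += 2 / 7
    with pytest.raises(ValueError):
        tp.partition_deliveries(10.0, s)


@given(st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=2, max_size=9),
       st.floats(min_value=0.0, max_value=1e7))
def test_partition_sums_exactly(weights, d):
    shares = np.asarray(weights) / np.sum(weights)
    shares = shares / shares.sum()  # force float-1 normalisation
    if abs(shares.sum() - 1.0) > 1e-9:
        return
    d_a = tp.partition_deliveries(d, shares)
    assert d_a.sum() == d
    assert (d_a >= -1e-9 * max(d, 1.0)).all()


def test_age_probabilities_raw_addition():
    bundle = _toy_posterior(gamma=0.010, beta={"35-39": 0.010})
    p = age_probabilities(bundle.age_effects, "AAA", mode="raw")
    assert np.allclose(p["35-39"], 0.020)
    assert np.allclose(p["15-19"], 0.010)


def test_age_probabilities_flat_betas_equal_gamma():
    bundle = _toy_posterior(gamma=0.015, gamma_sd=0.002)
    p = age_probabilities(bundle.age_effects, "AAA", mode="raw")
    gamma = bundle.age_effects.country_effect_draws("AAA")
    for a in AGE_GROUPS_5YR:
        np.testing.assert_allclose(p[a], np.clip(gamma, 0, 1))


def test_recentered_mode_closure():
    bundle = _toy_posterior(gamma=0.01, beta={"35-39": 0.01}, gamma_sd=0.003)
    tr = bundle.rate_draws("AAA")
    p = age_probabilities(
        bundle.age_effects, "AAA", mode="recentered",
        baseline_shares=_uniform_shares(), tr_draws=tr,
    )
    implied = p.to_numpy() @ _uniform_shares().to_numpy()
    np.testing.assert_allclose(implied, tr, rtol=1e-12)


def test_unknown_country_errors():
    bundle = _toy_posterior()
    with pytest.raises(KeyError):
        age_probabilities(bundle.age_effects, "ZZZ", mode="raw")


def test_expected_twins_uniform_probability_mixture_invariance():
    d_a = tp.partition_deliveries(1000.0, np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05]))
    dt, dt_a, tr = tp.expected_twin_deliveries(d_a, np.full(7, 0.02))
    assert tr == pytest.approx(0.02, rel=1e-12)


def test_expected_twins_older_shares_raise_rate():
    p = np.linspace(0.01, 0.02, 7)
    young = tp.partition_deliveries(1000.0, np.array([0.4, 0.3, 0.1, 0.1, 0.05, 0.03, 0.02]))
    old = tp.partition_deliveries(1000.0, np.array([0.02, 0.03, 0.05, 0.1, 0.1, 0.3, 0.4]))
    _, _, tr_young = tp.expected_twin_deliveries(young, p)
    _, _, tr_old = tp.expected_twin_deliveries(old, p)
    assert tr_old > tr_young


def test_expected_twins_zero_probability():
    dt, dt_a, tr = tp.expected_twin_deliveries(np.full(7, 10.0), np.zeros(7))
    assert dt == 0.0


def test_expected_twins_mismatched_groups_error():
    da = pd.DataFrame(np.ones((2, 7)), columns=list(AGE_GROUPS_5YR))
    pa = da.rename(columns={"45-49": "50-54"})
    with pytest.raises(ValueError, match="mismatch"):
        tp.expected_twin_deliveries(da, pa)


# -- percent change and the sibling metric ---------------------------------------

def test_pct_change_values():
    assert tp.pct_change(55.0, 50.0) == pytest.approx(10.0)
    assert tp.pct_change(50.0, 50.0) == 0.0
    with pytest.raises(ValueError):
        tp.pct_change(1.0, 0.0)


def test_median_of_changes_not_change_of_medians():
    base = np.array([1.0, 1.0, 100.0])
    scen = np.array([2.0, 1.0, 100.0])
    per_draw = np.median(tp.pct_change(scen, base))  # 0%
    of_medians = tp.pct_change(np.median(scen), np.median(base))  # +100%
    assert per_draw != of_medians
    assert per_draw == 0.0


def test_summary_reports_median_of_per_draw_changes():
    bundle = _toy_posterior(gamma=0.015, gamma_sd=0.004)
    res = tp.run_scenario(_input(), _input(year=2050, births=1100.0), bundle)
    assert res.summary().loc["pct_change_count", "median"] == pytest.approx(
        float(np.median(res.draws["pct_change_count"])), rel=1e-12
    )


@pytest.mark.parametrize("tr,lo,hi", [(0.0069, 72.0, 74.0), (0.5, 1.5, 1.5)])
def test_twin_sibling_ratio(tr, lo, hi):
    assert lo <= tp.twin_sibling_ratio(tr) <= hi


def test_twin_sibling_ratio_limit_and_domain(caplog):
    with caplog.at_level("WARNING"):
        assert tp.twin_sibling_ratio(0.0) == np.inf
    with pytest.raises(ValueError):
        tp.twin_sibling_ratio(1.5)


# -- scenarios --------------------------------------------------------------------

def test_identity_scenario_zero_change_every_draw():
    bundle = _toy_posterior(gamma=0.012, beta={"35-39": 0.008}, gamma_sd=0.002)
    res = tp.run_scenario(_input(), _input(year=2050), bundle)
    assert (res.draws["pct_change_rate"] == 0.0).all()
    assert (res.draws["pct_change_count"] == 0.0).all()


def test_doubled_births_fixed_shares():
    bundle = _toy_posterior(gamma=0.012, beta={"35-39": 0.008}, gamma_sd=0.002)
    res = tp.run_scenario(_input(), _input(year=2050, births=2000.0), bundle)
    np.testing.assert_allclose(res.draws["pct_change_count"], 100.0, rtol=1e-10)
    np.testing.assert_allclose(res.draws["pct_change_rate"], 0.0, atol=1e-10)


def test_scale_equivariance():
    bundle = _toy_posterior(gamma=0.012, beta={"35-39": 0.008}, gamma_sd=0.002)
    res1 = tp.run_scenario(_input(), _input(year=2050, births=1000.0), bundle)
    res3 = tp.run_scenario(_input(), _input(year=2050, births=3000.0), bundle)
    np.testing.assert_allclose(res3.draws["dt"], 3.0 * res1.draws["dt"], rtol=1e-12)
    np.testing.assert_allclose(res3.draws["d"], 3.0 * res1.draws["d"], rtol=1e-12)
    np.testing.assert_allclose(
        res3.draws["implied_tr"], res1.draws["implied_tr"], rtol=1e-12
    )


def test_birth_conservation_per_draw_at_baseline():
    bundle = _toy_posterior(gamma=0.018, beta={"30-34": 0.006, "35-39": 0.01},
                            gamma_sd=0.003)
    res = tp.run_scenario(_input(births=50000.0), _input(year=2050, births=60000.0), bundle)
    b = res.draws["d_baseline"] + res.draws["dt_baseline"]
    np.testing.assert_allclose(b, 50000.0, rtol=1e-6)


def test_older_shift_raises_rate_in_most_draws(lpm_large, deliveries_large, params_large):
    posterior = tp.draw_posterior(lpm_large, n_draws=400, seed=3)
    rates = tp.fit_country_rates(deliveries_large, n_draws=400, seed=4)
    bundle = tp.PosteriorBundle(rates, posterior)
    tab = tp.generate_projection_tables(params_large, [2010, 2100])
    base = tp.ProjectionInput.from_frame(tab, "S00", 2010)
    scn = tp.ProjectionInput.from_frame(tab, "S00", 2100)
    res = tp.run_scenario(base, scn, bundle)
    assert (res.draws["pct_change_rate"] > 0).mean() >= 0.95


def test_mismatched_countries_error():
    bundle = _toy_posterior()
    with pytest.raises(ValueError, match="countries"):
        tp.run_scenario(_input(country="AAA"), _input(country="BBB"), bundle)


def test_flags_select_baseline_components():
    bundle = _toy_posterior(gamma=0.012, beta={"35-39": 0.008}, gamma_sd=0.002)
    old = pd.Series([0.02, 0.03, 0.05, 0.1, 0.1, 0.3, 0.4], index=AGE_GROUPS_5YR)
    scn = _input(year=2100, births=2000.0, shares=old)
    res = tp.run_scenario(_input(), scn, bundle, use_scenario_shares=False)
    # only births change -> rate unchanged
    np.testing.assert_allclose(res.draws["pct_change_rate"], 0.0, atol=1e-10)
    res2 = tp.run_scenario(_input(), scn, bundle, use_scenario_births=False)
    np.testing.assert_allclose(res2.draws["pct_change_count"],
                               res2.draws["pct_change_rate"], rtol=1e-10)


# -- decomposition ----------------------------------------------------------------

def _wf_input(year, women, asfr):
    w = pd.Series(women, index=AGE_GROUPS_5YR, dtype=float)
    f = pd.Series(asfr, index=AGE_GROUPS_5YR, dtype=float)
    births = float((w * f).sum())
    shares = (w * f) / births
    return tp.ProjectionInput(country="AAA", year=year, births=births,
                              age_shares=shares, women=w, asfr=f)


W0 = [1000, 1000, 900, 800, 700, 600, 500]
F0 = [0.08, 0.15, 0.15, 0.12, 0.08, 0.03, 0.01]
W1 = [900, 950, 950, 900, 850, 700, 600]
F1 = [0.05, 0.12, 0.16, 0.15, 0.11, 0.05, 0.02]


def test_decomposition_identity_scenario_all_zero():
    bundle = _toy_posterior(gamma=0.012, beta={"35-39": 0.01}, gamma_sd=0.002)
    dec = tp.decompose_change(_wf_input(2010, W0, F0), _wf_input(2100, W0, F0), bundle)
    for result in dec.values():
        np.testing.assert_allclose(result.total, 0.0, atol=1e-15)
        for term in result.pure.values():
            np.testing.assert_allclose(term, 0.0, atol=1e-15)


def test_decomposition_single_factor_case():
    bundle = _toy_posterior(gamma=0.012, beta={"35-39": 0.01}, gamma_sd=0.002)
    dec = tp.decompose_change(_wf_input(2010, W0, F0), _wf_input(2100, W0, F1), bundle)
    rate = dec["rate"]
    np.testing.assert_allclose(rate.pure["composition"], 0.0, atol=1e-15)
    np.testing.assert_allclose(rate.pure["asfr"], rate.total, rtol=1e-12)
    np.testing.assert_allclose(rate.interaction, 0.0, atol=1e-12)


def test_decomposition_additivity_identities():
    bundle = _toy_posterior(gamma=0.012, beta={"30-34": 0.006, "35-39": 0.01},
                            gamma_sd=0.003)
    dec = tp.decompose_change(_wf_input(2010, W0, F0), _wf_input(2100, W1, F1), bundle)
    for result in dec.values():
        seq = sum(result.sequential.values())
        np.testing.assert_allclose(seq, result.total, rtol=1e-12, atol=1e-15)
        sym = sum(result.symmetrized.values())
        np.testing.assert_allclose(sym, result.total, rtol=1e-12, atol=1e-15)
        pure_plus = sum(result.pure.values()) + result.interaction
        np.testing.assert_allclose(pure_plus, result.total, rtol=1e-12, atol=1e-15)


def test_decomposition_two_group_hand_enumeration():
    # two effective age groups: all mass on 20-24 and 35-39
    w0 = [0, 1000, 0, 0, 1000, 0, 0]
    f0 = [0, 0.10, 0, 0, 0.05, 0, 0]
    w1 = [0, 800, 0, 0, 1400, 0, 0]
    f1 = [0, 0.08, 0, 0, 0.09, 0, 0]
    gamma, b3539 = 0.010, 0.010
    bundle = _toy_posterior(gamma=gamma, beta={"35-39": b3539}, n_draws=3)
    dec = tp.decompose_change(_wf_input(2010, w0, f0), _wf_input(2100, w1, f1), bundle,
                              mode="raw")

    def tr(w, f):
        births = w[1] * f[1] + w[4] * f[4]
        s_old = w[4] * f[4] / births
        return gamma + s_old * b3539

    base, full = tr(w0, f0), tr(w1, f1)
    asfr_only, comp_only = tr(w0, f1), tr(w1, f0)
    rate = dec["rate"]
    np.testing.assert_allclose(rate.total, full - base, rtol=1e-12)
    np.testing.assert_allclose(rate.pure["asfr"], asfr_only - base, rtol=1e-12)
    np.testing.assert_allclose(rate.pure["composition"], comp_only - base, rtol=1e-12)
    np.testing.assert_allclose(
        rate.interaction, (full - base) - (asfr_only - base) - (comp_only - base),
        rtol=1e-10,
    )


def test_decomposition_requires_women_and_asfr():
    bundle = _toy_posterior()
    with pytest.raises(ValueError, match="women/asfr"):
        tp.decompose_change(_input(), _input(year=2100), bundle)
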