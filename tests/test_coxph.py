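"""Cox partial-likelihood core and Nelson-Aalen estimator."""

import numpy as np
import pytest

import waistmi as wm
from waistmi.coxph import DegenerateModelError


def test_three_subject_closed_form_mle():
    """Two-event partial likelihood with exposure {1, 0, 1} has the
    closed-form root beta = -log(2)/2."""
    entry = np.zeros(3)
    exit_ = np.array([1.0, 2.0, 3.0])
    event = np.array([1, 1, 0])
    x = np.array([1.0, 0.0, 1.0])
    fit = wm.fit_cox(entry, exit_, event, x[:, None])
    assert fit.coef[0] == pytest.approx(-0.5 * np.log(2.0), abs=1e-8)
    assert fit.n_events == 2


def test_agrees_with_independent_implementations(complete_table):
    """Coefficients and SEs match lifelines (Efron; tie-free data) and
    statsmodels PHReg (Breslow) on a left-truncated fit."""
    from lifelines import CoxPHFitter
    from statsmodels.duration.hazard_regression import PHReg
    from waistmi.models import _analysis_design

    table = complete_table
    X, terms = _analysis_design(table, "a")
    fit = wm.fit_cox(
        table["entry_age"].to_numpy(),
        table["exit_age"].to_numpy(),
        table["event"].to_numpy(),
        X,
    )
    sm_fit = PHReg(
        table["exit_age"].to_numpy(),
        X,
        status=table["event"].to_numpy(),
        entry=table["entry_age"].to_numpy(),
        ties="breslow",
    ).fit()
    np.testing.assert_allclose(fit.coef, sm_fit.params, atol=1e-6)
    np.testing.assert_allclose(fit.se, sm_fit.bse, rtol=1e-5)

    df = table[["entry_age", "exit_age", "event"]].copy()
    for j, t in enumerate(terms):
        df[t] = X[:, j]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="exit_age", event_col="event", entry_col="entry_age")
    np.testing.assert_allclose(fit.coef, cph.params_[list(terms)], atol=1e-5)
    np.testing.assert_allclose(
        fit.se, cph.standard_errors_[list(terms)], rtol=1e-4
    )


def test_time_shift_invariance(complete_table):
    fit = wm.fit_model_a(complete_table)
    shifted = complete_table.copy()
    shifted["entry_age"] += 7.0
    shifted["exit_age"] += 7.0
    fit2 = wm.fit_model_a(shifted)
    assert fit2.target_loghr == pytest.approx(fit.target_loghr, abs=1e-8)
    assert fit2.se == pytest.approx(fit.se, rel=1e-8)


def test_per_10cm_is_pure_reparameterisation(complete_table):
    """Scaling waist by 10 scales the fitted coefficient by exactly 1/10."""
    fit = wm.fit_model_a(complete_table)
    scaled = complete_table.copy()
    scaled["wc1"] *= 10.0
    scaled["wc2"] *= 10.0
    fit2 = wm.fit_model_a(scaled)
    assert fit2.target_loghr == pytest.approx(fit.target_loghr / 10.0, rel=1e-6)


def test_degenerate_inputs_raise(complete_table):
    constant = complete_table.copy()
    constant["wc1"] = 90.0
    constant["wc2"] = 95.0
    constant["female"] = 1
    constant["cob"] = 0
    constant["education"] = 0
    with pytest.raises(DegenerateModelError):
        wm.fit_model_a(constant)
    few_events = complete_table[complete_table["event"] == 0].head(100)
    with pytest.raises(DegenerateModelError):
        wm.fit_model_a(few_events)


def test_wald_interval_definition(complete_table):
    fit = wm.fit_model_b(complete_table)
    assert fit.ci95[0] == pytest.approx(fit.target_loghr - 1.96 * fit.se)
    assert fit.ci95[1] == pytest.approx(fit.target_loghr + 1.96 * fit.se)
    assert fit.se > 0


def test_model_b_matches_model_a_when_hazard_depends_on_wc2_only():
    """No-confounding limit: if the cancer hazard is a function of wc2
    alone and wc2 is independent of the demographics, models (a) and (b)
    target the same per-10 cm log HR."""
    from dataclasses import replace

    cfg = wm.desk_profile(n=50_000)
    params = wm.default_exposure_params()
    flat = {k: 0.0 for k in params.coefficients_w1}
    exposure = wm.ExposureModelParams(
        intercept_w1=85.0,
        intercept_w2=87.0,
        coefficients_w1=flat,
        coefficients_w2=dict(flat),
        residual_cov=params.residual_cov,
    )
    loghr = float(np.log(1.5))
    events = replace(
        wm.default_event_params(1.5, profile="high_incidence"),
        cancer_coefficients={
            # wc1 coefficient equal to the per-cm change effect makes the
            # linear predictor collapse to (loghr/10) * wc2
            "wc1": loghr / 10.0,
            "female": 0.0, "age": 0.0,
            "education_secondary_trade": 0.0, "education_tertiary": 0.0,
            "cob_uk": 0.0, "cob_mediterranean": 0.0,
        },
    )
    table = wm.generate_covariates(n=50_000, seed=61)
    table = wm.simulate_waist(table, exposure, seed=62)
    table = wm.simulate_outcomes(table, events, seed=63)
    fit_a = wm.fit_model_a(table)
    fit_b = wm.fit_model_b(table)
    assert abs(fit_a.target_loghr - loghr) < 3 * fit_a.se
    assert abs(fit_b.target_loghr - loghr) < 3 * fit_b.se
    assert abs(fit_a.target_loghr - fit_b.target_loghr) < 3 * np.hypot(
        fit_a.se, fit_b.se
    )


def test_complete_case_estimate_drops_missing(complete_table):
    amputed = wm.impose_mcar(complete_table, 0.5, seed=71)
    cc = wm.complete_case_estimate(amputed, "a")
    direct = wm.fit_model_a(amputed[amputed["wc2"].notna()])
    assert cc.target_loghr == direct.target_loghr
    none_missing = wm.complete_case_estimate(complete_table, "a")
    assert none_missing.target_loghr == wm.fit_model_a(complete_table).target_loghr
    all_missing = complete_table.copy()
    all_missing["wc2"] = np.nan
    with pytest.raises(ValueError):
        wm.complete_case_estimate(all_missing, "a")


def test_mcar_complete_case_is_unbiased():
    """50% MCAR leaves the complete-case estimate within MC tolerance of
    the complete-data estimate, with a larger SE."""
    cfg = wm.desk_profile(n=40_000)
    table = wm.simulate_complete(cfg, np.random.SeedSequence(81))
    full = wm.fit_model_a(table)
    cc = wm.complete_case_estimate(wm.impose_mcar(table, 0.5, seed=82), "a")
    assert abs(cc.target_loghr - full.target_loghr) < 3 * cc.se
    assert cc.se > full.se


def test_nelson_aalen_hand_computed_increments():
    # common entry: H(1) = 1/3, H(3) = 1/3 + 1
    H = wm.nelson_aalen([0, 0, 0], [1.0, 2.0, 3.0], [1, 0, 1])
    np.testing.assert_allclose(H, [1 / 3, 1 / 3, 4 / 3])
    # late entry shrinks the risk set at t=3 to two subjects
    H = wm.nelson_aalen([0, 0, 0, 2.5], [1.0, 2.0, 3.0, 3.0], [1, 0, 1, 0])
    np.testing.assert_allclose(H, [1 / 3, 1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2])
    # no events at all
    H = wm.nelson_aalen([0, 0], [1.0, 2.0], [0, 0])
    np.testing.assert_allclose(H, 0.0)
    with pytest.raises(ValueError):
        wm.nelson_aalen([], [], [])


def test_nelson_aalen_matches_lifelines(complete_table):
    from lifelines import NelsonAalenFitter

    H = wm.nelson_aalen(
        complete_table["entry_age"].to_numpy(),
        complete_table["exit_age"].to_numpy(),
        complete_table["event"].to_numpy(),
    )
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(
        complete_table["exit_age"],
        event_observed=complete_table["event"],
        entry=complete_table["entry_age"],
    )
    expected = naf.cumulative_hazard_at_times(
        complete_table["exit_age"]
    ).to_numpy()
    np.testing.assert_allclose(H, expected, atol=1e-10)
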