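"""Survey-weighted logistic models: parameter recovery, weighting
equivariances, OR-per-IQR arithmetic, AUC behaviour, stepwise selection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from gpif import generate_population
from gpif.impute import finalize_completed
from gpif.outcome_models import (DataError, FitError, OutcomeModelSpec,
                                 FittedOutcomeModel, DesignRecipe,
                                 evaluate_auc, fit_logistic_irls,
                                 fit_outcome_model, or_per_iqr,
                                 select_terms_aic, weighted_quantile)
from gpif.synthpop import OutcomeTruth


def test_metabolic_mediators_refused_in_adjustment():
    spec = OutcomeModelSpec(outcome="diabetes",
                            adjustment=["age", "Y_hypertension"])
    with pytest.raises(DataError, match="mediator"):
        spec.validate()


def test_null_dgp_recovers_null_model(complete_data):
    """Outcome independent of everything: every slope within 3 SE of 0."""
    df = complete_data.copy()
    rng = np.random.default_rng(8)
    df["Y_diabetes"] = rng.binomial(1, 0.3, len(df)).astype(float)
    m = fit_outcome_model(df, OutcomeModelSpec(outcome="diabetes"))
    se = np.sqrt(np.diag(m.cov))
    assert (np.abs(m.params[1:]) < 3 * se[1:]).all()


def test_known_coefficients_recovered(big_complete_data, spec):
    """True exposure and age effects bracketed at n = 20 000."""
    m = fit_outcome_model(big_complete_data, OutcomeModelSpec(outcome="diabetes"))
    truth = spec.outcomes["diabetes"]
    se = np.sqrt(np.diag(m.cov))
    j_bmi = m.names.index("bmi")
    j_age = m.names.index("age")
    assert abs(m.params[j_bmi] - truth.exposure_coef) < 3 * se[j_bmi]
    assert abs(m.params[j_age] - truth.covariate_coefs["age_c"]) < 3 * se[j_age]
    # the OR-per-IQR interval brackets the DGP truth on the same scale
    res = or_per_iqr(m, big_complete_data)
    truth_or = np.exp(truth.exposure_coef * res.iqr)
    assert res.ci_low < truth_or < res.ci_high


def test_equal_weights_match_unweighted(complete_data):
    df = complete_data.copy()
    df["weight"] = 1.0
    spec_m = OutcomeModelSpec(outcome="hypertension")
    a = fit_outcome_model(df, spec_m, weight_col="weight")
    b = fit_outcome_model(df, spec_m, weight_col=None)
    np.testing.assert_allclose(a.params, b.params, rtol=1e-8)


def test_weight_rescaling_leaves_coefficients_unchanged(complete_data):
    spec_m = OutcomeModelSpec(outcome="hypertension")
    a = fit_outcome_model(complete_data, spec_m)
    df = complete_data.copy()
    df["weight"] = df["weight"] * 3.7
    b = fit_outcome_model(df, spec_m)
    np.testing.assert_allclose(a.params, b.params, rtol=1e-7)


def test_nonpositive_weights_rejected(complete_data):
    df = complete_data.copy()
    df.loc[df.index[0], "weight"] = 0.0
    with pytest.raises(DataError, match="positive"):
        fit_outcome_model(df, OutcomeModelSpec(outcome="diabetes"))


def test_irls_matches_statsmodels(complete_data):
    spec_m = OutcomeModelSpec(outcome="msk", exposure="wc")
    m = fit_outcome_model(complete_data, spec_m)
    X = m.recipe.build(complete_data)
    y = complete_data["Y_msk"].to_numpy(float)
    w = complete_data["weight"].to_numpy(float)
    beta = fit_logistic_irls(X, y, w)
    np.testing.assert_allclose(beta, m.params, atol=1e-8)


def _inject(beta, names, exposure="bmi"):
    recipe = DesignRecipe(exposure=exposure, adjustment=[], levels={})
    return FittedOutcomeModel(outcome="diabetes", recipe=recipe,
                              params=np.asarray(beta, float), names=names,
                              cov=np.diag([0.0] * len(beta)), aic=0.0, n=0,
                              weighted=True)


def test_or_per_iqr_closed_form():
    # uniform exposure on [0, 16]: IQR = 8 exactly under the weighted quantile
    x = np.linspace(0.0, 16.0, 4001)
    df = pd.DataFrame({"bmi": x, "weight": np.ones_like(x)})
    model = _inject([-3.0, 0.05], ["intercept", "bmi"])
    res = or_per_iqr(model, df)
    assert res.iqr == pytest.approx(8.0, abs=1e-2)
    assert res.odds_ratio == pytest.approx(np.exp(0.05 * res.iqr), rel=1e-12)
    # null effect
    res0 = or_per_iqr(_inject([-3.0, 0.0], ["intercept", "bmi"]), df)
    assert res0.odds_ratio == 1.0
    # doubling the IQR squares the OR
    df2 = pd.DataFrame({"bmi": 2 * x, "weight": np.ones_like(x)})
    res2 = or_per_iqr(model, df2)
    assert res2.odds_ratio == pytest.approx(res.odds_ratio ** 2, rel=1e-6)


def test_or_per_iqr_degenerate_exposure():
    df = pd.DataFrame({"bmi": np.full(50, 25.0), "weight": np.ones(50)})
    with pytest.raises(DataError, match="IQR"):
        or_per_iqr(_inject([0.0, 0.1], ["intercept", "bmi"]), df)


def test_weighted_quantile_reduces_to_numpy():
    x = np.random.default_rng(0).normal(size=5001)
    q = weighted_quantile(x, [0.25, 0.5, 0.75], np.ones_like(x))
    np.testing.assert_allclose(q, np.quantile(x, [0.25, 0.5, 0.75]), atol=1e-3)


def test_model_json_round_trip_bitwise(complete_data, tmp_path):
    spec_m = OutcomeModelSpec(outcome="cvd", exposure="wc")
    m = fit_outcome_model(complete_data, spec_m)
    path = tmp_path / "model.json"
    m.to_json(path)
    m2 = FittedOutcomeModel.from_json(str(path))
    p1 = m.predict_risk(complete_data)
    p2 = m2.predict_risk(complete_data)
    assert (p1 == p2).all()


def test_auc_near_perfect_for_steep_monotone_risk(complete_data):
    df = complete_data.copy()
    rng = np.random.default_rng(5)
    p = 1 / (1 + np.exp(-8.0 * (df["bmi"].to_numpy() - 26.0)))
    df["Y_diabetes"] = rng.binomial(1, p).astype(float)
    spec_m = OutcomeModelSpec(outcome="diabetes", adjustment=[])
    auc = evaluate_auc(df, spec_m, seed=1)
    assert auc > 0.97


def test_auc_chance_level_for_independent_outcome(spec):
    ds = generate_population(spec.complete(), 10_000, seed=404)
    df = finalize_completed(ds)
    rng = np.random.default_rng(6)
    df["Y_diabetes"] = rng.binomial(1, 0.3, len(df)).astype(float)
    auc = evaluate_auc(df, OutcomeModelSpec(outcome="diabetes"), seed=2)
    assert abs(auc - 0.5) < 0.03


def test_auc_single_class_split_rejected(complete_data):
    df = complete_data.copy()
    df["Y_diabetes"] = 0.0
    with pytest.raises(DataError, match="single"):
        evaluate_auc(df, OutcomeModelSpec(outcome="diabetes"), seed=0)


def test_stepwise_empty_candidates_noop(complete_data):
    spec_m = OutcomeModelSpec(outcome="diabetes")
    assert select_terms_aic(complete_data, spec_m) == []


def _with_outcome(spec, df, truth, rng):
    from gpif.synthpop import covariate_frame, linear_predictor
    enc = covariate_frame(df)
    p = 1 / (1 + np.exp(-linear_predictor(truth, df["bmi"].to_numpy(), enc)))
    out = df.copy()
    out["Y_diabetes"] = rng.binomial(1, p).astype(float)
    return out


def test_stepwise_detects_strong_interaction(spec):
    """A large true exposure-by-sex interaction is selected nearly always.

    Scaled-down selection-power simulation: 12 replicates at n = 6 000 with
    a strong interaction; require selection in >= 10 of 12.
    """
    truth = OutcomeTruth(exposure="bmi", intercept=-4.4, exposure_coef=0.05,
                         covariate_coefs={"age_c": 0.02},
                         interaction_coefs={"female": 0.08})
    hits = 0
    for r in range(12):
        ds = generate_population(spec.complete(), 6_000, seed=700 + r)
        df = _with_outcome(spec, finalize_completed(ds), truth,
                           np.random.default_rng(900 + r))
        sel = select_terms_aic(df, OutcomeModelSpec(
            outcome="diabetes", candidate_interactions=["sex", "road_noise"]))
        hits += "interaction:sex" in sel
    assert hits >= 10


def test_stepwise_rarely_admits_spurious_terms(spec):
    """With no true interaction/curvature, AIC keeps the main-effects model
    in the majority of replicates (two candidates; each spurious candidate
    enters with probability ~0.16 under the AIC=2 penalty)."""
    truth = OutcomeTruth(exposure="bmi", intercept=-4.4, exposure_coef=0.05,
                         covariate_coefs={"age_c": 0.02})
    empty = 0
    for r in range(12):
        ds = generate_population(spec.complete(), 4_000, seed=800 + r)
        df = _with_outcome(spec, finalize_completed(ds), truth,
                           np.random.default_rng(1000 + r))
        sel = select_terms_aic(df, OutcomeModelSpec(
            outcome="diabetes", candidate_quadratic=True,
            candidate_interactions=["road_noise"]))
        empty += (sel == [])
    assert empty >= 7


def test_selection_refit_is_deterministic(complete_data):
    spec_m = OutcomeModelSpec(outcome="diabetes", selection="aic",
                              candidate_quadratic=True,
                              candidate_interactions=["sex"])
    a = fit_outcome_model(complete_data, spec_m)
    b = fit_outcome_model(complete_data, spec_m)
    np.testing.assert_array_equal(a.params, b.params)
    assert a.selected_terms == b.selected_terms
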