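"""Chained random-forest imputation: observed-value preservation, donor
closure, seed-stream independence, MCAR mean recovery, chain diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gpif import generate_population
from gpif.impute import (CompletedDatasets, ImputationConfig,
                         UnimputableVariableError, chain_converged,
                         finalize_completed, rf_mice_impute)
from gpif.synthpop import ConfigurationError

FAST = dict(n_iterations=4, n_trees=10, seed=5)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ImputationConfig(m=0).validate()
    with pytest.raises(ConfigurationError, match="diagonal"):
        ImputationConfig(predictor_matrix={"income": ["income", "age"]}).validate()


def test_no_missing_values_returns_identical_copies(spec):
    ds = generate_population(spec.complete(), 400, seed=9)
    out = rf_mice_impute(ds, ImputationConfig(m=3, **FAST))
    assert out.m == 3
    assert out.chain_trace.empty
    for d in out.datasets:
        pd.testing.assert_frame_equal(d, ds)


def test_observed_cells_preserved_bit_exactly(survey):
    out = rf_mice_impute(survey, ImputationConfig(m=2, **FAST))
    for col in ("income", "alcohol", "weight_meas", "height_meas", "wc_meas"):
        obs = survey[col].notna()
        for d in out.datasets:
            assert (d.loc[obs, col].to_numpy() ==
                    survey.loc[obs, col].to_numpy()).all()
            assert d[col].notna().all()


def test_imputed_categorical_and_binary_values_are_observed_levels(spec):
    spec2 = dataclasses.replace(spec, missingness={
        "smoking": {"base": -2.0}, "road_noise": {"base": -2.2}})
    ds = generate_population(spec2, 1_500, seed=31)
    assert ds["smoking"].isna().any() and ds["road_noise"].isna().any()
    out = rf_mice_impute(ds, ImputationConfig(m=2, **FAST))
    for d in out.datasets:
        assert d["smoking"].notna().all()
        assert set(d["smoking"].unique()) <= set(ds["smoking"].cat.categories)
        assert set(d["road_noise"].unique()) <= {0.0, 1.0}


def test_record_count_and_order_preserved(survey):
    out = rf_mice_impute(survey, ImputationConfig(m=2, **FAST))
    for d in out.datasets:
        assert len(d) == len(survey)
        assert (d["id"].to_numpy() == survey["id"].to_numpy()).all()


def test_per_imputation_streams_independent_of_m(survey):
    """Completed dataset k is identical whether m = k or larger."""
    a = rf_mice_impute(survey, ImputationConfig(m=1, **FAST))
    b = rf_mice_impute(survey, ImputationConfig(m=3, **FAST))
    pd.testing.assert_frame_equal(a.datasets[0], b.datasets[0])


def test_deterministic_given_seed(survey):
    a = rf_mice_impute(survey, ImputationConfig(m=1, **FAST))
    b = rf_mice_impute(survey, ImputationConfig(m=1, **FAST))
    pd.testing.assert_frame_equal(a.datasets[0], b.datasets[0])


def test_mcar_mean_recovered_within_pooled_se(spec):
    """MCAR missingness on a continuous covariate: pooled imputed mean within
    3 pooled SEs of the complete-data mean (n = 5 000)."""
    spec2 = dataclasses.replace(spec, missingness={})
    ds = generate_population(spec2, 5_000, seed=55)
    full_mean = ds["alcohol"].mean()
    amp = ds.copy()
    rng = np.random.default_rng(66)
    mis = rng.random(len(amp)) < 0.15
    amp.loc[mis, "alcohol"] = np.nan
    out = rf_mice_impute(amp, ImputationConfig(m=5, n_iterations=6, n_trees=15,
                                               seed=7))
    means = [d["alcohol"].mean() for d in out.datasets]
    n = len(amp)
    within = np.mean([d["alcohol"].var(ddof=1) / n for d in out.datasets])
    between = np.var(means, ddof=1)
    pooled_se = np.sqrt(within + (1 + 1 / 5) * between)
    assert abs(np.mean(means) - full_mean) < 3 * pooled_se


def test_unimputable_variable_raises(survey):
    bad = survey.copy()
    bad["income"] = np.nan
    with pytest.raises(UnimputableVariableError, match="income"):
        rf_mice_impute(bad, ImputationConfig(m=1, **FAST))


def test_chain_trace_shape_and_derived_bmi(survey):
    cfg = ImputationConfig(m=2, **FAST)
    out = rf_mice_impute(survey, cfg)
    tr = out.chain_trace
    n_targets = tr["variable"].nunique()
    assert len(tr) == n_targets * cfg.m * cfg.n_iterations
    for d in out.datasets:
        fin = finalize_completed(d)
        derived = fin["weight_meas"] / (fin["height_meas"] / 100.0) ** 2
        np.testing.assert_allclose(fin["bmi"], derived, rtol=1e-12)


def _trace(means, sd=1.0):
    rows = [("x", 0, i, m, sd) for i, m in enumerate(means)]
    return pd.DataFrame(rows, columns=["variable", "imputation", "iteration",
                                       "mean", "sd"])


def test_constant_chain_converges_with_zero_slope():
    ok, summ = chain_converged(_trace([3.0] * 12), window=10)
    assert ok
    assert summ["slope"].abs().max() == 0.0


def test_monotone_drift_flagged_as_nonconverged():
    ok, _ = chain_converged(_trace(np.linspace(0, 30, 12), sd=1.0), window=10)
    assert not ok


def test_window_larger_than_iterations_rejected():
    with pytest.raises(ValueError, match="window"):
        chain_converged(_trace([1.0, 2.0, 1.5]), window=10)


def test_default_run_chains_converge(spec):
    ds = generate_population(spec, 6_000, seed=21)
    out = rf_mice_impute(ds, ImputationConfig(m=3, n_iterations=15, n_trees=15,
                                              seed=5))
    ok, _ = chain_converged(out.chain_trace, window=10)
    assert ok


def test_completed_write_round_trip(tmp_path, survey):
    out = rf_mice_impute(survey, ImputationConfig(m=2, **FAST))
    paths = out.write(tmp_path)
    assert len(paths) == 2
    back = pd.read_csv(paths[0])
    assert back["income"].notna().all()
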