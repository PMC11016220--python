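"""G-computation estimator: exact null, frozen toy oracle, bootstrap
arithmetic and consistency, oracle equivalence on complete data."""

import numpy as np
import pytest

from gpif import (OutcomeModelSpec, bootstrap_pif, bootstrap_pifs,
                  estimate_pif, generate_population, true_pif)
from gpif.impute import finalize_completed
from gpif.outcome_models import DataError
from gpif.scenarios import builtin_scenario, identity_scenario

# hand enumeration over the 4-person fixture: risks expit(-3 + 0.1 BMI) at
# BMI {20, 26, 30, 35} vs {20, 25, 29, 34} after the one-unit reduction
TOY_PIF = 0.04045406371091531
TOY_RD = -0.018130632414436132


def test_identity_scenario_gives_exact_zero(complete_data):
    for outcome, expo in (("diabetes", "bmi"), ("msk", "wc")):
        est = estimate_pif(complete_data,
                           OutcomeModelSpec(outcome=outcome, exposure=expo),
                           identity_scenario(exposure=expo), seed=0)
        assert est.pif == 0.0
        assert est.rd == 0.0


def test_toy_fixture_matches_hand_enumeration(toy_frame, toy_model):
    est = estimate_pif(toy_frame, OutcomeModelSpec(outcome="diabetes",
                                                   adjustment=[]),
                       builtin_scenario("s2", "bmi>25"), seed=0,
                       model=toy_model)
    assert est.pif == pytest.approx(TOY_PIF, abs=1e-12)
    assert est.rd == pytest.approx(TOY_RD, abs=1e-12)
    # independent in-test enumeration of the same 8 expit terms
    risks_f = 1 / (1 + np.exp(-(-3 + 0.1 * np.array([20, 26, 30, 35.0]))))
    risks_cf = 1 / (1 + np.exp(-(-3 + 0.1 * np.array([20, 25, 29, 34.0]))))
    assert est.pif == pytest.approx(1 - risks_cf.mean() / risks_f.mean(),
                                    abs=1e-15)


def test_exposure_mismatch_rejected(complete_data):
    with pytest.raises(DataError, match="exposure"):
        estimate_pif(complete_data, OutcomeModelSpec(outcome="diabetes"),
                     builtin_scenario("s4"), seed=0)


def test_point_estimate_matches_oracle_on_complete_data(big_complete_data, spec):
    """Plug-in PIF within 3 combined SEs of the oracle at n = 20 000."""
    scen = builtin_scenario("s2", "bmi>25")
    est = bootstrap_pif(big_complete_data, OutcomeModelSpec(outcome="diabetes"),
                        scen, n_boot=120, seed=5)
    oracle = true_pif(spec, scen, "diabetes", n_mc=200_000, seed=17)
    z = (est.pif - oracle.pif) / np.hypot(est.se_pif, oracle.mc_se)
    assert abs(z) < 3


def test_two_replicate_bootstrap_se_arithmetic(complete_data):
    res = bootstrap_pifs(complete_data, [OutcomeModelSpec(outcome="diabetes")],
                         [builtin_scenario("s2", "bmi>25")], n_boot=2, seed=3,
                         keep_replicates=True)
    est = res[("diabetes", "s2@bmi>25")]
    p1, p2 = est.replicates[:, 0]
    assert est.se_pif == pytest.approx(abs(p1 - p2) / np.sqrt(2), rel=1e-12)


def test_doubling_n_boot_is_stable(complete_data):
    spec_m = OutcomeModelSpec(outcome="hypertension")
    scen = builtin_scenario("s2", "bmi>25")
    a = bootstrap_pif(complete_data, spec_m, scen, n_boot=150, seed=21)
    b = bootstrap_pif(complete_data, spec_m, scen, n_boot=300, seed=21)
    assert a.pif == b.pif   # point estimate is the full-data estimate
    assert abs(b.se_pif - a.se_pif) / a.se_pif < 0.10


def test_bootstrap_se_consistent_with_sampling_variability(spec):
    """Mean bootstrap SE tracks the empirical SD of the point estimator over
    fresh surveys (scaled-down consistency simulation)."""
    scen = builtin_scenario("s2", "bmi>25")
    spec_m = OutcomeModelSpec(outcome="hypertension")
    points, boot_ses = [], []
    for r in range(40):
        ds = generate_population(spec.complete(), 1_200, seed=4000 + r)
        dd = finalize_completed(ds)
        if r < 12:   # bootstrap SEs are costlier; a subset suffices
            est = bootstrap_pif(dd, spec_m, scen, n_boot=150, seed=r)
            boot_ses.append(est.se_pif)
            points.append(est.pif)
        else:
            points.append(estimate_pif(dd, spec_m, scen, seed=r).pif)
    ratio = np.mean(boot_ses) / np.std(points, ddof=1)
    assert 0.8 < ratio < 1.25


def test_n_boot_lower_bound():
    with pytest.raises(ValueError):
        bootstrap_pifs(None, [], [], n_boot=1, seed=0)


def test_shared_fit_bootstrap_matches_single(complete_data):
    """The multi-combination bootstrap equals the single-pair call."""
    spec_m = OutcomeModelSpec(outcome="diabetes")
    scen2 = builtin_scenario("s2", "bmi>25")
    scen3 = builtin_scenario("s3", "bmi>25")
    joint = bootstrap_pifs(complete_data, [spec_m], [scen2, scen3],
                           n_boot=60, seed=8)
    single = bootstrap_pifs(complete_data, [spec_m], [scen2],
                            n_boot=60, seed=8)
    a = joint[("diabetes", "s2@bmi>25")]
    b = single[("diabetes", "s2@bmi>25")]
    assert a.pif == b.pif
    assert a.se_pif == pytest.approx(b.se_pif, rel=1e-12)
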