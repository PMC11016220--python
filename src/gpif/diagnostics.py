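"""Positivity diagnostics, residual conditional SDs, and the estimator
validation harness (bias / RMSE / coverage against the known-truth oracle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import gcomp, scenarios as sc
from .impute import ImputationConfig, finalize_completed, rf_mice_impute
from .outcome_models import OutcomeModelSpec, DataError
from .pool import rubin_pool
from .synthpop import (ADJUSTMENT_COVARIATES, CATEGORICAL_LEVELS,
                       PopulationSpec, generate_population, true_pif)

__all__ = ["OverlapReport", "positivity_overlap", "conditional_sd",
           "run_simulation_study", "SimulationStudyError"]


class SimulationStudyError(RuntimeError):
    """Too many simulation replicates failed."""


def _covariate_design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Intercept + main effects, categoricals dummy-coded (first level ref)."""
    cols = [np.ones(len(df))]
    for v in covariates:
        if v in CATEGORICAL_LEVELS:
            codes = pd.Categorical(df[v], categories=CATEGORICAL_LEVELS[v]).codes
            if (codes < 0).any():
                raise DataError(f"covariate {v!r} has missing/unknown values")
            for j in range(1, len(CATEGORICAL_LEVELS[v])):
                cols.append((codes == j).astype(float))
        else:
            x = df[v].to_numpy(float)
            if np.isnan(x).any():
                raise DataError(f"covariate {v!r} has missing values")
            cols.append(x)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# positivity


@dataclass
class OverlapReport:
    """Overlap of predicted exposure-class membership between groups.

    ``overlap`` is the integrated minimum of the two 50-bin histogram
    densities of the predicted probability of belonging to the exposed
    class, a value in [0, 1] and symmetric in the group labels.
    """

    overlap: float
    positivity_plausible: bool
    summary: pd.DataFrame      # per-group quantiles of the predicted probability
    threshold: float


def positivity_overlap(df: pd.DataFrame, confounders: Optional[Sequence[str]] = None,
                       exposure_class_rule: Optional[Callable] = None,
                       weight_col: Optional[str] = "weight",
                       n_bins: int = 50, threshold: float = 0.2) -> OverlapReport:
    """Check the experimental-treatment-assignment (positivity) assumption.

    Fits a main-effects logistic model for membership in the exposed class
    (default: overweight, BMI > 25) on the confounders, predicts the
    membership probability separately within the exposed and reference
    groups, and reports the histogram overlap coefficient of the two
    distributions.  Values near zero flag structural non-overlap.
    """
    if confounders is None:
        confounders = [c for c in ADJUSTMENT_COVARIATES]
    if exposure_class_rule is None:
        exposure_class_rule = lambda d: d["bmi"].to_numpy(float) > 25.0
    cls = np.asarray(exposure_class_rule(df), bool)
    if cls.all() or not cls.any():
        raise DataError("both exposure classes must be non-empty")

    X = _covariate_design(df, confounders)
    w = (df[weight_col].to_numpy(float) if weight_col is not None
         else np.ones(len(df)))
    res = sm.GLM(cls.astype(float), X, family=sm.families.Binomial(),
                 var_weights=w).fit(maxiter=200)
    p = np.asarray(res.predict(X), float)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h1, _ = np.histogram(p[cls], bins=edges, weights=w[cls], density=True)
    h0, _ = np.histogram(p[~cls], bins=edges, weights=w[~cls], density=True)
    overlap = float(np.minimum(h1, h0).sum() * (1.0 / n_bins))

    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    summary = pd.DataFrame({
        "quantile": qs,
        "exposed": np.quantile(p[cls], qs),
        "reference": np.quantile(p[~cls], qs),
    })
    return OverlapReport(overlap=overlap,
                         positivity_plausible=overlap >= threshold,
                         summary=summary, threshold=threshold)


# ---------------------------------------------------------------------------
# residual conditional SD


def conditional_sd(df: pd.DataFrame, variable: str,
                   covariates: Optional[Sequence[str]] = None,
                   weight_col: Optional[str] = "weight") -> float:
    """Weighted residual SD of ``variable`` given the covariates.

    Linear (weighted least squares) regression; aliased columns are dropped
    with a warning.  Reported in the units of the variable.
    """
    if covariates is None:
        covariates = [c for c in ADJUSTMENT_COVARIATES]
    X = _covariate_design(df, covariates)
    y = df[variable].to_numpy(float)
    w = (df[weight_col].to_numpy(float) if weight_col is not None
         else np.ones(len(df)))

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(f"design for {variable!r} is rank deficient "
                      f"({rank}/{X.shape[1]}); aliased columns dropped",
                      RuntimeWarning, stacklevel=2)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    return float(np.sqrt(np.sum(w * resid ** 2) / np.sum(w) * n / max(1, n - rank)))


# ---------------------------------------------------------------------------
# simulation study


def run_simulation_study(spec: PopulationSpec,
                         scenario_list: Sequence[sc.ScenarioDefinition],
                         outcomes: Sequence[str], n: int, replicates: int,
                         n_boot: int, seed: int, impute: bool = False,
                         imputation_config: Optional[ImputationConfig] = None,
                         n_mc_oracle: int = 200_000,
                         max_fail_fraction: float = 0.05) -> pd.DataFrame:
    """Bias, RMSE, empirical/bootstrap SE and 95% CI coverage of the PIF
    estimator against the known-truth oracle.

    Repeats generate -> (optionally impute) -> estimate -> pool over
    ``replicates`` fresh surveys of size ``n``.  Without imputation the
    complete-data variant of the generating process is used (full
    examination arm, no item nonresponse) and the CI is the normal
    bootstrap interval; with imputation the Rubin-pooled interval is used.
    Fully deterministic given ``seed``.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    model_specs = {o: OutcomeModelSpec(outcome=o, exposure=spec.outcomes[o].exposure)
                   for o in outcomes}
    pairs = [(o, s) for o in outcomes for s in scenario_list
             if s.exposure == spec.outcomes[o].exposure or s.id == "identity"]
    if not pairs:
        raise ValueError("no compatible scenario/outcome pair")

    ss = np.random.SeedSequence([int(seed), 0x51D])
    oracle_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    truths = {}
    for o, s in pairs:
        scn = s if s.exposure == spec.outcomes[o].exposure else None
        if scn is None:   # identity paired across exposures
            truths[(o, s.key)] = 0.0
        else:
            truths[(o, s.key)] = true_pif(spec, scn, o, n_mc=n_mc_oracle,
                                          seed=oracle_seed).pif

    gen_spec = spec if impute else spec.complete()
    rep_seeds = ss.spawn(replicates)
    rows: dict[tuple, list] = {k: [] for k in truths}
    n_failed = 0
    for r in range(replicates):
        child = rep_seeds[r]
        s_int = int(child.generate_state(1)[0] % (2 ** 31))
        try:
            ds = generate_population(gen_spec, n, seed=s_int, mode="survey")
            if impute:
                cfg = imputation_config or ImputationConfig(m=5, n_iterations=10,
                                                            n_trees=25)
                import dataclasses
                cfg = dataclasses.replace(cfg, seed=s_int)
                completed = [finalize_completed(d)
                             for d in rf_mice_impute(ds, cfg).datasets]
            else:
                completed = [finalize_completed(ds)]

            per_imp: dict[tuple, list] = {k: [] for k in truths}
            for i, dd in enumerate(completed):
                res = gcomp.bootstrap_pifs(
                    dd, list(model_specs.values()),
                    list({s.key: s for _, s in pairs}.values()),
                    n_boot=n_boot, seed=s_int + i)
                for (o, skey), est in res.items():
                    if (o, skey) in per_imp:
                        per_imp[(o, skey)].append(est)
            for key, ests in per_imp.items():
                if not ests:
                    continue
                if len(ests) == 1:
                    e = ests[0]
                    se = e.se_pif if e.se_pif is not None else 0.0
                    lo, hi = e.pif - 1.96 * se, e.pif + 1.96 * se
                    rows[key].append((e.pif, se, lo, hi))
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pooled = rubin_pool([e.pif for e in ests],
                                            [(e.se_pif or 0.0) ** 2 for e in ests])
                    rows[key].append((pooled.point, pooled.se,
                                      pooled.ci_low, pooled.ci_high))
        except Exception:
            n_failed += 1

    if n_failed > max_fail_fraction * replicates:
        raise SimulationStudyError(
            f"{n_failed}/{replicates} simulation replicates failed")

    out = []
    for (o, skey), lst in rows.items():
        if not lst:
            continue
        arr = np.asarray(lst, float)
        truth = truths[(o, skey)]
        est = arr[:, 0]
        cover = np.mean((arr[:, 2] <= truth) & (truth <= arr[:, 3]))
        out.append({
            "outcome": o, "scenario": skey, "truth": truth,
            "n_replicates": len(lst),
            "bias": float(est.mean() - truth),
            "rmse": float(np.sqrt(np.mean((est - truth) ** 2))),
            "empirical_se": float(est.std(ddof=1)) if len(est) > 1 else np.nan,
            "mean_boot_se": float(np.nanmean(arr[:, 1])),
            "coverage": float(cover),
            "n_failed": n_failed,
        })
    return pd.DataFrame(out)
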