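"""Potential impact fractions by g-computation with bootstrap uncertainty.

The estimator is the standard plug-in: fit the outcome model, predict every
record's risk at its factual exposure and at the scenario's counterfactual
exposure with all other covariates held fixed, take survey-weighted means
of both, and report ``PIF = 1 - P_cf / P_obs`` and ``RD = P_cf - P_obs``.
Because the factual denominator is the model-standardised prevalence, the
null (identity) scenario gives PIF = 0 exactly.

Standard errors come from a nonparametric bootstrap: records are resampled
with replacement carrying their weights, the outcome model is refit in
every replicate, and the scenario (including fresh distribution-shift
draws from the replicate's own reference pool) is re-applied.  Replicates
for several scenario/outcome combinations share one model refit per
outcome, which is what makes 200-1000 replicates practical on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import scenarios as sc
from .outcome_models import (FittedOutcomeModel, OutcomeModelSpec, DataError,
                             fit_logistic_irls, fit_outcome_model)
from .synthpop import EstimandError

__all__ = ["PIFEstimate", "estimate_pif", "bootstrap_pif", "bootstrap_pifs",
           "BootstrapError"]


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed."""


@dataclass
class PIFEstimate:
    """PIF and risk difference of one scenario x outcome x target."""

    scenario: str          # scenario key, e.g. "s2@bmi>25"
    outcome: str
    p_obs: float           # model-standardised factual prevalence (fraction)
    p_cf: float            # counterfactual prevalence (fraction)
    rd: float              # p_cf - p_obs
    pif: float             # 1 - p_cf / p_obs
    se_pif: Optional[float] = None
    se_rd: Optional[float] = None
    se_p_obs: Optional[float] = None
    n_boot: int = 0
    n_dropped: int = 0
    seed: Optional[int] = None
    replicates: Optional[np.ndarray] = None   # (pif, rd, p_obs) per replicate

    def ci(self, z: float = 1.96) -> tuple[float, float]:
        if self.se_pif is None:
            raise ValueError("no bootstrap SE available")
        return (self.pif - z * self.se_pif, self.pif + z * self.se_pif)


def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _point_from_predictions(risk_f: np.ndarray, risk_cf: np.ndarray,
                            w: np.ndarray) -> tuple[float, float, float, float]:
    p_obs = _weighted_mean(risk_f, w)
    p_cf = _weighted_mean(risk_cf, w)
    if p_obs == 0.0:
        raise EstimandError("model-standardised factual prevalence is zero")
    return p_obs, p_cf, p_cf - p_obs, 1.0 - p_cf / p_obs


def estimate_pif(df: pd.DataFrame, model_spec: OutcomeModelSpec,
                 scenario: sc.ScenarioDefinition, seed: int = 0,
                 weight_col: Optional[str] = "weight",
                 model: Optional[FittedOutcomeModel] = None) -> PIFEstimate:
    """Point PIF on one completed dataset (no bootstrap).

    ``model`` injects a pre-specified risk model, bypassing fitting —
    useful for closed-form checks.  ``seed`` only feeds the
    distribution-shift draws.
    """
    if model is None:
        model = fit_outcome_model(df, model_spec, weight_col=weight_col)
    if model.exposure != scenario.exposure:
        raise DataError(f"model exposure {model.exposure!r} does not match "
                        f"scenario exposure {scenario.exposure!r}")
    cf, _ = sc.apply_scenario(df, scenario, seed=seed, weight_col=weight_col)
    x = df[model.exposure].to_numpy(float)
    risk_f = model.predict_risk(df, exposure_values=x)
    risk_cf = model.predict_risk(df, exposure_values=cf.to_numpy(float))
    w = (df[weight_col].to_numpy(float) if weight_col is not None
         else np.ones(len(df)))
    p_obs, p_cf, rd, pif = _point_from_predictions(risk_f, risk_cf, w)
    return PIFEstimate(scenario=scenario.key, outcome=model_spec.outcome,
                       p_obs=p_obs, p_cf=p_cf, rd=rd, pif=pif, seed=seed)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class _OutcomePlan:
    spec: OutcomeModelSpec
    model: FittedOutcomeModel
    X: np.ndarray              # full-data design
    y: np.ndarray
    x: np.ndarray              # exposure values
    inter_z: list[np.ndarray]  # covariate columns interacting with exposure
    inter_idx: list[int]       # their coefficient indices
    quad_idx: Optional[int]
    exp_idx: int


def _make_plan(df: pd.DataFrame, spec: OutcomeModelSpec,
               weight_col: Optional[str]) -> _OutcomePlan:
    model = fit_outcome_model(df, spec, weight_col=weight_col)
    recipe = model.recipe
    X = recipe.build(df)
    from .outcome_models import _response
    y = _response(df, spec.outcome)
    x = df[recipe.exposure].to_numpy(float)
    names = model.names
    exp_idx = names.index(recipe.exposure)
    quad_idx = names.index(f"{recipe.exposure}^2") if recipe.quadratic else None
    inter_z, inter_idx = [], []
    for v in recipe.interactions:
        if v in recipe.levels:
            codes = pd.Categorical(df[v], categories=recipe.levels[v]).codes
            for j in range(1, len(recipe.levels[v])):
                inter_idx.append(names.index(f"{recipe.exposure}:{v}[{recipe.levels[v][j]}]"))
                inter_z.append((codes == j).astype(float))
        else:
            inter_idx.append(names.index(f"{recipe.exposure}:{v}"))
            inter_z.append(df[v].to_numpy(float))
    return _OutcomePlan(spec=spec, model=model, X=X, y=y, x=x,
                        inter_z=inter_z, inter_idx=inter_idx,
                        quad_idx=quad_idx, exp_idx=exp_idx)


def _eta_shift(plan: _OutcomePlan, beta: np.ndarray, rows: np.ndarray,
               x_cf: np.ndarray) -> np.ndarray:
    """eta_cf - eta_f for resampled rows, exploiting the design structure."""
    x = plan.x[rows]
    shift = beta[plan.exp_idx] * (x_cf - x)
    if plan.quad_idx is not None:
        shift = shift + beta[plan.quad_idx] * (x_cf ** 2 - x ** 2)
    for z, j in zip(plan.inter_z, plan.inter_idx):
        shift = shift + beta[j] * z[rows] * (x_cf - x)
    return shift


def _expit(v):
    return 1.0 / (1.0 + np.exp(-v))


def bootstrap_pifs(df: pd.DataFrame, model_specs: Sequence[OutcomeModelSpec],
                   scenario_list: Sequence[sc.ScenarioDefinition],
                   n_boot: int = 1000, seed: int = 0,
                   weight_col: Optional[str] = "weight",
                   max_drop_fraction: float = 0.10,
                   keep_replicates: bool = False,
                   ) -> dict[tuple[str, str], PIFEstimate]:
    """Joint bootstrap over all compatible scenario x outcome pairs.

    Each replicate resamples records once, refits each outcome model once
    (Newton refit warm-started at the full-data coefficients) and re-applies
    every scenario, so uncertainty is coherent across combinations.
    Replicates where an outcome degenerates to a single class are dropped
    for that outcome; more than ``max_drop_fraction`` dropped raises
    :class:`BootstrapError`.  Returns a dict keyed by
    ``(outcome, scenario.key)``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    n = len(df)
    w_full = (df[weight_col].to_numpy(float) if weight_col is not None
              else np.ones(n))
    bmi = df["bmi"].to_numpy(float) if "bmi" in df.columns else None
    height = df["height"].to_numpy(float) if "height" in df.columns else None

    plans = [_make_plan(df, spec, weight_col) for spec in model_specs]
    pairs = [(pi, s) for pi, plan in enumerate(plans) for s in scenario_list
             if s.exposure == plan.spec.exposure]
    if not pairs:
        raise DataError("no scenario/outcome pair with matching exposure")

    root = np.random.SeedSequence([int(seed), 0xB007])
    rep_seeds = root.spawn(n_boot)
    point_seed = int(root.generate_state(1)[0] % (2 ** 31))

    # point estimates on the full data (one seeded draw for s1)
    results: dict[tuple[str, str], PIFEstimate] = {}
    reps: dict[tuple[str, str], list[tuple[float, float, float]]] = {}
    for pi, s in pairs:
        plan = plans[pi]
        cf, _ = sc.apply_scenario(df, s, seed=point_seed, weight_col=weight_col)
        risk_f = _expit(plan.X @ plan.model.params)
        rows = np.arange(n)
        risk_cf = _expit(plan.X @ plan.model.params
                         + _eta_shift(plan, plan.model.params, rows,
                                      cf.to_numpy(float)))
        p_obs, p_cf, rd, pif = _point_from_predictions(risk_f, risk_cf, w_full)
        results[(plan.spec.outcome, s.key)] = PIFEstimate(
            scenario=s.key, outcome=plan.spec.outcome, p_obs=p_obs, p_cf=p_cf,
            rd=rd, pif=pif, n_boot=n_boot, seed=seed)
        reps[(plan.spec.outcome, s.key)] = []

    dropped = {pi: 0 for pi, _ in enumerate(plans)}
    for b in range(n_boot):
        rng = np.random.default_rng(rep_seeds[b])
        rows = rng.integers(0, n, n)
        w = w_full[rows]
        bmi_b = bmi[rows] if bmi is not None else None
        height_b = height[rows] if height is not None else None

        betas = {}
        for pi, plan in enumerate(plans):
            yb = plan.y[rows]
            if yb.min() == yb.max():
                betas[pi] = None
                dropped[pi] += 1
                continue
            betas[pi] = fit_logistic_irls(plan.X[rows], yb, w,
                                          start=plan.model.params, ridge=1e-8)

        df_b = None
        for pi, s in pairs:
            plan = plans[pi]
            beta = betas[pi]
            if beta is None:
                continue
            x_b = plan.x[rows]
            if s.target is not None or s.transform is not None:
                if df_b is None:
                    df_b = df.iloc[rows].reset_index(drop=True)
                cf_series, _mask = sc.apply_scenario(
                    df_b, s, seed=int(rng.integers(0, 2 ** 31)),
                    exposure_col=plan.model.exposure, weight_col=weight_col)
                cf_b = cf_series.to_numpy(float)
            else:
                cf_b, _mask = _apply_resampled(s, plan, rows, x_b, bmi_b,
                                               height_b, w, rng)
            eta_f = plan.X[rows] @ beta
            risk_f = _expit(eta_f)
            risk_cf = _expit(eta_f + _eta_shift(plan, beta, rows, cf_b))
            try:
                p_obs, p_cf, rd, pif = _point_from_predictions(risk_f, risk_cf, w)
            except EstimandError:
                continue
            reps[(plan.spec.outcome, s.key)].append((pif, rd, p_obs))

    for pi, plan in enumerate(plans):
        if dropped[pi] > max_drop_fraction * n_boot:
            raise BootstrapError(
                f"{dropped[pi]}/{n_boot} bootstrap replicates dropped for "
                f"outcome {plan.spec.outcome!r} (single-class resamples)")

    for key, lst in reps.items():
        arr = np.asarray(lst, float)
        est = results[key]
        est.n_dropped = n_boot - len(lst)
        if len(lst) >= 2:
            est.se_pif = float(np.std(arr[:, 0], ddof=1))
            est.se_rd = float(np.std(arr[:, 1], ddof=1))
            est.se_p_obs = float(np.std(arr[:, 2], ddof=1))
        if keep_replicates:
            est.replicates = arr
    return results


def _apply_resampled(s: sc.ScenarioDefinition, plan: _OutcomePlan,
                     rows: np.ndarray, x_b: np.ndarray,
                     bmi_b: Optional[np.ndarray],
                     height_b: Optional[np.ndarray], w: np.ndarray,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Scenario application on resampled arrays (fresh s1 draws)."""
    cf = x_b.copy()
    base_bmi = bmi_b if bmi_b is not None else (x_b if s.exposure == "bmi" else None)
    if s.id == "identity":
        return cf, np.zeros(len(x_b), bool)
    if s.id == "s4":
        if height_b is None:
            raise DataError("scenario s4 needs a 'height' column")
        mask = x_b / height_b > 0.5
        cf[mask] = height_b[mask] / 2.0
        return cf, mask
    if base_bmi is None:
        raise DataError("BMI-targeted scenario needs a 'bmi' column")
    thr = 25.0 if s.target_variant == "bmi>25" else 30.0
    mask = base_bmi > thr
    if s.id == "s2":
        cf[mask] = x_b[mask] - 1.0
    elif s.id == "s3":
        cf[mask] = 0.9 * x_b[mask]
    elif s.id == "s1":
        pool = (base_bmi >= sc.NORMAL_BMI_LO) & (base_bmi < sc.NORMAL_BMI_HI)
        if not pool.any():
            raise sc.ScenarioError("empty normal-BMI reference pool in replicate")
        wp = w[pool]
        cf[mask] = rng.choice(base_bmi[pool], size=int(mask.sum()),
                              replace=True, p=wp / wp.sum())
    else:
        raise sc.ScenarioError(f"unsupported scenario {s.id!r} in bootstrap")
    return cf, mask


def bootstrap_pif(df: pd.DataFrame, model_spec: OutcomeModelSpec,
                  scenario: sc.ScenarioDefinition, n_boot: int = 1000,
                  seed: int = 0, weight_col: Optional[str] = "weight",
                  ) -> PIFEstimate:
    """Bootstrap PIF for one scenario x outcome; see :func:`bootstrap_pifs`."""
    res = bootstrap_pifs(df, [model_spec], [scenario], n_boot=n_boot,
                         seed=seed, weight_col=weight_col)
    return res[(model_spec.outcome, scenario.key)]
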