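"""Counterfactual weight-reduction intervention scenarios.

Four built-in interventions, applied to a completed (no missing values)
person-level table:

``s1``  distribution shift — each person in the target has their BMI
        redrawn from the survey-weighted empirical distribution of people
        with normal BMI (18.5 <= BMI < 25);
``s2``  one-unit BMI reduction in the target;
``s3``  10% weight loss, i.e. BMI_cf = 0.9 x BMI (BMI is proportional to
        weight at fixed height);
``s4``  waist circumference reduced to half the height among everyone with
        WC/height > 0.5.

Targets for s1-s3 are either all people with overweight (BMI > 25) or with
obesity (BMI > 30); s4 has the single WC:height target.  Records outside
the target always keep their factual exposure exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioDefinition", "ScenarioError", "builtin_scenario",
    "identity_scenario", "apply_scenario", "mean_exposure_reduction",
    "BUILTIN_IDS", "TARGET_VARIANTS",
]

BUILTIN_IDS = ("s1", "s2", "s3", "s4")
TARGET_VARIANTS = ("bmi>25", "bmi>30")

NORMAL_BMI_LO = 18.5
NORMAL_BMI_HI = 25.0


class ScenarioError(ValueError):
    """Scenario is infeasible or misconfigured on the given data."""


@dataclass(frozen=True)
class ScenarioDefinition:
    """A named counterfactual intervention: target predicate + transform.

    ``target`` and ``transform`` allow custom scenarios: ``target`` maps a
    DataFrame to a boolean mask; ``transform`` maps (factual exposure array,
    DataFrame, rng) to counterfactual exposure values for target rows.
    Built-ins are created by :func:`builtin_scenario`.
    """

    id: str
    exposure: str                        # "bmi" | "wc"
    target_variant: str = "bmi>25"       # for s1-s3; s4 ignores it
    stochastic: bool = False
    label: str = ""
    target: Optional[Callable] = field(default=None, compare=False)
    transform: Optional[Callable] = field(default=None, compare=False)

    @property
    def key(self) -> str:
        if self.id == "s4":
            return "s4"
        return f"{self.id}@{self.target_variant}"


def builtin_scenario(scenario_id: str, target_variant: str = "bmi>25") -> ScenarioDefinition:
    """One of the four built-in interventions with a target variant."""
    if scenario_id == "identity":
        return identity_scenario()
    if scenario_id not in BUILTIN_IDS:
        raise ScenarioError(f"unknown scenario id {scenario_id!r}")
    if scenario_id == "s4":
        return ScenarioDefinition(id="s4", exposure="wc", target_variant="wc:height>0.5",
                                  label="WC to half of height (WC:height > 0.5)")
    if target_variant not in TARGET_VARIANTS:
        raise ScenarioError(f"unknown target variant {target_variant!r}")
    labels = {"s1": "shift to normal-BMI distribution",
              "s2": "one-unit BMI reduction",
              "s3": "10% weight loss"}
    return ScenarioDefinition(id=scenario_id, exposure="bmi",
                              target_variant=target_variant,
                              stochastic=(scenario_id == "s1"),
                              label=labels[scenario_id])


def identity_scenario(exposure: str = "bmi") -> ScenarioDefinition:
    """The null intervention: nobody is targeted, nothing changes."""
    return ScenarioDefinition(id="identity", exposure=exposure,
                              target_variant="none", label="no intervention")


def _target_mask(df: pd.DataFrame, scenario: ScenarioDefinition,
                 expo: np.ndarray, bmi: np.ndarray,
                 height: np.ndarray) -> np.ndarray:
    if scenario.target is not None:
        return np.asarray(scenario.target(df), bool)
    if scenario.id == "identity":
        return np.zeros(len(df), bool)
    if scenario.id == "s4":
        return expo / height > 0.5
    thr = 25.0 if scenario.target_variant == "bmi>25" else 30.0
    return bmi > thr


def apply_scenario(df: pd.DataFrame, scenario: ScenarioDefinition, seed: int,
                   exposure_col: Optional[str] = None, bmi_col: str = "bmi",
                   height_col: str = "height", weight_col: Optional[str] = "weight",
                   ) -> tuple[pd.Series, np.ndarray]:
    """Counterfactual exposure column and target mask for one scenario.

    Non-target records keep their factual exposure bit-identically.  The
    distribution-shift draws are deterministic given ``seed`` and use the
    survey-weighted empirical reference pool (``weight_col=None`` means
    equal weights, as in the oracle's superpopulation).
    """
    if exposure_col is None:
        exposure_col = "bmi" if scenario.exposure == "bmi" else "wc"
    expo = df[exposure_col].to_numpy(float)
    if np.isnan(expo).any():
        raise ScenarioError(f"{exposure_col} contains missing values; "
                            "scenarios require completed data")
    bmi = df[bmi_col].to_numpy(float) if bmi_col in df.columns else expo
    if scenario.id == "s4":
        height = df[height_col].to_numpy(float)
    else:
        height = np.full(len(df), np.nan)

    mask = _target_mask(df, scenario, expo, bmi, height)
    cf = expo.copy()

    if scenario.transform is not None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5CE4]))
        cf[mask] = np.asarray(scenario.transform(expo[mask], df.loc[mask], rng), float)
    elif scenario.id == "identity":
        pass
    elif scenario.id == "s2":
        cf[mask] = expo[mask] - 1.0
    elif scenario.id == "s3":
        cf[mask] = 0.9 * expo[mask]
    elif scenario.id == "s4":
        cf[mask] = height[mask] / 2.0
    elif scenario.id == "s1":
        pool = (bmi >= NORMAL_BMI_LO) & (bmi < NORMAL_BMI_HI)
        if not pool.any():
            raise ScenarioError("empty normal-BMI reference pool for the "
                                "distribution-shift scenario")
        pool_vals = bmi[pool]
        if weight_col is not None:
            w = df[weight_col].to_numpy(float)[pool]
            p = w / w.sum()
        else:
            p = None
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5CE4]))
        cf[mask] = rng.choice(pool_vals, size=int(mask.sum()), replace=True, p=p)
    else:
        raise ScenarioError(f"unknown scenario id {scenario.id!r}")

    return pd.Series(cf, index=df.index, name=f"{exposure_col}_cf"), mask


def mean_exposure_reduction(df: pd.DataFrame, scenario: ScenarioDefinition,
                            seed: int, basis: str = "target",
                            weight_col: Optional[str] = "weight",
                            **apply_kwargs) -> float:
    """Survey-weighted mean of (factual - counterfactual) exposure.

    ``basis="target"`` (default) averages over the target population, which
    makes the one-unit-reduction scenario equal exactly 1; ``basis="all"``
    averages over everyone (non-targets contribute zero reduction).
    """
    if basis not in ("target", "all"):
        raise ValueError(f"unknown averaging basis {basis!r}")
    cf, mask = apply_scenario(df, scenario, seed, weight_col=weight_col, **apply_kwargs)
    exposure_col = cf.name.rsplit("_cf", 1)[0]
    expo = df[exposure_col].to_numpy(float)
    diff = expo - cf.to_numpy(float)
    w = (df[weight_col].to_numpy(float) if weight_col is not None
         else np.ones(len(df)))
    if basis == "target":
        if not mask.any():
            warnings.warn("empty target population; mean reduction reported as 0",
                          RuntimeWarning, stacklevel=2)
            return 0.0
        return float(np.average(diff[mask], weights=w[mask]))
    if w.sum() == 0:
        raise ScenarioError("all weights are zero")
    return float(np.average(diff, weights=w))
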