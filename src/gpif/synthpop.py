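"""Synthetic health-interview-survey generator with a known-truth PIF oracle.

The generator emulates the structure of a merged interview + examination
survey: a fully observed self-report layer (height/weight), a small
examination arm carrying measured anthropometry (height, weight, waist
circumference), socio-demographic and lifestyle covariates, three
environmental exposures, four binary chronic-disease outcomes generated from
known logistic models, and a two-stage survey design with unequal weights.

Because every piece of the data-generating process is parametric and known,
the module can also compute the *true* potential impact fraction of any
intervention scenario by Monte-Carlo integration over the superpopulation —
the oracle against which the g-computation estimator is validated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SelfReportModel",
    "AnthropometryModel",
    "OutcomeTruth",
    "DesignSpec",
    "PopulationSpec",
    "OraclePIF",
    "default_spec",
    "generate_population",
    "true_pif",
    "linear_predictor",
    "covariate_frame",
    "write_dataset",
    "read_dataset",
    "make_codebook",
    "ConfigurationError",
    "EstimandError",
    "CATEGORICAL_LEVELS",
    "OUTCOMES",
]

OUTCOMES = ("diabetes", "hypertension", "cvd", "msk")

CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "year": ["2008", "2013", "2018"],
    "region": ["flanders", "wallonia", "brussels"],
    "sex": ["male", "female"],
    "education": ["primary", "lower_secondary", "upper_secondary", "higher"],
    "household": ["single", "single_parent", "couple", "couple_children", "other"],
    "smoking": ["never", "former", "occasional", "daily"],
    "physical_activity": ["active", "light", "sedentary"],
}

#: covariates entering outcome / adjustment models, in codebook order
ADJUSTMENT_COVARIATES = [
    "age", "sex", "education", "income", "household", "smoking",
    "indoor_smoking", "alcohol", "physical_activity",
    "black_carbon", "vegetation", "road_noise", "region", "year",
]


class ConfigurationError(ValueError):
    """A population/imputation/pipeline configuration field is invalid."""


class EstimandError(ValueError):
    """The requested estimand is undefined (e.g. zero factual prevalence)."""


@dataclass
class SelfReportModel:
    """Additive bias + noise mapping true to self-reported anthropometry.

    Defaults encode the usual survey pattern: weight under-reported,
    height over-reported.
    """

    weight_bias: float = -2.0   # kg, mean(self - true)
    weight_sd: float = 2.0      # kg
    height_bias: float = 1.0    # cm
    height_sd: float = 1.5      # cm


@dataclass
class AnthropometryModel:
    """Conditional models for true BMI, height, weight and waist circumference.

    True BMI is normal around a covariate-linear mean with residual SD
    ``bmi_sd``; weight is *derived* as BMI x (height/100)^2 so the
    weight-height-BMI identity holds exactly.  WC is linear in BMI, so its
    SD given covariates only is sqrt((wc_slope*bmi_sd)^2 + wc_sd^2).
    """

    bmi_intercept: float = 25.52
    bmi_coefs: dict[str, float] = field(default_factory=lambda: {
        "age_c": 0.10, "female": -0.6, "education_num": -0.45,
        "alcohol": 0.18, "sedentary": 0.5, "active": -0.3,
        "former_smoker": 0.35, "daily_smoker": -0.25,
        "black_carbon": 0.15, "vegetation": -0.8, "road_noise": 0.1,
    })
    bmi_sd: float = 5.3          # conditional SD of BMI given covariates
    height_male: float = 178.0
    height_female: float = 164.5
    height_age_slope: float = -0.06
    height_sd: float = 6.5
    wc_intercept: float = 40.0
    wc_slope: float = 2.0        # cm per BMI unit
    wc_sd: float = 7.866384175718853   # => SD(WC | covariates) = 13.2 cm
    bmi_min: float = 10.0    # guard against absurd draws; truncates ~0.2% mass
    # examination-device noise (measured layer)
    meas_weight_sd: float = 0.3
    meas_height_sd: float = 0.5
    meas_wc_sd: float = 1.0


@dataclass
class OutcomeTruth:
    """True logistic model of one binary outcome: expit(linear predictor)."""

    exposure: str                 # "bmi" | "wc"
    intercept: float
    exposure_coef: float
    exposure_quad: float = 0.0
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    interaction_coefs: dict[str, float] = field(default_factory=dict)  # name -> coef on exposure*x


@dataclass
class DesignSpec:
    """Schematic two-stage survey design: strata containing clusters.

    Strata are nested in region; Brussels is oversampled relative to its
    population share, and the weights carry the inverse of that
    oversampling times outcome-independent cluster / household noise, so
    weighted statistics are consistent for the superpopulation.
    """

    strata_per_region: int = 4
    clusters_per_stratum: int = 10
    weight_noise_sd: float = 0.35   # lognormal sigma of household-level factor
    cluster_noise_sd: float = 0.15  # lognormal sigma of cluster-level factor


@dataclass
class PopulationSpec:
    """Full parametrization of the synthetic data-generating process."""

    covariates: dict[str, object] = field(default_factory=lambda: dict(
        year_p=[0.34, 0.33, 0.33],
        region_pop=[0.58, 0.32, 0.10],
        region_sample=[0.45, 0.33, 0.22],
        female_p=0.51,
        age_mean=48.0, age_sd=18.0, age_min=18.0, age_max=90.0,
        education_marginal=[0.12, 0.22, 0.33, 0.33],
        education_age_slope=-0.015,      # younger cohorts more educated
        income_edu_slope=0.45, income_noise_sd=0.8,
        household_p=[0.16, 0.05, 0.28, 0.38, 0.13],
        smoking_p=[0.52, 0.24, 0.05, 0.19],
        smoking_female_never_shift=0.06,
        indoor_base=-2.2, indoor_daily=1.5,
        alcohol_p=[0.35, 0.40, 0.15, 0.06, 0.04],
        pa_sedentary_base=-0.9, pa_sedentary_age=0.015, pa_active_p=0.25,
        bc_mu=0.20, bc_brussels=0.40, bc_income=-0.03, bc_sigma=0.35,
        veg_base=[0.48, 0.58, 0.25],    # by region
        veg_sd=0.12,
        noise_base=-1.2, noise_brussels=1.0, noise_bc=0.8,
    ))
    anthropometry: AnthropometryModel = field(default_factory=AnthropometryModel)
    selfreport: SelfReportModel = field(default_factory=SelfReportModel)
    outcomes: dict[str, OutcomeTruth] = field(default_factory=lambda: _default_outcomes())
    design: DesignSpec = field(default_factory=DesignSpec)
    subsample_fraction: float = 0.043
    missingness: dict[str, dict[str, float]] = field(default_factory=lambda: {
        # MAR: P(missing) = expit(base + age * (age-48)/10), depends on
        # the always-observed age only
        "income": {"base": -2.7, "age": 0.15},
        "alcohol": {"base": -3.1, "age": 0.10},
    })

    def validate(self) -> None:
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ConfigurationError(
                f"subsample_fraction must be in (0, 1], got {self.subsample_fraction}")
        for name, m in self.outcomes.items():
            if m.exposure not in ("bmi", "wc"):
                raise ConfigurationError(f"outcome {name!r}: unknown exposure {m.exposure!r}")
        for nm in ("strata_per_region", "clusters_per_stratum"):
            if getattr(self.design, nm) < 1:
                raise ConfigurationError(f"design.{nm} must be >= 1")
        for var, pars in self.missingness.items():
            if var in ("stratum", "cluster", "weight") or var.startswith("Y_"):
                raise ConfigurationError(
                    f"missingness may not target design or outcome column {var!r}")

    def complete(self) -> "PopulationSpec":
        """Copy of the spec with no missingness and a full examination arm."""
        return dataclasses.replace(self, missingness={}, subsample_fraction=1.0)

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PopulationSpec":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yml", ".yaml")):
                with open(text) as fh:
                    payload = yaml.safe_load(fh)
            else:
                payload = yaml.safe_load(text)
        payload = dict(payload)
        payload["anthropometry"] = AnthropometryModel(**payload["anthropometry"])
        payload["selfreport"] = SelfReportModel(**payload["selfreport"])
        payload["design"] = DesignSpec(**payload["design"])
        payload["outcomes"] = {k: OutcomeTruth(**v) for k, v in payload["outcomes"].items()}
        return cls(**payload)


def _default_outcomes() -> dict[str, OutcomeTruth]:
    # Intercepts chosen so marginal prevalences land near national
    # interview-survey figures (~5%, ~29%, ~7%, ~35%); see docs/methods.md.
    return {
        "diabetes": OutcomeTruth(
            exposure="bmi", intercept=-5.909, exposure_coef=0.10,
            covariate_coefs={"age_c": 0.045, "female": -0.20, "education_num": -0.15,
                             "daily_smoker": 0.20, "sedentary": 0.30,
                             "black_carbon": 0.15, "road_noise": 0.10}),
        "hypertension": OutcomeTruth(
            exposure="bmi", intercept=-3.783, exposure_coef=0.095,
            covariate_coefs={"age_c": 0.050, "female": -0.15, "alcohol": 0.10,
                             "black_carbon": 0.10, "road_noise": 0.15}),
        "cvd": OutcomeTruth(
            exposure="wc", intercept=-5.052, exposure_coef=0.020,
            covariate_coefs={"age_c": 0.055, "female": -0.35, "daily_smoker": 0.45,
                             "sedentary": 0.30, "black_carbon": 0.20,
                             "vegetation": -0.30, "road_noise": 0.15}),
        "msk": OutcomeTruth(
            exposure="wc", intercept=-2.098, exposure_coef=0.013,
            covariate_coefs={"age_c": 0.030, "female": 0.35, "sedentary": 0.25,
                             "daily_smoker": 0.15}),
    }


def default_spec() -> PopulationSpec:
    """The documented default data-generating process."""
    return PopulationSpec()


# ---------------------------------------------------------------------------
# covariate encodings shared by the true models and the oracle


def covariate_frame(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Numeric encodings of the covariates used in true linear predictors."""
    enc = {
        "age_c": df["age"].to_numpy(float) - 48.0,
        "female": (df["sex"] == "female").to_numpy(float),
        "education_num": df["education"].cat.codes.to_numpy().astype(float)
        if isinstance(df["education"].dtype, pd.CategoricalDtype)
        else pd.Categorical(df["education"], CATEGORICAL_LEVELS["education"]).codes.astype(float),
        "income": df["income"].to_numpy(float),
        "alcohol": df["alcohol"].to_numpy(float),
        "sedentary": (df["physical_activity"] == "sedentary").to_numpy(float),
        "active": (df["physical_activity"] == "active").to_numpy(float),
        "daily_smoker": (df["smoking"] == "daily").to_numpy(float),
        "former_smoker": (df["smoking"] == "former").to_numpy(float),
        "indoor_smoking": df["indoor_smoking"].to_numpy(float),
        "black_carbon": df["black_carbon"].to_numpy(float),
        "vegetation": df["vegetation"].to_numpy(float),
        "road_noise": df["road_noise"].to_numpy(float),
        "brussels": (df["region"] == "brussels").to_numpy(float),
        "wallonia": (df["region"] == "wallonia").to_numpy(float),
        "year_2013": (df["year"] == "2013").to_numpy(float),
        "year_2018": (df["year"] == "2018").to_numpy(float),
    }
    return enc


def linear_predictor(model: OutcomeTruth, exposure: np.ndarray,
                     enc: Mapping[str, np.ndarray]) -> np.ndarray:
    """Identity-link linear predictor of a true outcome model."""
    lp = model.intercept + model.exposure_coef * exposure
    if model.exposure_quad:
        lp = lp + model.exposure_quad * exposure ** 2
    # sorted iteration: results do not depend on dict key order
    for name in sorted(model.covariate_coefs):
        lp = lp + model.covariate_coefs[name] * np.asarray(enc[name], float)
    for name in sorted(model.interaction_coefs):
        lp = lp + model.interaction_coefs[name] * exposure * np.asarray(enc[name], float)
    return lp


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# generation


def _empty_dataset() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _SCHEMA.items()})
    for c, levels in CATEGORICAL_LEVELS.items():
        df[c] = pd.Categorical([], categories=levels)
    return df


_SCHEMA = {
    "id": "int64", "year": "object", "region": "object", "stratum": "int64",
    "cluster": "int64", "weight": "float64", "sex": "object", "age": "float64",
    "education": "object", "income": "float64", "household": "object",
    "smoking": "object", "indoor_smoking": "float64", "alcohol": "float64",
    "physical_activity": "object", "black_carbon": "float64",
    "vegetation": "float64", "road_noise": "float64",
    "height_true": "float64", "weight_true": "float64", "bmi_true": "float64",
    "wc_true": "float64",
    "height_self": "float64", "weight_self": "float64", "bmi_self": "float64",
    "exam": "float64", "height_meas": "float64", "weight_meas": "float64",
    "wc_meas": "float64", "bmi_meas": "float64",
    "Y_diabetes": "float64", "Y_hypertension": "float64",
    "Y_cvd": "float64", "Y_msk": "float64",
}


def generate_population(spec: PopulationSpec, n: int, seed: int,
                        mode: str = "survey") -> pd.DataFrame:
    """Draw ``n`` records from the data-generating process.

    Parameters
    ----------
    spec
        The data-generating process.
    n
        Number of records (>= 0).
    seed
        Master seed; generation is fully deterministic given it.
    mode
        ``"survey"`` draws with the oversampled design and unequal weights
        and applies missingness; ``"population"`` draws from the
        superpopulation (population region shares, unit weights, no
        missingness) — used by the oracle and by complete-data simulations.
    """
    spec.validate()
    if mode not in ("survey", "population"):
        raise ValueError(f"unknown mode {mode!r}")
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    if n == 0:
        return _empty_dataset()

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    cv = spec.covariates
    out = {}

    out["id"] = np.arange(n, dtype=np.int64)
    year = rng.choice(3, size=n, p=np.asarray(cv["year_p"]) / np.sum(cv["year_p"]))
    region_p = cv["region_pop"] if mode == "population" else cv["region_sample"]
    region = rng.choice(3, size=n, p=np.asarray(region_p) / np.sum(region_p))
    female = rng.random(n) < cv["female_p"]
    age = np.clip(rng.normal(cv["age_mean"], cv["age_sd"], n),
                  cv["age_min"], cv["age_max"])

    # education: ordered latent shifted by age (younger -> more educated)
    from scipy.stats import norm
    marg = np.asarray(cv["education_marginal"], float)
    cutpoints = norm.ppf(np.cumsum(marg)[:-1] / marg.sum())
    latent = rng.normal(size=n) + cv["education_age_slope"] * (age - cv["age_mean"])
    education = np.searchsorted(cutpoints, latent, side="left")

    # income 1..5: latent on education + noise, mapped through fixed cutpoints
    inc_lat = cv["income_edu_slope"] * (education - 1.5) + rng.normal(0, cv["income_noise_sd"], n)
    inc_sd = np.sqrt((cv["income_edu_slope"] ** 2) * 1.1 + cv["income_noise_sd"] ** 2)
    inc_cuts = norm.ppf([0.2, 0.4, 0.6, 0.8]) * inc_sd
    income = 1.0 + np.searchsorted(inc_cuts, inc_lat, side="left")

    household = rng.choice(5, size=n, p=np.asarray(cv["household_p"]) / np.sum(cv["household_p"]))

    smoke_p = np.tile(np.asarray(cv["smoking_p"], float), (n, 1))
    shift = cv["smoking_female_never_shift"]
    smoke_p[female, 0] += shift
    smoke_p[female, 3] -= shift
    smoke_p /= smoke_p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    smoking = (u[:, None] > np.cumsum(smoke_p, axis=1)).sum(axis=1)

    daily = (smoking == 3).astype(float)
    indoor = (rng.random(n) < _expit(cv["indoor_base"] + cv["indoor_daily"] * daily)).astype(float)

    alcohol = 1.0 + rng.choice(5, size=n, p=np.asarray(cv["alcohol_p"]) / np.sum(cv["alcohol_p"]))

    p_sed = _expit(cv["pa_sedentary_base"] + cv["pa_sedentary_age"] * (age - cv["age_mean"]))
    u = rng.random(n)
    sedentary = u < p_sed
    active = (~sedentary) & (rng.random(n) < cv["pa_active_p"] / max(1e-12, 1 - p_sed.mean()))
    pa = np.where(sedentary, 2, np.where(active, 0, 1))

    bru = (region == 2).astype(float)
    bc = np.exp(rng.normal(cv["bc_mu"] + cv["bc_brussels"] * bru
                           + cv["bc_income"] * income, cv["bc_sigma"]))
    veg_base = np.asarray(cv["veg_base"], float)[region]
    veg = np.clip(veg_base + rng.normal(0, cv["veg_sd"], n), 0.0, 1.0)
    noise = (rng.random(n) < _expit(cv["noise_base"] + cv["noise_brussels"] * bru
                                    + cv["noise_bc"] * (bc - 1.3))).astype(float)

    out.update(
        year=pd.Categorical.from_codes(year, CATEGORICAL_LEVELS["year"]),
        region=pd.Categorical.from_codes(region, CATEGORICAL_LEVELS["region"]),
        sex=pd.Categorical.from_codes(female.astype(int), CATEGORICAL_LEVELS["sex"]),
        age=age,
        education=pd.Categorical.from_codes(education, CATEGORICAL_LEVELS["education"]),
        income=income.astype(float),
        household=pd.Categorical.from_codes(household, CATEGORICAL_LEVELS["household"]),
        smoking=pd.Categorical.from_codes(smoking, CATEGORICAL_LEVELS["smoking"]),
        indoor_smoking=indoor,
        alcohol=alcohol.astype(float),
        physical_activity=pd.Categorical.from_codes(pa, CATEGORICAL_LEVELS["physical_activity"]),
        black_carbon=bc, vegetation=veg, road_noise=noise,
    )

    df = pd.DataFrame(out)
    enc = covariate_frame(df)

    # anthropometry
    an = spec.anthropometry
    bmi_mean = an.bmi_intercept + sum(an.bmi_coefs[k] * enc[k]
                                      for k in sorted(an.bmi_coefs))
    bmi_true = np.maximum(an.bmi_min, bmi_mean + rng.normal(0, an.bmi_sd, n))
    height_true = (np.where(female, an.height_female, an.height_male)
                   + an.height_age_slope * (age - cv["age_mean"])
                   + rng.normal(0, an.height_sd, n))
    weight_true = bmi_true * (height_true / 100.0) ** 2
    wc_true = an.wc_intercept + an.wc_slope * bmi_true + rng.normal(0, an.wc_sd, n)

    sr = spec.selfreport
    weight_self = weight_true + sr.weight_bias + rng.normal(0, sr.weight_sd, n)
    height_self = height_true + sr.height_bias + rng.normal(0, sr.height_sd, n)
    bmi_self = weight_self / (height_self / 100.0) ** 2

    exam_frac = 1.0 if mode == "population" else spec.subsample_fraction
    exam = (rng.random(n) < exam_frac).astype(float)
    height_meas = np.where(exam == 1, height_true + rng.normal(0, an.meas_height_sd, n), np.nan)
    weight_meas = np.where(exam == 1, weight_true + rng.normal(0, an.meas_weight_sd, n), np.nan)
    wc_meas = np.where(exam == 1, wc_true + rng.normal(0, an.meas_wc_sd, n), np.nan)
    bmi_meas = weight_meas / (height_meas / 100.0) ** 2

    df["height_true"] = height_true
    df["weight_true"] = weight_true
    df["bmi_true"] = bmi_true
    df["wc_true"] = wc_true
    df["height_self"] = height_self
    df["weight_self"] = weight_self
    df["bmi_self"] = bmi_self
    df["exam"] = exam
    df["height_meas"] = height_meas
    df["weight_meas"] = weight_meas
    df["wc_meas"] = wc_meas
    df["bmi_meas"] = bmi_meas

    # outcomes from the true models (true exposure layer)
    for name in sorted(spec.outcomes):
        model = spec.outcomes[name]
        expo = bmi_true if model.exposure == "bmi" else wc_true
        p = _expit(linear_predictor(model, expo, enc))
        df["Y_" + name] = rng.binomial(1, p).astype(float)

    # survey design: strata nested in region, clusters in strata
    dg = spec.design
    stratum_in_region = rng.integers(0, dg.strata_per_region, n)
    stratum = region * dg.strata_per_region + stratum_in_region
    cluster_in_stratum = rng.integers(0, dg.clusters_per_stratum, n)
    cluster = stratum * dg.clusters_per_stratum + cluster_in_stratum
    df["stratum"] = stratum.astype(np.int64)
    df["cluster"] = cluster.astype(np.int64)

    if mode == "population":
        df["weight"] = 1.0
    else:
        pop = np.asarray(cv["region_pop"], float)
        samp = np.asarray(cv["region_sample"], float)
        base = (pop / pop.sum())[region] / (samp / samp.sum())[region]
        n_clusters = 3 * dg.strata_per_region * dg.clusters_per_stratum
        clus_f = np.exp(rng.normal(0, dg.cluster_noise_sd, n_clusters)
                        - dg.cluster_noise_sd ** 2 / 2)
        hh_f = np.exp(rng.normal(0, dg.weight_noise_sd, n) - dg.weight_noise_sd ** 2 / 2)
        df["weight"] = base * clus_f[cluster] * hh_f

    # MAR missingness on covariates only, applied after generation
    if mode == "survey":
        for var in sorted(spec.missingness):
            pars = spec.missingness[var]
            p_mis = _expit(pars.get("base", -3.0) + pars.get("age", 0.0) * (age - 48.0) / 10.0)
            mask = rng.random(n) < p_mis
            if mask.any():
                if isinstance(df[var].dtype, pd.CategoricalDtype):
                    df.loc[mask, var] = np.nan
                else:
                    df.loc[mask, var] = np.nan

    return df[list(_SCHEMA)].copy()


# ---------------------------------------------------------------------------
# oracle


@dataclass
class OraclePIF:
    pif: float
    mc_se: float
    p_obs: float
    p_cf: float


def true_pif(spec: PopulationSpec, scenario, outcome: str,
             n_mc: int, seed: int) -> OraclePIF:
    """Monte-Carlo oracle PIF of ``scenario`` on ``outcome``.

    Simulates ``n_mc`` individuals from the superpopulation, evaluates the
    *true* outcome model risk at the factual and scenario-transformed
    exposure (all other covariates held fixed), and returns
    ``1 - P_cf / P_obs`` with a delta-method Monte-Carlo standard error.
    For the distribution-shift scenario the counterfactual draws come from
    the true normal-BMI pool of the simulated superpopulation.
    """
    from . import scenarios as _sc

    if outcome not in spec.outcomes:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    model = spec.outcomes[outcome]
    if scenario.exposure != model.exposure:
        raise ConfigurationError(
            f"scenario exposure {scenario.exposure!r} does not match the true "
            f"exposure {model.exposure!r} of outcome {outcome!r}")

    df = generate_population(spec, n_mc, seed, mode="population")
    enc = covariate_frame(df)
    expo_col = "bmi_true" if model.exposure == "bmi" else "wc_true"
    expo = df[expo_col].to_numpy(float)

    cf, _mask = _sc.apply_scenario(
        df, scenario, seed=int(np.random.SeedSequence([int(seed), 1]).generate_state(1)[0] % (2 ** 31)),
        exposure_col=expo_col, bmi_col="bmi_true", height_col="height_true",
        weight_col=None)
    r_f = _expit(linear_predictor(model, expo, enc))
    r_cf = _expit(linear_predictor(model, cf.to_numpy(float), enc))

    p_obs = float(r_f.mean())
    p_cf = float(r_cf.mean())
    if p_obs == 0.0:
        raise EstimandError("factual prevalence is zero; PIF undefined")
    pif = 1.0 - p_cf / p_obs
    # delta method on (mean r_cf, mean r_f)
    infl = r_cf / p_obs - (p_cf / p_obs ** 2) * r_f
    mc_se = float(np.sqrt(np.var(infl, ddof=1) / len(infl)))
    return OraclePIF(pif=pif, mc_se=mc_se, p_obs=p_obs, p_cf=p_cf)


# ---------------------------------------------------------------------------
# CSV + codebook I/O


def make_codebook() -> list[dict]:
    """Codebook rows (name, type, levels, units, role) for the dataset."""
    rows = []

    def add(name, vtype, role, units="", levels=None):
        rows.append({"name": name, "type": vtype, "role": role,
                     "units": units, "levels": levels or []})

    add("id", "integer", "identifier")
    for c in ("year", "region"):
        add(c, "categorical", "covariate", levels=CATEGORICAL_LEVELS[c])
    add("stratum", "integer", "design")
    add("cluster", "integer", "design")
    add("weight", "numeric", "design", units="inverse selection probability")
    add("sex", "categorical", "covariate", levels=CATEGORICAL_LEVELS["sex"])
    add("age", "numeric", "covariate", units="years")
    add("education", "categorical", "covariate", levels=CATEGORICAL_LEVELS["education"])
    add("income", "numeric", "covariate", units="quintile 1-5")
    add("household", "categorical", "covariate", levels=CATEGORICAL_LEVELS["household"])
    add("smoking", "categorical", "covariate", levels=CATEGORICAL_LEVELS["smoking"])
    add("indoor_smoking", "binary", "covariate")
    add("alcohol", "numeric", "covariate", units="drinks category 1-5")
    add("physical_activity", "categorical", "covariate",
        levels=CATEGORICAL_LEVELS["physical_activity"])
    add("black_carbon", "numeric", "covariate", units="ug/m3")
    add("vegetation", "numeric", "covariate", units="fraction 0-1")
    add("road_noise", "binary", "covariate", units="Lden > 55 dB")
    for c, u in (("height_true", "cm"), ("weight_true", "kg"),
                 ("bmi_true", "kg/m2"), ("wc_true", "cm")):
        add(c, "numeric", "truth", units=u)
    for c, u in (("height_self", "cm"), ("weight_self", "kg"), ("bmi_self", "kg/m2")):
        add(c, "numeric", "exposure", units=u)
    add("exam", "binary", "design", units="examination arm")
    for c, u in (("height_meas", "cm"), ("weight_meas", "kg"),
                 ("wc_meas", "cm"), ("bmi_meas", "kg/m2")):
        add(c, "numeric", "exposure", units=u)
    for o in OUTCOMES:
        add("Y_" + o, "binary", "outcome")
    return rows


def write_dataset(df: pd.DataFrame, csv_path, codebook_path=None) -> None:
    """Write a dataset as CSV (missing values as empty fields) + YAML codebook."""
    df.to_csv(csv_path, index=False, na_rep="")
    if codebook_path is not None:
        with open(codebook_path, "w") as fh:
            yaml.safe_dump(make_codebook(), fh, sort_keys=False)


def read_dataset(csv_path, codebook_path=None) -> pd.DataFrame:
    """Read a dataset written by :func:`write_dataset`, restoring dtypes."""
    df = pd.read_csv(csv_path)
    levels = CATEGORICAL_LEVELS
    if codebook_path is not None:
        with open(codebook_path) as fh:
            rows = yaml.safe_load(fh)
        levels = {r["name"]: r["levels"] for r in rows
                  if r["type"] == "categorical" and r["levels"]}
    def _as_level(x):
        # CSV readback turns numeric-looking levels ("2008") into numbers
        if isinstance(x, float):
            return str(int(x)) if x.is_integer() else str(x)
        if isinstance(x, (int, np.integer)):
            return str(int(x))
        return str(x)

    for c, lv in levels.items():
        if c in df.columns:
            s = df[c]
            vals = np.array([_as_level(x) if pd.notna(x) else None
                             for x in s.to_numpy()], dtype=object)
            df[c] = pd.Categorical(vals, categories=[str(x) for x in lv])
    return df
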