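"""Survey-weighted logistic outcome models.

Models follow the adjustment-set-from-DAG convention: one continuous
adiposity exposure (BMI or waist circumference) plus socio-demographic,
lifestyle and environmental confounders, region and survey year.  Weights
enter as likelihood weights (statsmodels ``var_weights``) with a robust
(HC1 sandwich) variance; metabolic mediators are refused in the adjustment
set.  Optional quadratic-exposure and exposure-by-covariate interaction
terms are selected by bidirectional stepwise AIC.

The fitted model carries a serialisable design recipe (reference-level
dummy coding, first codebook level as reference), so risk predictions are
reproducible bit-for-bit after a JSON round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthpop import ADJUSTMENT_COVARIATES, CATEGORICAL_LEVELS

__all__ = [
    "OutcomeModelSpec", "FittedOutcomeModel", "DesignRecipe",
    "fit_outcome_model", "or_per_iqr", "evaluate_auc", "select_terms_aic",
    "fit_logistic_irls", "weighted_quantile", "FitError", "DataError",
]

#: mediators / colliders on the adiposity -> disease pathway, never adjusted for
METABOLIC_MEDIATORS = frozenset({"hypertension", "Y_hypertension",
                                 "hypercholesterolemia"})


class FitError(RuntimeError):
    """Model fitting failed (e.g. perfect separation)."""


class DataError(ValueError):
    """Input data violate a model precondition."""


@dataclass
class OutcomeModelSpec:
    outcome: str
    exposure: str = "bmi"                       # "bmi" | "wc"
    adjustment: list[str] = field(default_factory=lambda: list(ADJUSTMENT_COVARIATES))
    candidate_interactions: list[str] = field(default_factory=list)
    candidate_quadratic: bool = False
    selection: str = "none"                     # "none" | "aic"

    def validate(self) -> None:
        bad = METABOLIC_MEDIATORS.intersection(self.adjustment)
        if bad:
            raise DataError(
                f"metabolic mediators/colliders {sorted(bad)} may not be in the "
                f"adjustment set of outcome {self.outcome!r}")
        if self.exposure not in ("bmi", "wc"):
            raise DataError(f"unknown exposure {self.exposure!r}")
        if self.selection not in ("none", "aic"):
            raise DataError(f"unknown selection method {self.selection!r}")


# ---------------------------------------------------------------------------
# design recipe


@dataclass
class DesignRecipe:
    """Reproducible design-matrix expansion for one fitted model.

    Terms, in column order: intercept, exposure, optional exposure^2,
    main effects (numeric as-is, categoricals dummy-coded against the first
    level), then selected exposure-by-covariate interactions.
    """

    exposure: str
    adjustment: list[str]
    levels: dict[str, list[str]]
    quadratic: bool = False
    interactions: list[str] = field(default_factory=list)

    def column_names(self) -> list[str]:
        names = ["intercept", self.exposure]
        if self.quadratic:
            names.append(f"{self.exposure}^2")
        for v in self.adjustment:
            if v in self.levels:
                names += [f"{v}[{lv}]" for lv in self.levels[v][1:]]
            else:
                names.append(v)
        for v in self.interactions:
            if v in self.levels:
                names += [f"{self.exposure}:{v}[{lv}]" for lv in self.levels[v][1:]]
            else:
                names.append(f"{self.exposure}:{v}")
        return names

    def _covariate_block(self, df: pd.DataFrame) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        cols, raw = [], {}
        for v in self.adjustment:
            if v in self.levels:
                codes = pd.Categorical(df[v], categories=self.levels[v]).codes
                if (codes < 0).any():
                    raise DataError(f"covariate {v!r} has values outside its levels "
                                    "or missing entries")
                for j in range(1, len(self.levels[v])):
                    cols.append((codes == j).astype(float))
            else:
                x = df[v].to_numpy(float)
                if np.isnan(x).any():
                    raise DataError(f"covariate {v!r} has missing values")
                cols.append(x)
        for v in self.interactions:
            if v in self.levels:
                codes = pd.Categorical(df[v], categories=self.levels[v]).codes
                for j in range(1, len(self.levels[v])):
                    raw[f"{v}[{j}]"] = (codes == j).astype(float)
            else:
                raw[v] = df[v].to_numpy(float)
        return (np.column_stack(cols) if cols else np.empty((len(df), 0))), raw

    def build(self, df: pd.DataFrame,
              exposure_values: Optional[np.ndarray] = None) -> np.ndarray:
        """Design matrix; ``exposure_values`` overrides the exposure column."""
        n = len(df)
        x = (np.asarray(exposure_values, float) if exposure_values is not None
             else df[self.exposure].to_numpy(float))
        if np.isnan(x).any():
            raise DataError(f"exposure {self.exposure!r} has missing values")
        blocks = [np.ones(n), x]
        if self.quadratic:
            blocks.append(x ** 2)
        cov_block, inter_raw = self._covariate_block(df)
        X = np.column_stack(blocks + ([cov_block] if cov_block.shape[1] else []))
        if self.interactions:
            inter_cols = []
            for v in self.interactions:
                if v in self.levels:
                    for j in range(1, len(self.levels[v])):
                        inter_cols.append(x * inter_raw[f"{v}[{j}]"])
                else:
                    inter_cols.append(x * inter_raw[v])
            X = np.column_stack([X] + inter_cols)
        return X

    def to_dict(self) -> dict:
        return {"exposure": self.exposure, "adjustment": list(self.adjustment),
                "levels": {k: list(v) for k, v in self.levels.items()},
                "quadratic": self.quadratic, "interactions": list(self.interactions)}

    @classmethod
    def from_dict(cls, d: dict) -> "DesignRecipe":
        return cls(exposure=d["exposure"], adjustment=list(d["adjustment"]),
                   levels={k: list(v) for k, v in d["levels"].items()},
                   quadratic=bool(d["quadratic"]),
                   interactions=list(d["interactions"]))


def _make_recipe(spec: OutcomeModelSpec, quadratic=False,
                 interactions: Sequence[str] = ()) -> DesignRecipe:
    levels = {v: CATEGORICAL_LEVELS[v] for v in spec.adjustment
              if v in CATEGORICAL_LEVELS}
    for v in interactions:
        if v in CATEGORICAL_LEVELS:
            levels.setdefault(v, CATEGORICAL_LEVELS[v])
    return DesignRecipe(exposure=spec.exposure, adjustment=list(spec.adjustment),
                        levels=levels, quadratic=quadratic,
                        interactions=list(interactions))


# ---------------------------------------------------------------------------
# fitting


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def fit_logistic_irls(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                      start: Optional[np.ndarray] = None, tol: float = 1e-10,
                      max_iter: int = 60, ridge: float = 0.0) -> np.ndarray:
    """Weighted-likelihood logistic Newton solver.

    Matches statsmodels GLM(Binomial, var_weights) coefficients to solver
    tolerance; used inside bootstrap loops where the per-fit overhead of
    the full GLM machinery dominates.  ``ridge`` adds a tiny L2 penalty for
    near-singular replicate designs.
    """
    p = X.shape[1]
    beta = np.zeros(p) if start is None else np.asarray(start, float).copy()
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        np.clip(eta, -30, 30, out=eta)
        mu = _expit(eta)
        wt = w * mu * (1.0 - mu)
        g = X.T @ (w * (y - mu)) - ridge * beta
        H = (X * wt[:, None]).T @ X + (ridge + 1e-12) * eye
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def weighted_loglik(X, y, w, beta) -> float:
    eta = np.clip(X @ beta, -30, 30)
    mu = _expit(eta)
    return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log1p(-mu))))


@dataclass
class FittedOutcomeModel:
    outcome: str
    recipe: DesignRecipe
    params: np.ndarray
    names: list[str]
    cov: np.ndarray
    aic: float
    n: int
    weighted: bool
    selected_terms: list[str] = field(default_factory=list)

    @property
    def exposure(self) -> str:
        return self.recipe.exposure

    def linear_predictor(self, df: pd.DataFrame,
                         exposure_values: Optional[np.ndarray] = None) -> np.ndarray:
        return self.recipe.build(df, exposure_values) @ self.params

    def predict_risk(self, df: pd.DataFrame,
                     exposure_values: Optional[np.ndarray] = None) -> np.ndarray:
        return _expit(self.linear_predictor(df, exposure_values))

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "outcome": self.outcome, "recipe": self.recipe.to_dict(),
            "params": [float(v) for v in self.params], "names": self.names,
            "cov": [[float(v) for v in row] for row in self.cov],
            "aic": float(self.aic), "n": int(self.n),
            "weighted": bool(self.weighted),
            "selected_terms": list(self.selected_terms),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedOutcomeModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            payload = json.loads(text) if text.lstrip().startswith("{") else json.load(open(text))
        return cls(outcome=payload["outcome"],
                   recipe=DesignRecipe.from_dict(payload["recipe"]),
                   params=np.asarray(payload["params"], float),
                   names=list(payload["names"]),
                   cov=np.asarray(payload["cov"], float),
                   aic=payload["aic"], n=payload["n"],
                   weighted=payload["weighted"],
                   selected_terms=list(payload["selected_terms"]))


def _response(df: pd.DataFrame, outcome: str) -> np.ndarray:
    col = outcome if outcome in df.columns else "Y_" + outcome
    y = df[col].to_numpy(float)
    if np.isnan(y).any():
        raise DataError(f"outcome {col!r} has missing values")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError(f"outcome {col!r} is not 0/1")
    return y


def _weights(df: pd.DataFrame, weight_col: Optional[str]) -> np.ndarray:
    if weight_col is None:
        return np.ones(len(df))
    w = df[weight_col].to_numpy(float)
    if np.isnan(w).any() or (w <= 0).any():
        raise DataError("survey weights must be strictly positive")
    return w


def fit_outcome_model(df: pd.DataFrame, spec: OutcomeModelSpec,
                      weight_col: Optional[str] = "weight") -> FittedOutcomeModel:
    """Maximise the survey-weighted logistic likelihood for one outcome.

    With ``selection="aic"`` the candidate quadratic/interaction terms are
    first chosen by :func:`select_terms_aic`, then the selected model is
    refit.  Deterministic throughout.
    """
    spec.validate()
    selected: list[str] = []
    quadratic, interactions = False, []
    if spec.selection == "aic" and (spec.candidate_quadratic or spec.candidate_interactions):
        selected = select_terms_aic(df, spec, weight_col=weight_col)
        quadratic = "quadratic" in selected
        interactions = [t.split(":", 1)[1] for t in selected if t.startswith("interaction:")]
    recipe = _make_recipe(spec, quadratic=quadratic, interactions=interactions)
    X = recipe.build(df)
    y = _response(df, spec.outcome)
    w = _weights(df, weight_col)

    try:
        res = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit(
            cov_type="HC1", maxiter=200)
        params = np.asarray(res.params, float)
        cov = np.asarray(res.cov_params(), float)
        aic = float(res.aic)
    except Exception as exc:  # statsmodels PerfectSeparation or LinAlg errors
        raise FitError(f"logistic fit failed for outcome {spec.outcome!r}: {exc}") from exc
    names = recipe.column_names()
    mu = _expit(np.clip(X @ params, -700, 700))
    separated = (not np.isfinite(params).all()
                 or (mu[y == 1].size and mu[y == 0].size
                     and mu[y == 1].min() > 1 - 1e-8 and mu[y == 0].max() < 1e-8))
    if separated:
        scale = np.abs(params) * (X.std(axis=0) + (np.arange(X.shape[1]) == 0))
        term = names[int(np.argmax(scale))]
        raise FitError(f"perfect separation for outcome {spec.outcome!r}: "
                       f"term {term!r} separates the classes")
    return FittedOutcomeModel(outcome=spec.outcome, recipe=recipe, params=params,
                              names=names, cov=cov, aic=aic, n=len(df),
                              weighted=weight_col is not None,
                              selected_terms=selected)


# ---------------------------------------------------------------------------
# OR per IQR


def weighted_quantile(x: np.ndarray, q, w: Optional[np.ndarray] = None) -> np.ndarray:
    """Weighted quantile with linear interpolation on the weighted CDF."""
    x = np.asarray(x, float)
    if w is None:
        return np.quantile(x, q)
    w = np.asarray(w, float)
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cdf = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
    return np.interp(np.atleast_1d(q), cdf, xs)


@dataclass
class ORPerIQR:
    odds_ratio: float
    ci_low: float
    ci_high: float
    iqr: float
    conditional: bool   # True when quadratic/interaction terms involve the exposure


def or_per_iqr(model: FittedOutcomeModel, df: pd.DataFrame,
               weight_col: Optional[str] = "weight") -> ORPerIQR:
    """Odds ratio for a one-IQR increase of the exposure.

    The IQR is computed from the survey-weighted exposure distribution.
    When the selected model contains quadratic or interaction terms the
    main-effect OR is conditional (covariates at reference, exposure at
    zero curvature) and is flagged as such.
    """
    x = df[model.exposure].to_numpy(float)
    w = None if weight_col is None else _weights(df, weight_col)
    q25, q75 = weighted_quantile(x, [0.25, 0.75], w)
    iqr = float(q75 - q25)
    if iqr <= 0:
        raise DataError(f"degenerate exposure {model.exposure!r}: IQR = 0")
    j = model.names.index(model.exposure)
    beta, se = float(model.params[j]), float(np.sqrt(model.cov[j, j]))
    conditional = model.recipe.quadratic or bool(model.recipe.interactions)
    return ORPerIQR(odds_ratio=float(np.exp(beta * iqr)),
                    ci_low=float(np.exp((beta - 1.96 * se) * iqr)),
                    ci_high=float(np.exp((beta + 1.96 * se) * iqr)),
                    iqr=iqr, conditional=conditional)


# ---------------------------------------------------------------------------
# discrimination


def evaluate_auc(df: pd.DataFrame, spec: OutcomeModelSpec, train_fraction: float = 0.7,
                 seed: int = 0, weight_col: Optional[str] = "weight") -> float:
    """Split-sample weighted AUC: fit on 70%, evaluate on the held-out 30%."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA0C]))
    n = len(df)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train, test = perm[:n_train], perm[n_train:]
    dtr, dte = df.iloc[train], df.iloc[test]
    y_te = _response(dte, spec.outcome)
    if len(np.unique(y_te)) < 2:
        raise DataError("test split contains a single outcome class")
    model = fit_outcome_model(dtr, spec, weight_col=weight_col)
    p = model.predict_risk(dte)
    w = None if weight_col is None else _weights(dte, weight_col)
    return float(roc_auc_score(y_te, p, sample_weight=w))


# ---------------------------------------------------------------------------
# stepwise AIC


def select_terms_aic(df: pd.DataFrame, spec: OutcomeModelSpec,
                     weight_col: Optional[str] = "weight") -> list[str]:
    """Bidirectional greedy stepwise AIC over quadratic + interaction terms.

    Starts from the main-effects model; at each step the single add or drop
    move that lowers AIC the most is taken (ties broken by candidate
    order), until no move improves.  Returns the selected term list, each
    item ``"quadratic"`` or ``"interaction:<covariate>"``.
    """
    spec.validate()
    candidates: list[str] = []
    if spec.candidate_quadratic:
        candidates.append("quadratic")
    candidates += [f"interaction:{v}" for v in spec.candidate_interactions]
    if not candidates:
        return []

    y = _response(df, spec.outcome)
    w = _weights(df, weight_col)

    def aic_of(terms: frozenset[str]) -> float:
        recipe = _make_recipe(
            spec, quadratic="quadratic" in terms,
            interactions=[t.split(":", 1)[1] for t in candidates
                          if t in terms and t.startswith("interaction:")])
        X = recipe.build(df)
        beta = fit_logistic_irls(X, y, w)
        return -2.0 * weighted_loglik(X, y, w, beta) + 2.0 * X.shape[1]

    cache: dict[frozenset, float] = {}

    def aic_cached(terms: frozenset[str]) -> float:
        if terms not in cache:
            cache[terms] = aic_of(terms)
        return cache[terms]

    current: frozenset[str] = frozenset()
    current_aic = aic_cached(current)
    while True:
        best_terms, best_aic = None, current_aic
        for t in candidates:
            trial = current - {t} if t in current else current | {t}
            a = aic_cached(trial)
            if a < best_aic - 1e-9:
                best_terms, best_aic = trial, a
        if best_terms is None:
            break
        current, current_aic = best_terms, best_aic
    return [t for t in candidates if t in current]
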