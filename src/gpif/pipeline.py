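"""End-to-end orchestration: generate/load -> impute -> per-imputation
g-computation over every scenario x outcome x target -> Rubin pooling ->
tidy report.

All randomness flows from one mandatory master seed through a counter-based
seed-spawning scheme (per-imputation, then per-bootstrap-replicate), so two
runs of the same configuration produce byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import gcomp, scenarios as sc
from .impute import ImputationConfig, chain_converged, finalize_completed, rf_mice_impute
from .outcome_models import OutcomeModelSpec, evaluate_auc, fit_outcome_model, or_per_iqr
from .pool import rubin_pool
from .synthpop import (ConfigurationError, PopulationSpec, default_spec,
                       generate_population, read_dataset)

log = logging.getLogger("gpif")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    ``scenarios`` entries are ``{"id": "s2", "target": "bmi>25"}`` dicts;
    ``outcome_specs`` entries configure :class:`OutcomeModelSpec`.  Every
    scenario must have at least one outcome model with a matching exposure.
    """

    master_seed: int
    n: int = 20_000
    population_spec: Optional[PopulationSpec] = None
    input_csv: Optional[str] = None
    input_codebook: Optional[str] = None
    imputation: ImputationConfig = field(default_factory=lambda: ImputationConfig(
        m=5, n_iterations=20, n_trees=25))
    outcome_specs: list[OutcomeModelSpec] = field(default_factory=list)
    scenarios: list[dict] = field(default_factory=list)
    n_boot: int = 200
    adjust_physical_activity: bool = True
    output_dir: Optional[str] = None
    train_fraction: float = 0.7

    def scenario_objects(self) -> list[sc.ScenarioDefinition]:
        out = []
        for entry in self.scenarios:
            out.append(sc.builtin_scenario(entry["id"],
                                           entry.get("target", "bmi>25")))
        return out

    def validate(self) -> None:
        if self.master_seed is None:
            raise ConfigurationError("master_seed is mandatory")
        if not self.outcome_specs:
            raise ConfigurationError("no outcome model specified")
        if not self.scenarios:
            raise ConfigurationError("no scenario specified")
        exposures = {s.exposure for s in self.outcome_specs}
        for scen in self.scenario_objects():
            if scen.id != "identity" and scen.exposure not in exposures:
                raise ConfigurationError(
                    f"scenario {scen.key!r} has exposure {scen.exposure!r} but no "
                    "outcome model uses that exposure")
        for s in self.outcome_specs:
            s.validate()

    # -- YAML --------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "master_seed": self.master_seed, "n": self.n,
            "input_csv": self.input_csv, "input_codebook": self.input_codebook,
            "imputation": dataclasses.asdict(self.imputation),
            "outcome_specs": [dataclasses.asdict(s) for s in self.outcome_specs],
            "scenarios": list(self.scenarios), "n_boot": self.n_boot,
            "adjust_physical_activity": self.adjust_physical_activity,
            "train_fraction": self.train_fraction,
        }
        if self.population_spec is not None:
            d["population_spec"] = yaml.safe_load(self.population_spec.to_yaml())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pop = d.pop("population_spec", None)
        spec = (PopulationSpec.from_yaml(yaml.safe_dump(pop))
                if pop is not None else None)
        imp = ImputationConfig(**d.pop("imputation", {}))
        specs = [OutcomeModelSpec(**s) for s in d.pop("outcome_specs", [])]
        d.pop("output_dir", None)
        return cls(population_spec=spec, imputation=imp, outcome_specs=specs, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(master_seed: int, n: int = 20_000, n_boot: int = 200,
                   m: int = 5) -> RunConfig:
    """The shipped desk-scale example configuration.

    BMI models for the interview-driven outcomes (diabetes, hypertension)
    under the three BMI scenarios at both targets; WC models for CVD and
    MSK under the waist-circumference scenario.
    """
    specs = [OutcomeModelSpec(outcome="diabetes", exposure="bmi"),
             OutcomeModelSpec(outcome="hypertension", exposure="bmi"),
             OutcomeModelSpec(outcome="cvd", exposure="wc"),
             OutcomeModelSpec(outcome="msk", exposure="wc")]
    scen = [{"id": sid, "target": tv}
            for sid in ("s1", "s2", "s3") for tv in ("bmi>25", "bmi>30")]
    scen.append({"id": "s4"})
    return RunConfig(master_seed=master_seed, n=n,
                     population_spec=default_spec(),
                     imputation=ImputationConfig(m=m, n_iterations=20, n_trees=25),
                     outcome_specs=specs, scenarios=scen, n_boot=n_boot)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    chain_summary: Optional[pd.DataFrame]
    chain_converged: Optional[bool]
    manifest: dict

    def write(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        self.report.to_csv(os.path.join(directory, "report.csv"), index=False)
        with open(os.path.join(directory, "report.json"), "w") as fh:
            fh.write(self.report.to_json(orient="records", indent=1))
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        if self.chain_summary is not None:
            self.chain_summary.to_csv(
                os.path.join(directory, "chain_summary.csv"), index=False)


def _config_hash(config: RunConfig) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring."""
    config.validate()
    t0 = time.perf_counter()
    ss = np.random.SeedSequence([int(config.master_seed), 0xF1FE])
    gen_seed, imp_seed, auc_seed = (int(x % (2 ** 31))
                                    for x in ss.generate_state(3))

    specs = config.outcome_specs
    if not config.adjust_physical_activity:
        specs = [dataclasses.replace(
            s, adjustment=[c for c in s.adjustment if c != "physical_activity"])
            for s in specs]

    # stage 1: load or generate
    if config.input_csv is not None:
        data = read_dataset(config.input_csv, config.input_codebook)
        spec = config.population_spec
    else:
        spec = config.population_spec or default_spec()
        data = generate_population(spec, config.n, seed=gen_seed)
    log.info("input: %d records (%.1fs)", len(data), time.perf_counter() - t0)

    # stage 2: imputation
    t1 = time.perf_counter()
    has_missing = bool(data.drop(columns=["bmi_meas"], errors="ignore")
                       .isna().any().any())
    if has_missing:
        cfg = dataclasses.replace(config.imputation, seed=imp_seed)
        completed_sets = rf_mice_impute(data, cfg)
        completed = [finalize_completed(d) for d in completed_sets.datasets]
        if completed_sets.chain_trace.empty:
            conv, chain_summary = None, None
        else:
            window = max(2, min(10, cfg.n_iterations))
            conv, chain_summary = chain_converged(completed_sets.chain_trace, window)
    else:
        completed = [finalize_completed(data)]
        conv, chain_summary = None, None
    m = len(completed)
    log.info("imputation: m=%d (%.1fs)", m, time.perf_counter() - t1)

    # stage 3: per-imputation estimation
    t2 = time.perf_counter()
    scen_objs = config.scenario_objects()
    imp_seeds = np.random.SeedSequence([int(config.master_seed), 0xE57]).spawn(m)
    per_imp: dict[tuple[str, str], list[gcomp.PIFEstimate]] = {}
    log_or: dict[str, list[tuple[float, float]]] = {s.outcome: [] for s in specs}
    aucs: dict[str, list[float]] = {s.outcome: [] for s in specs}
    reductions: dict[str, list[float]] = {}
    for i, dd in enumerate(completed):
        i_seed = int(imp_seeds[i].generate_state(1)[0] % (2 ** 31))
        res = gcomp.bootstrap_pifs(dd, specs, scen_objs, n_boot=config.n_boot,
                                   seed=i_seed)
        for key, est in res.items():
            per_imp.setdefault(key, []).append(est)
        for spec_o in specs:
            full = fit_outcome_model(dd, spec_o)
            orr = or_per_iqr(full, dd)
            se_log = (np.log(orr.ci_high) - np.log(orr.ci_low)) / (2 * 1.96)
            log_or[spec_o.outcome].append((np.log(orr.odds_ratio), se_log ** 2))
            aucs[spec_o.outcome].append(
                evaluate_auc(dd, spec_o, config.train_fraction, seed=auc_seed + i))
        for scen in scen_objs:
            reductions.setdefault(scen.key, []).append(
                sc.mean_exposure_reduction(dd, scen, seed=i_seed))
    log.info("estimation: %d combos x m=%d, n_boot=%d (%.1fs)",
             len(per_imp), m, config.n_boot, time.perf_counter() - t2)

    # stage 4: pooling
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for (outcome, skey), ests in sorted(per_imp.items()):
            pooled_pif = rubin_pool([e.pif for e in ests],
                                    [(e.se_pif or 0.0) ** 2 for e in ests])
            pooled_rd = rubin_pool([e.rd for e in ests],
                                   [(e.se_rd or 0.0) ** 2 for e in ests])
            pooled_prev = rubin_pool([e.p_obs for e in ests],
                                     [(e.se_p_obs or 0.0) ** 2 for e in ests])
            lo_pairs = log_or[outcome]
            pooled_or = rubin_pool([a for a, _ in lo_pairs],
                                   [b for _, b in lo_pairs])
            scen = next(s for s in scen_objs if s.key == skey)
            rows.append({
                "outcome": outcome, "scenario": scen.id,
                "target": scen.target_variant, "scenario_key": skey,
                "baseline_prev_pct": 100 * pooled_prev.point,
                "baseline_prev_lo": 100 * pooled_prev.ci_low,
                "baseline_prev_hi": 100 * pooled_prev.ci_high,
                "or_per_iqr": float(np.exp(pooled_or.point)),
                "or_lo": float(np.exp(pooled_or.ci_low)),
                "or_hi": float(np.exp(pooled_or.ci_high)),
                "rd_pct": 100 * pooled_rd.point,
                "rd_lo": 100 * pooled_rd.ci_low,
                "rd_hi": 100 * pooled_rd.ci_high,
                "pif_pct": 100 * pooled_pif.point,
                "pif_lo": 100 * pooled_pif.ci_low,
                "pif_hi": 100 * pooled_pif.ci_high,
                "mean_reduction": float(np.mean(reductions[skey])),
                "mean_auc": float(np.mean(aucs[outcome])),
                "m": m, "n_boot": config.n_boot,
            })
    report = pd.DataFrame(rows)

    manifest = {
        "package_version": _pkg_version,
        "config_hash": _config_hash(config),
        "master_seed": int(config.master_seed),
        "stage_seeds": {"generate": gen_seed, "impute": imp_seed, "auc": auc_seed},
        "n_records": int(len(data)), "m": m, "n_boot": int(config.n_boot),
        "chain_converged": conv,
    }
    result = PipelineResult(report=report, chain_summary=chain_summary,
                            chain_converged=conv, manifest=manifest)
    if config.output_dir:
        result.write(config.output_dir)
    log.info("pipeline done (%.1fs)", time.perf_counter() - t0)
    return result
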