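#!/usr/bin/env python
"""Correct the self-report measurement error by chained random-forest
multiple imputation.

Reads the survey written by 01_simulate.py, imputes the measured
anthropometry outside the examination arm (and the missing covariates) in
one chained process, checks chain convergence, and reports how much of the
known -2 kg self-report weight bias the imputation removed.  Completed
datasets go to results/imputed/.
"""

import os

import numpy as np

from gpif import ImputationConfig, chain_converged, rf_mice_impute
from gpif.synthpop import read_dataset

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 2025
M, ITERS, TREES = 3, 12, 25


def main():
    data_csv = os.path.join(BASE, "data", "survey.csv")
    if not os.path.exists(data_csv):
        raise SystemExit("run analysis/01_simulate.py first")
    ds = read_dataset(data_csv, os.path.join(BASE, "data", "codebook.yaml"))

    cfg = ImputationConfig(m=M, n_iterations=ITERS, n_trees=TREES, seed=SEED)
    out = rf_mice_impute(ds, cfg)
    outdir = os.path.join(BASE, "imputed")
    os.makedirs(outdir, exist_ok=True)
    out.write(outdir)

    ok, summary = chain_converged(out.chain_trace, window=min(10, ITERS))
    summary.to_csv(os.path.join(outdir, "chain_summary.csv"), index=False)
    print(f"m={M} imputations, {ITERS} cycles, {TREES} trees; "
          f"chains converged: {ok}")

    not_exam = ds["weight_meas"].isna().to_numpy()
    target = float((ds.loc[not_exam, "weight_true"]
                    - ds.loc[not_exam, "weight_self"]).mean())
    rec = np.array([float((d.loc[not_exam, "weight_meas"]
                           - ds.loc[not_exam, "weight_self"]).mean())
                    for d in out.datasets])
    print(f"realised self-report weight gap (true - self): {target:+.2f} kg")
    print(f"recovered by imputation: {rec.mean():+.2f} kg "
          f"(per-imputation spread {rec.std(ddof=1):.3f})")


if __name__ == "__main__":
    main()
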