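#!/usr/bin/env python
"""Estimate potential impact fractions of the four weight-reduction
scenarios and pool them across imputations.

Runs the full pipeline end to end (generate -> impute -> per-imputation
bootstrap g-computation -> Rubin pooling) at desk scale and writes the
tidy report (baseline prevalence, OR per IQR, risk difference, PIF, mean
exposure reduction, mean AUC per scenario x outcome x target) under
results/pifs/.
"""

import os

from gpif.pipeline import default_config, run_pipeline

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    cfg = default_config(master_seed=2026, n=6_000, n_boot=100, m=3)
    cfg.imputation.n_iterations = 12
    cfg.output_dir = os.path.join(BASE, "pifs")
    result = run_pipeline(cfg)

    cols = ["outcome", "scenario", "target", "baseline_prev_pct", "rd_pct",
            "pif_pct", "pif_lo", "pif_hi", "mean_reduction"]
    print(result.report[cols].round(2).to_string(index=False))
    dia = result.report.query("outcome == 'diabetes' and target == 'bmi>25'")
    dia = dia.set_index("scenario")["pif_pct"]
    print(f"\ndiabetes, overweight target: distribution shift prevents "
          f"{dia['s1']:.1f}% of cases, 10% weight loss {dia['s3']:.1f}%, "
          f"one BMI unit {dia['s2']:.1f}% - impact tracks intervention size")
    print("scenario 2's mean reduction is exactly 1 BMI unit by construction; "
          "the overweight target always dominates the obesity-only target")


if __name__ == "__main__":
    main()
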