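#!/usr/bin/env python
"""Generate the synthetic health-survey dataset used by the analysis chain.

Draws a survey of 6 000 adults from the default data-generating process:
self-reported height/weight for everyone, measured anthropometry in a ~4%
examination arm, item nonresponse on income and alcohol, four chronic
disease outcomes and unequal survey weights.  Writes the dataset, its
codebook and a descriptive summary under results/data/.
"""

import os

import numpy as np

from gpif import default_spec, generate_population, write_dataset

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "data")
SEED = 2024
N = 6_000


def main():
    os.makedirs(OUT, exist_ok=True)
    spec = default_spec()
    spec.to_yaml(os.path.join(OUT, "population_spec.yaml"))
    df = generate_population(spec, N, seed=SEED)
    write_dataset(df, os.path.join(OUT, "survey.csv"),
                  os.path.join(OUT, "codebook.yaml"))

    exam = int(df["exam"].sum())
    print(f"generated {len(df)} records (seed {SEED}); "
          f"{exam} in the examination arm ({100 * exam / len(df):.1f}%)")
    print(f"overweight (true BMI > 25): {100 * (df.bmi_true > 25).mean():.1f}%; "
          f"obesity: {100 * (df.bmi_true > 30).mean():.1f}%")
    print("self-report gap, weight (kg): "
          f"{(df.weight_self - df.weight_true).mean():+.2f}")
    prev = {o: f"{100 * df['Y_' + o].mean():.1f}%"
            for o in ("diabetes", "hypertension", "cvd", "msk")}
    print("crude outcome prevalences:", prev)
    miss = df[["income", "alcohol"]].isna().mean()
    print(f"item nonresponse: income {100 * miss['income']:.1f}%, "
          f"alcohol {100 * miss['alcohol']:.1f}%")


if __name__ == "__main__":
    main()
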