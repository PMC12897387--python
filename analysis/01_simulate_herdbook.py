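#!/usr/bin/env python
"""Simulate the synthetic herdbook the downstream analyses run on.

Two traits are generated over the same pedigree structure:

- a continuous stature-like trait (cm) with variance components
  (sigma_a2, sigma_pe2, sigma_cg2, sigma_e2) = (8.5, 5.0, 3.3, 3.5),
- a 9-point milking-ease-like score from a logistic liability with latent
  (sigma_a2, sigma_pe2, sigma_cg2) = (0.9, 1.2, 0.5) and residual pi^2/3.

Both share the herd-year contemporary-group structure, 1-4 records per
cow (most cows evaluated once), seasons, evaluators nested in herds, a
diet factor and the dam-age covariate.  Outputs go to results/data/.
"""

import numpy as np

from pedeval.simulate import SimulationConfig, simulate_records

SEED = 20240915
OUT = "results/data"


def main():
    stature = SimulationConfig(
        seed=SEED, trait="stature", trait_mean=137.0,
        sigma_a2=8.5, sigma_pe2=5.0, sigma_cg2=3.3, sigma_e2=3.5)
    ds = simulate_records(config=stature)
    ds.write(f"{OUT}/stature")
    print(f"stature: {len(ds.pedigree)} animals, {len(ds.records)} records, "
          f"{ds.records.cow.nunique()} cows -> {OUT}/stature")

    milking = SimulationConfig(
        seed=SEED + 1, trait="milking_ease", trait_scale="ordinal-9",
        residual_law="logistic",
        sigma_a2=0.9, sigma_pe2=1.2, sigma_cg2=0.5,
        sigma_e2=float(np.pi ** 2 / 3),
        thresholds=tuple(np.linspace(-3.0, 3.0, 8)))
    ds = simulate_records(config=milking)
    ds.write(f"{OUT}/milking_ease")
    counts = ds.records.value.value_counts().sort_index()
    print(f"milking ease scores 1-9 frequency: {counts.to_dict()}")
    print(f"-> {OUT}/milking_ease")


if __name__ == "__main__":
    main()
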