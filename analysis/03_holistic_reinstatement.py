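#!/usr/bin/env python
"""Holistic-reinstatement recovery: template-to-trial similarity conditions.

Sweeps the planted reinstatement strength and reports, per strength, the mean
Fisher-z similarity for unique-store within-city, shared-store within-city and
unique-store between-city pairs (averaged across the 8 tSNR levels), plus the
within-minus-between contrast.  A positive contrast that grows with the
planted strength demonstrates parameter recovery.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from overlapmaps.simulate import EffectSpec
from overlapmaps.workflows import holistic_scores, simulate_subject

OUT = Path(__file__).resolve().parents[1] / "results"
SEEDS = range(20)
GRID = (0.0, 0.25, 0.5, 1.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for eta in GRID:
        for seed in SEEDS:
            subj = simulate_subject(
                EffectSpec(eta_holistic=eta, gamma_city=0.5), rng_seed=100 + seed
            )
            z = holistic_scores(subj)
            rows.append({"eta_holistic": eta, "seed": seed, **z,
                         "contrast": z["unique_within"] - z["unique_between"]})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "holistic_recovery.tsv", sep="\t", index=False)
    summary = df.groupby("eta_holistic")[["unique_within", "shared_within",
                                          "unique_between", "contrast"]].mean()
    print(summary.round(4))
    print("\ncontrast grows with planted strength:",
          bool(np.all(np.diff(summary["contrast"]) > -0.01)))


if __name__ == "__main__":
    main()
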