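#!/usr/bin/env python
"""Heterogeneity and treatment-effect statistics on the fitted populations.

Consumes the per-population fitted-D tables written by
02_multispecies_pipeline.py and asks the experiment's two questions:

* do distinct membrane species diffuse with distinguishable D5
  distributions (pairwise two-sample K-S within each condition)?
* does cholesterol depletion change each species' distribution
  (same-species across-condition K-S), and by how much do the population
  mean and the MAD shrink?

Writes results/pairwise_ks.csv and prints the comparison table.
"""

from itertools import combinations
from pathlib import Path

import pandas as pd

from qdspt.popstats import compare_conditions

RESULTS = Path(__file__).resolve().parents[1] / "results"
SPECIES = ["GM1", "CD59", "EGFR"]
CONDITIONS = ["untreated", "mbCD"]


def main() -> None:
    pops = {}
    for sp in SPECIES:
        for cond in CONDITIONS:
            path = RESULTS / f"fits_{sp}_{cond}.csv"
            if not path.exists():
                raise SystemExit(
                    f"{path} missing - run 02_multispecies_pipeline.py first")
            pops[f"{sp} ({cond})"] = pd.read_csv(path)["D5_um2_s"].to_numpy()

    pairs = [(f"{sp} (untreated)", f"{sp} (mbCD)") for sp in SPECIES]
    for cond in CONDITIONS:
        pairs += [(f"{a} ({cond})", f"{b} ({cond})")
                  for a, b in combinations(SPECIES, 2)]

    comparisons, table = compare_conditions(pops, pairs=pairs)
    table.to_csv(RESULTS / "pairwise_ks.csv", index=False)

    print("Pairwise two-sample K-S tests on fitted D5 populations "
          "(alpha = 0.05):\n")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    treat = table.iloc[:len(SPECIES)]
    print("\nEffect of cholesterol depletion per species:")
    for row in treat.itertuples():
        print(f"  {row.label_1} -> {row.label_2}: mean D5 change "
              f"{row.mean_change_pct:+.0f}%, MAD change "
              f"{row.mad_change_pct:+.0f}%, "
              f"{'significant' if row.significant else 'not significant'} "
              f"(p = {row.p_value:.2g})")


if __name__ == "__main__":
    main()
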