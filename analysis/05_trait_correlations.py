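#!/usr/bin/env python
"""Correlates photosynthetic capacity with biochemical, diffusional and
anatomical traits, and checks cross-year agreement of the fits.

Species-mean regressions of Amax and An(400) against every other trait
(Pearson r with two-sided p), plus per-tree 2022-vs-2024 agreement for the
biochemical parameters. Writes results/05_correlations.csv and
results/05_year_agreement.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from oakleaf.phylocomp import PhyloError, pearson_regression

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    means = pd.read_csv(RESULTS / "04_species_means.csv")
    rows = []
    skip = {"species", "habit"}
    for response in ("amax", "an_400"):
        for trait in means.columns:
            if trait in skip or trait == response:
                continue
            x = means[trait].to_numpy(dtype=float)
            y = means[response].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            try:
                rows.append({"response": response, "trait": trait,
                             **pearson_regression(x[ok], y[ok])})
            except PhyloError:
                continue
    corr = pd.DataFrame(rows)
    corr.to_csv(RESULTS / "05_correlations.csv", index=False)
    strong = corr[(corr.p <= 0.05)].sort_values("p")
    print("species-mean correlates of photosynthetic capacity (p <= 0.05):")
    print(strong.round({"slope": 3, "intercept": 2, "r": 3, "p": 4})
          .to_string(index=False))

    fits = pd.read_csv(RESULTS / "02_per_leaf_fits.csv")
    a = fits[fits.year == 2022]
    b = fits[fits.year == 2024]
    joined = a.merge(b, on=["species", "tree_id"], suffixes=("_22", "_24"))
    rows = []
    for trait in ("vcmax", "jmax", "tpu", "amax"):
        x = joined[f"{trait}_22"].to_numpy(dtype=float)
        y = joined[f"{trait}_24"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            continue
        rows.append({"trait": trait, **pearson_regression(x[ok], y[ok])})
    agree = pd.DataFrame(rows)
    agree.to_csv(RESULTS / "05_year_agreement.csv", index=False)
    print("\n2022 vs 2024 agreement of biochemical parameters:")
    print(agree.round({"slope": 2, "intercept": 2, "r": 3, "p": 4})
          .to_string(index=False))


if __name__ == "__main__":
    main()
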