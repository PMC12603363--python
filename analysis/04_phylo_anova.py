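#!/usr/bin/env python
"""Phylogenetic ANOVA of species-mean traits between leaf habits.

Merges the 2022 per-leaf fits, anatomy traits and morphology, averages to
species means, and tests every trait against habit with PGLS + RRPP
(1000 permutations) on the pruned six-species tree. Writes
results/04_species_means.csv and results/04_phylo_anova.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from oakleaf.io import read_newick
from oakleaf.phylocomp import pgls_anova, prune_tree, species_means
from oakleaf.pipeline import ANOVA_TRAITS

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 11


def main() -> None:
    fits = pd.read_csv(RESULTS / "02_per_leaf_fits.csv")
    anat = pd.read_csv(RESULTS / "03_anatomy_traits.csv")
    morph = pd.read_csv(RESULTS / "campaign" / "morphology.csv")
    per_tree = (fits[fits.year == 2022]
                .merge(anat, on="tree_id")
                .merge(morph[["tree_id", "lma"]], on="tree_id"))
    per_tree["amax_per_thickness"] = per_tree.amax / per_tree.l_leaf
    per_tree["amax_per_mass"] = per_tree.amax / per_tree.lma

    means = species_means(per_tree)
    means.to_csv(RESULTS / "04_species_means.csv", index=False)
    tree = prune_tree(read_newick(RESULTS / "campaign" / "phylogeny.nwk"),
                      set(means.species))

    rows = []
    for i, trait in enumerate(ANOVA_TRAITS + ("amax_per_thickness",
                                              "amax_per_mass")):
        if trait not in means.columns or means[trait].isna().any():
            continue
        r = pgls_anova(means, trait, tree, n_perm=1000, seed=SEED + i)
        rows.append({"trait": trait, "F": r.f_statistic, "p": r.p_value,
                     "n_perm": r.n_permutations, "seed": r.seed,
                     "mean_deciduous": r.group_means.get("deciduous", np.nan),
                     "mean_evergreen": r.group_means.get("evergreen", np.nan)})
    out = pd.DataFrame(rows).sort_values("p")
    out.to_csv(RESULTS / "04_phylo_anova.csv", index=False)
    print("phylogenetic ANOVA (sorted by p):")
    print(out.round({"F": 2, "p": 3, "mean_deciduous": 3,
                     "mean_evergreen": 3}).to_string(index=False))
    sig = out[out.p <= 0.05].trait.tolist()
    print(f"\ntraits differing between habits at p <= 0.05: {sig}")


if __name__ == "__main__":
    main()
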