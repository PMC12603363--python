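#!/usr/bin/env python
"""Generate the synthetic two-season oak campaign.

Six species (three deciduous/evergreen sister pairs), three trees each:
FvCB-consistent A-Ci curves for 2022 (9 setpoints) and 2024 (13 setpoints)
with An noise of 0.5 umol m-2 s-1, one labeled leaf phantom per tree for
2022, a per-tree morphology table, and the pruned phylogeny.

Tables go to results/campaign; the (binary) phantom TIFF stacks go to
scratch/phantom_stacks and are regenerated on demand.
"""

import shutil
from pathlib import Path

import pandas as pd

from oakleaf.pipeline import generate_study_dataset

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "campaign"
STACKS = ROOT / "scratch" / "phantom_stacks"
SEED = 20240601


def main() -> None:
    paths = generate_study_dataset(OUT, seed=SEED, n_trees=3, noise_sd=0.5,
                                   years=(2022, 2024), with_stacks=True)
    # keep binary stacks out of the results tree
    STACKS.parent.mkdir(exist_ok=True)
    if STACKS.exists():
        shutil.rmtree(STACKS)
    shutil.move(paths["stack_dir"], STACKS)

    gas = pd.read_csv(paths["gas_table"])
    print(f"campaign seed {SEED}")
    print(f"  gas-exchange rows: {len(gas)} "
          f"({gas.groupby('year').size().to_dict()} points per year)")
    print(f"  trees: {gas.tree_id.nunique()}, species: {gas.species.nunique()}")
    print(f"  tables under {OUT}")
    print(f"  phantom stacks under {STACKS}")


if __name__ == "__main__":
    main()
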