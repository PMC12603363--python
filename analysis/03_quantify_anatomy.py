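#!/usr/bin/env python
"""Quantify mesophyll anatomy from the labeled phantom stacks.

Per tree: tissue volumes, cell-airspace interface areas (face-count
estimator), porosity, volume ratios and leaf thickness. Writes
results/03_anatomy_traits.csv.
"""

from pathlib import Path

import pandas as pd

from oakleaf.anatomy3d import anatomy_traits
from oakleaf.io import read_label_stack

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
STACKS = ROOT / "scratch" / "phantom_stacks"


def main() -> None:
    if not STACKS.exists():
        raise SystemExit("no phantom stacks found; run 01_simulate_campaign.py")
    rows = []
    for tif in sorted(STACKS.glob("*.tif")):
        vol = read_label_stack(tif, tif.with_suffix(".yaml"))
        tr = anatomy_traits(vol, seed=0)
        rows.append({"tree_id": tif.stem, **tr.as_dict()})
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "03_anatomy_traits.csv", index=False)
    morph = pd.read_csv(RESULTS / "campaign" / "morphology.csv")
    merged = out.merge(morph[["tree_id", "habit"]], on="tree_id")
    print(f"quantified {len(out)} leaf volumes")
    print(merged.groupby("habit")[
        ["theta_ias", "p_to_m", "s_to_m", "s_to_p", "sa_mes_total", "l_leaf"]
    ].mean().round(3).to_string())


if __name__ == "__main__":
    main()
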