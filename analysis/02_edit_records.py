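#!/usr/bin/env python
"""Edit the simulated records: ranges, minimum counts, CG connectedness.

The stature records pass the biological-range filter (119-155 cm) and the
evaluator / contemporary-group minimum-count filters (fewer than five
records removes the level), then the connectedness filter (a CG needs ten
or more genetic links into the largest connected component to stay).
Score traits skip the range filter.  Writes the edited records and the
per-rule removal counts under results/edited/.
"""

from pathlib import Path

import pandas as pd

from pedeval.editing import apply_editing_plan
from pedeval.pedigree import read_pedigree_csv

DATA = Path("results/data")
OUT = Path("results/edited")

TRAITS = {
    "stature": {"ranges": {"stature": (119, 155)}, "score": ()},
    "milking_ease": {"ranges": {}, "score": ("milking_ease",)},
}


def main():
    for trait, opts in TRAITS.items():
        ped = read_pedigree_csv(DATA / trait / "pedigree.csv")
        rec = pd.read_csv(DATA / trait / "phenotypes.csv")
        edited, report = apply_editing_plan(
            rec, ped, cg_in_model=True, trait_ranges=opts["ranges"],
            score_traits=opts["score"])
        outdir = OUT / trait
        outdir.mkdir(parents=True, exist_ok=True)
        edited.to_csv(outdir / "phenotypes_edited.csv", index=False)
        report.to_frame().to_csv(outdir / "edit_report.csv", index=False)
        print(f"{trait}: {report.input_count} records in, "
              f"{report.surviving} surviving; removed by rule: "
              f"{report.removed}")


if __name__ == "__main__":
    main()
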