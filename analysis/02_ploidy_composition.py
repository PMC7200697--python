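#!/usr/bin/env python
"""Run the full imaging ploidy pipeline on both strain configurations.

For each animal: render three-channel frames, segment nuclei (pooled
log-Otsu threshold), group nuclei into cells by marker masks, normalize
intensities to the CD31+ endothelial median, window into 2n/4n/8n, and
summarize nucleation x ploidy composition.  Writes per-animal compositions
to ``results/composition.csv`` and the between-strain Student t-tests to
``results/comparisons.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from ploidyscope import ploidy_calling as pc
from ploidyscope.pipeline import imaging_study_composition

STRAINS = ("BALB_cJ", "BALB_cByJ")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--n-animals", type=int, default=5)
    ap.add_argument("--n-cells", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohorts = {
        strain: imaging_study_composition(
            strain,
            n_animals=args.n_animals,
            n_cells=args.n_cells,
            n_reference=150,
            seed=args.seed,
        )
        for strain in STRAINS
    }
    rows = []
    for strain, comps in cohorts.items():
        for comp in comps:
            rows.append({"strain": strain, **comp.to_row()})
    composition = pd.DataFrame(rows)
    composition.to_csv(args.out / "composition.csv", index=False)

    cmp_rows = []
    for metric in ("mononuclear_fraction", "mono_pct2n", "diploid_cell_fraction"):
        res = pc.compare_groups(
            [c.__dict__[metric] for c in cohorts["BALB_cJ"]],
            [c.__dict__[metric] for c in cohorts["BALB_cByJ"]],
            metric,
        )
        cmp_rows.append(vars(res))
        print(
            f"{metric:>24}: cJ-like {res.mean_a:5.1f}±{res.sd_a:4.2f}  "
            f"cByJ-like {res.mean_b:5.1f}±{res.sd_b:4.2f}  "
            f"t={res.t:7.2f} df={res.df} p={res.p:.2e}"
        )
    pd.DataFrame(cmp_rows).to_csv(args.out / "comparisons.csv", index=False)

    means = composition.groupby("strain")[
        ["mononuclear_fraction", "mono_pct2n", "diploid_cell_fraction"]
    ].mean().round(1)
    print("\nPer-strain means:\n", means)
    print(
        "\nThe two configurations differ >2-fold in mononuclear share but in "
        "opposite direction in mono-nuclear diploidy, so their diploid-cell "
        "levels are similar."
    )


if __name__ == "__main__":
    main()
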