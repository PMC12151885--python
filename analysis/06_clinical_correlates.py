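#!/usr/bin/env python
"""Spearman screen of composite aging scores against clinical covariates.

Restricts to subjects scored in at least four of the six blocks, correlates
each compartment composite with each clinical covariate (height-adjusted
partial Spearman for the stature-dependent walk metric), and exports the
p < 0.10 heat-map table with significance tiers.
"""

import argparse
from pathlib import Path

import pandas as pd

from omicage import correlates as co
from omicage import scores as sc
from omicage import synthetic as syn


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-blocks", type=int, default=4)
    args = ap.parse_args()

    _, metadata, truth = syn.read_cohort(args.results / "cohort")
    z = pd.read_csv(args.results / "scores" / "z_scores.csv", index_col=0)
    z.index = z.index.astype(str)
    comp = pd.read_csv(args.results / "scores" / "composite_scores.csv", index_col=0)
    comp.index = comp.index.astype(str)
    out = args.results / "correlates"
    out.mkdir(parents=True, exist_ok=True)

    table = sc.AgingScoreTable(raw=z, z=z, flags=z.notna().astype(str))
    keep = co.filter_min_blocks(table, min_blocks=args.min_blocks)
    print(f"{len(keep)} of {len(z)} subjects scored in >= {args.min_blocks} blocks")

    clinical_cols = [c for c in metadata.columns if c not in ("age", "sex", "race", "bmi")]
    screen = co.spearman_screen(
        comp.loc[keep], metadata.loc[keep, clinical_cols],
        adjust={"walk_speed": ["height"]},
    )
    screen.to_csv(out / "spearman_screen.csv", index=False)
    hits = co.heatmap_table(screen, p_max=0.10)
    hits.to_csv(out / "heatmap_table.csv", index=False)

    print(f"{len(hits)} covariate x compartment cells at p < 0.10:")
    if not hits.empty:
        print(hits[["covariate", "compartment", "rho", "p_value", "tier"]]
              .round(3).to_string(index=False))
    if truth is not None and truth.clinical_loadings is not None:
        signs = hits.merge(
            truth.clinical_loadings.rename("true_loading"), left_on="covariate",
            right_index=True, how="left",
        )
        consistent = ((signs["rho"] * signs["true_loading"]) > 0) | (signs["true_loading"] == 0)
        print(f"direction consistent with generator couplings in "
              f"{consistent.sum()}/{len(signs)} hits")


if __name__ == "__main__":
    main()
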