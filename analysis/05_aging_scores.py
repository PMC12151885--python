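#!/usr/bin/env python
"""Aging scores, |z| > 1.5 acceleration flags, composites, and concordance.

Residualizes each block's out-of-bag predicted age on chronological age,
column-standardizes the scores, flags accelerated/decelerated subjects,
averages omic z-scores into compartment composites, and reports how well
the composites recover the generator's latent biological-age deviation.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from omicage import scores as sc
from omicage import synthetic as syn


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    _, metadata, truth = syn.read_cohort(args.results / "cohort")
    clocks = args.results / "clocks"
    out = args.results / "scores"
    out.mkdir(parents=True, exist_ok=True)

    raw = pd.DataFrame(index=metadata.index)
    for path in sorted(clocks.glob("*_oob_predictions.csv")):
        name = path.name.replace("_oob_predictions.csv", "")
        preds = pd.read_csv(path, index_col=0)
        preds.index = preds.index.astype(str)
        raw[name] = sc.compute_scores(preds["oob_mean"], preds["age"])

    table = sc.flag_acceleration(raw, z_cut=1.5)
    table.z.to_csv(out / "z_scores.csv", index_label="sample_id")
    table.flags.to_csv(out / "flags.csv", index_label="sample_id")
    counts = table.flag_counts()
    print("flag counts per block:")
    print(counts.to_string())

    comp = sc.composite_scores(table)
    comp.to_csv(out / "composite_scores.csv", index_label="sample_id")
    bcorr, bp = sc.score_correlation_matrix(table.z)
    bcorr.to_csv(out / "block_score_correlation.csv")
    bp.to_csv(out / "block_score_correlation_p.csv")
    ccorr, _ = sc.score_correlation_matrix(comp)
    ccorr.to_csv(out / "compartment_score_correlation.csv")

    off = bcorr.to_numpy()[~np.eye(len(bcorr), dtype=bool)]
    off = off[~np.isnan(off)]
    print(f"cross-block score correlations: mean {off.mean():.2f}, min {off.min():.2f}")
    if truth is not None:
        overall = comp.mean(axis=1)
        ok = overall.notna()
        r = np.corrcoef(overall[ok], truth.delta[ok])[0, 1]
        print(f"overall composite vs true latent deviation: r = {r:.2f}")
    print(f"score tables written to {out}/")


if __name__ == "__main__":
    main()
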