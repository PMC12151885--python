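#!/usr/bin/env python
"""LOOCV refit of the plasma signature and a cross-platform intersection.

Refits the frequency-ordered plasma proteomic signature with an
unregularized leave-one-out linear model and reports the correlation
between chronological and LOOCV-predicted age; then intersects the
signature with a synthetic alternate-platform catalog (every second
feature of the block) to emulate transfer to a partial-overlap assay.
"""

import argparse
from pathlib import Path

import pandas as pd

from omicage import preprocess as pp
from omicage import synthetic as syn
from omicage import validation as va


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--block", default="plasma_proteomics")
    args = ap.parse_args()

    from omicage.io import read_blocks
    blocks = read_blocks(args.results / "clean")
    _, metadata, _ = syn.read_cohort(args.results / "cohort")
    block = next(b for b in blocks if b.name == args.block)
    sig = pd.read_csv(args.results / "clocks" / f"{args.block}_signature.csv")
    out = args.results / "validation"
    out.mkdir(parents=True, exist_ok=True)

    if sig.empty:
        # reduced permutation schedules can leave the significance-filtered
        # signature empty; fall back to the top features by selection frequency
        stats = pd.read_csv(args.results / "clocks" / f"{args.block}_feature_stats.csv")
        sig = stats[stats["freq"] > 0].head(25)
        print(f"{args.block}: significance-filtered signature empty; "
              f"using top {len(sig)} features by selection frequency")
    features = [f for f in sig["feature_id"] if f in block.values.columns]
    limit = block.n_samples - 2
    if len(features) > limit:
        features = features[:limit]
    if not features:
        print(f"{args.block}: no usable signature features; nothing to refit")
        return
    Xsig = pp.mean_impute(block.subset_features(features)).values
    loo = va.loocv_predict(Xsig, metadata.loc[block.sample_ids, "age"])
    pd.DataFrame({"loocv_pred": loo.predictions,
                  "age": metadata.loc[block.sample_ids, "age"]}).to_csv(
        out / f"{args.block}_loocv_predictions.csv", index_label="sample_id")
    print(f"{args.block}: LOOCV refit of {len(features)}-feature signature, "
          f"r = {loo.r:.3f} (p = {loo.p_value:.2g})")

    catalog = block.feature_ids[::2]  # synthetic alternate-platform catalog
    inter = va.intersect_features(list(sig["feature_id"]), catalog)
    pd.DataFrame({"feature_id": inter.overlap}).to_csv(
        out / f"{args.block}_platform_overlap.csv", index=False)
    print(f"platform intersection: {inter.n_overlap}/{len(sig)} signature features "
          f"present on the alternate catalog")


if __name__ == "__main__":
    main()
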