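"""Quality control and normalization of block matrices.

The QC policy mirrors standard affinity-proteomics practice: drop features
measured below the limit of detection in more than 70% of samples (strictly
greater than), drop assays whose standardized deviation from negative
controls exceeds the ensemble mean by 4 SD, optionally normalize a urine
block by a reference dilution marker (Cystatin-C-style), and run a
standardized PCA across blocks for outlier/compartment overview.

No operation mutates its input; each returns a fresh block and, where
relevant, a report table of what was removed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .blocks import OmicsBlock

log = logging.getLogger(__name__)

__all__ = [
    "filter_lod",
    "qc_exclude_assays",
    "normalize_by_reference",
    "mean_impute",
    "pca_overview",
]


def filter_lod(
    block: OmicsBlock, max_frac_below: float = 0.70
) -> tuple[OmicsBlock, pd.DataFrame]:
    """Drop features below the LOD in strictly more than ``max_frac_below`` of samples.

    Returns the filtered block and a report with the below-LOD fraction and
    dropped status of every feature. Idempotent: a second application removes
    nothing further.
    """
    frac = block.below_lod.mean(axis=0)
    dropped = frac > max_frac_below
    report = pd.DataFrame(
        {"frac_below_lod": frac, "dropped": dropped}
    ).rename_axis("feature_id")
    keep = [f for f, d in dropped.items() if not d]
    if not keep:
        log.warning("filter_lod: all %d features dropped in block %r", block.n_features, block.name)
    out = block.subset_features(keep)
    log.info(
        "filter_lod[%s]: %d -> %d features (dropped %d at frac > %.2f)",
        block.name, block.n_features, out.n_features, int(dropped.sum()), max_frac_below,
    )
    return out, report


def qc_exclude_assays(
    block: OmicsBlock,
    control_deviation: pd.Series | None = None,
    sd_cut: float = 4.0,
) -> tuple[OmicsBlock, pd.DataFrame]:
    """Drop assays deviating from negative controls by more than ``sd_cut`` SD.

    ``control_deviation`` is a per-feature standardized deviation from plate
    negative controls; features strictly above ``mean + sd_cut * SD`` of that
    vector (population SD) are removed. If no control vector exists — as for
    synthetic cohorts, which carry no plate controls — the block is returned
    unchanged with a logged notice.
    """
    if control_deviation is None:
        log.info("qc_exclude_assays[%s]: no control vector supplied; skipped", block.name)
        return block.copy(), pd.DataFrame(
            columns=["control_deviation", "dropped"]
        ).rename_axis("feature_id")
    dev = control_deviation.reindex(block.feature_ids)
    if dev.isna().any():
        missing = dev.index[dev.isna()].tolist()
        raise KeyError(f"control_deviation missing features: {missing[:5]}")
    threshold = dev.mean() + sd_cut * dev.std(ddof=0)
    dropped = dev > threshold
    report = pd.DataFrame(
        {"control_deviation": dev, "dropped": dropped}
    ).rename_axis("feature_id")
    out = block.subset_features([f for f, d in dropped.items() if not d])
    log.info(
        "qc_exclude_assays[%s]: %d -> %d features (threshold %.3f)",
        block.name, block.n_features, out.n_features, threshold,
    )
    return out, report


def normalize_by_reference(block: OmicsBlock, reference_feature: str) -> OmicsBlock:
    """Subtract a reference feature column from every feature (log scale).

    Used to remove per-sample dilution (e.g. urinary Cystatin C): on the log
    scale a common per-sample offset cancels exactly. The reference column is
    removed from the output. Raises if the reference is absent or has
    missing values.
    """
    if reference_feature not in block.values.columns:
        raise KeyError(
            f"reference feature {reference_feature!r} not in block {block.name!r}"
        )
    ref = block.values[reference_feature]
    if ref.isna().any():
        raise ValueError(
            f"reference feature {reference_feature!r} has missing values; cannot normalize"
        )
    values = block.values.sub(ref, axis=0).drop(columns=[reference_feature])
    mask = block.below_lod.drop(columns=[reference_feature])
    return OmicsBlock(values=values, below_lod=mask.copy(), name=block.name)


def mean_impute(block: OmicsBlock) -> OmicsBlock:
    """Replace missing entries with the feature's cohort mean.

    Features that are entirely missing are set to 0. Intended for stages
    (PCA, per-feature OLS on complete designs) that cannot carry NaNs; the
    clock performs its own fold-honest imputation instead.
    """
    values = block.values.copy()
    means = values.mean(axis=0)
    values = values.fillna(means).fillna(0.0)
    return OmicsBlock(values=values, below_lod=block.below_lod.copy(), name=block.name)


def pca_overview(
    blocks: list[OmicsBlock], n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Standardized PCA of all samples across blocks, on shared features.

    Rows from every block are stacked on the intersection of their feature
    IDs (each block contributes one observation per sample, labelled with the
    block name); when blocks share no features, each block's features are
    concatenated column-wise by position instead — useful only for blocks of
    equal width. Features are centred and scaled to unit variance; missing
    entries are mean-imputed (hence 0 after centring).

    Returns a table with columns ``block``, ``sample_id``, ``PC1..PCk`` and
    the explained-variance fractions.
    """
    if not blocks:
        raise ValueError("pca_overview needs at least one block")
    shared = set(blocks[0].feature_ids)
    for b in blocks[1:]:
        shared &= set(b.feature_ids)
    frames = []
    labels = []
    if shared:
        cols = sorted(shared)
        for b in blocks:
            frames.append(b.values.loc[:, cols])
            labels.extend([(b.name, s) for s in b.sample_ids])
        stacked = pd.concat(frames, axis=0, ignore_index=True)
    else:
        widths = {b.n_features for b in blocks}
        if len(widths) != 1:
            raise ValueError(
                "pca_overview: blocks share no feature IDs and differ in width"
            )
        for b in blocks:
            frames.append(pd.DataFrame(b.values.to_numpy()))
            labels.extend([(b.name, s) for s in b.sample_ids])
        stacked = pd.concat(frames, axis=0, ignore_index=True)
    if stacked.shape[0] < 2:
        raise ValueError("pca_overview needs at least 2 stacked samples")

    x = stacked.to_numpy(dtype=float)
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    x -= x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x /= sd

    k = min(n_components, min(x.shape) - 0)
    k = min(k, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    table = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(k)]
    )
    table.insert(0, "sample_id", [s for (_, s) in labels])
    table.insert(0, "block", [b for (b, _) in labels])
    return table, pca.explained_variance_ratio_
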