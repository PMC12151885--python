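"""Delimited-text readers and writers.

Matrices are CSV with the sample ID as the first column and feature IDs as
the header row; the below-LOD mask is an optional sibling file
``<stem>.lod.csv`` with the same layout (0/1 entries). Metadata tables are
CSV keyed by sample ID.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .blocks import OmicsBlock

log = logging.getLogger(__name__)

SAMPLE_COL = "sample_id"


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate {what} {dup}")


def write_block(block: OmicsBlock, path: str | Path, overwrite: bool = True) -> Path:
    """Write a block matrix (and its mask, if any cell is censored) to CSV."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    path.parent.mkdir(parents=True, exist_ok=True)
    block.values.to_csv(path, index_label=SAMPLE_COL)
    if block.below_lod.to_numpy().any():
        mask_path = path.with_suffix(".lod.csv")
        block.below_lod.astype(int).to_csv(mask_path, index_label=SAMPLE_COL)
    return path


def read_block(path: str | Path, name: str | None = None) -> OmicsBlock:
    """Read a block matrix from CSV, picking up ``<stem>.lod.csv`` if present."""
    path = Path(path)
    values = pd.read_csv(path, index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    _check_unique(values.index, "sample IDs", path)
    _check_unique(values.columns, "feature IDs", path)
    mask_path = path.with_suffix(".lod.csv")
    mask = None
    if mask_path.exists():
        mask = pd.read_csv(mask_path, index_col=0).astype(bool)
        mask.index = mask.index.astype(str)
        mask.columns = mask.columns.astype(str)
        # re-align by ID so row order on disk is immaterial
        mask = mask.reindex(index=values.index, columns=values.columns).fillna(False)
    else:
        log.debug("%s: no mask file, assuming nothing below LOD", path)
    if name is None:
        name = path.stem
    return OmicsBlock(values=values, below_lod=mask, name=name)


def read_blocks(dir_path: str | Path) -> list["OmicsBlock"]:
    """Read every block matrix CSV in a directory (masks picked up by stem)."""
    dir_path = Path(dir_path)
    blocks = []
    for path in sorted(dir_path.glob("*.csv")):
        if path.name.endswith(".lod.csv") or path.name in (
            "metadata.csv", "ground_truth_delta.csv", "ground_truth_features.csv",
            "ground_truth_clinical.csv",
        ):
            continue
        blocks.append(read_block(path))
    return blocks


def write_metadata(metadata: pd.DataFrame, path: str | Path, overwrite: bool = True) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    path.parent.mkdir(parents=True, exist_ok=True)
    metadata.to_csv(path, index_label=SAMPLE_COL)
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, index_col=0)
    meta.index = meta.index.astype(str)
    _check_unique(meta.index, "sample IDs", path)
    return meta


def align_block_to_metadata(block: OmicsBlock, metadata: pd.DataFrame) -> tuple[OmicsBlock, pd.DataFrame]:
    """Join a block with metadata on sample ID, in the block's row order.

    Raises if any block sample is missing from the metadata.
    """
    missing = [s for s in block.sample_ids if s not in metadata.index]
    if missing:
        raise KeyError(f"block {block.name!r}: samples absent from metadata: {missing[:5]}")
    return block, metadata.loc[block.sample_ids]
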