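"""Core containers for compartment/omic abundance matrices.

An :class:`OmicsBlock` holds one samples x features matrix of log-scale
relative abundances (e.g. Olink NPX or log metabolite intensities) for one
compartment/omic combination ("block"), together with a same-shaped boolean
below-limit-of-detection mask. Sample metadata (age, sex, race, BMI, clinical
covariates) lives in a plain :class:`pandas.DataFrame` keyed by sample ID and
is joined to blocks on that key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsBlock", "block_compartment", "block_omic"]


@dataclass
class OmicsBlock:
    """One compartment/omic abundance matrix with a below-LOD mask.

    Parameters
    ----------
    values
        Samples x features matrix of log-scale abundances; index are sample
        IDs, columns are feature IDs. Entries may be NaN where censored.
    below_lod
        Boolean mask of the same shape; ``True`` marks a measurement below
        the assay's limit of detection. If omitted, all ``False``.
    name
        Block label, conventionally ``"<compartment>_<omic>"`` such as
        ``"plasma_proteomics"``.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame | None = None
    name: str = "block"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.below_lod.shape != self.values.shape:
            raise ValueError(
                f"block {self.name!r}: below_lod shape {self.below_lod.shape} "
                f"!= values shape {self.values.shape}"
            )
        if not self.below_lod.index.equals(self.values.index) or not (
            self.below_lod.columns.equals(self.values.columns)
        ):
            self.below_lod = self.below_lod.reindex(
                index=self.values.index, columns=self.values.columns
            ).fillna(False)
        for axis, ids in (("sample", self.values.index), ("feature", self.values.columns)):
            if ids.has_duplicates:
                dup = ids[ids.duplicated()].unique().tolist()
                raise ValueError(f"block {self.name!r}: duplicate {axis} IDs {dup}")
        finite = self.values.to_numpy(dtype=float)
        bad = np.isinf(finite)
        if bad.any():
            raise ValueError(f"block {self.name!r}: non-finite abundance values present")
        self.below_lod = self.below_lod.astype(bool)

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "OmicsBlock":
        return OmicsBlock(self.values.copy(), self.below_lod.copy(), self.name)

    def subset_features(self, feature_ids) -> "OmicsBlock":
        """Return a new block restricted to ``feature_ids`` (order preserved)."""
        feature_ids = list(feature_ids)
        return OmicsBlock(
            self.values.loc[:, feature_ids].copy(),
            self.below_lod.loc[:, feature_ids].copy(),
            self.name,
        )


def block_compartment(name: str) -> str:
    """Compartment part of a ``"<compartment>_<omic>"`` block label."""
    return name.rsplit("_", 1)[0]


def block_omic(name: str) -> str:
    """Omic part of a ``"<compartment>_<omic>"`` block label."""
    parts = name.rsplit("_", 1)
    return parts[1] if len(parts) == 2 else ""
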