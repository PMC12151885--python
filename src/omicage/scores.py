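"""Aging scores: departures from the cohort-expected predicted age.

A subject's raw aging score in a block is the residual of their mean
out-of-bag predicted age from the cohort OLS line of predicted age on
chronological age — the "expected predicted age" for someone of that
chronological age. Residualizing (rather than taking predicted minus
chronological age directly) removes both constant calibration bias and the
regression-to-the-mean compression that shrinks predictions toward the
cohort mean. Scores are column-standardized per block; |z| > 1.5 flags
accelerated (positive) or decelerated (negative) biological aging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import block_compartment

log = logging.getLogger(__name__)

__all__ = [
    "compute_scores",
    "flag_acceleration",
    "composite_scores",
    "score_correlation_matrix",
    "AgingScoreTable",
]

FLAG_ACCELERATED = "accelerated"
FLAG_DECELERATED = "decelerated"
FLAG_NONE = "none"
FLAG_MISSING = "missing"


def compute_scores(oob_mean: pd.Series, age: pd.Series) -> pd.Series:
    """Raw aging scores: residuals of OOB predicted age on chronological age.

    ``raw_i = oob_i - (a + b * age_i)`` with (a, b) the cohort least-squares
    fit of prediction on age. Scores sum to zero exactly (up to float
    round-off). Requires >= 3 subjects and non-constant age.
    """
    oob_mean, age = oob_mean.align(age, join="inner")
    if len(oob_mean) < 3:
        raise ValueError("compute_scores needs at least 3 subjects")
    a = age.to_numpy(dtype=float)
    o = oob_mean.to_numpy(dtype=float)
    if np.std(a) == 0:
        raise ValueError("age is constant; expected-prediction line undefined")
    b = np.cov(a, o, ddof=0)[0, 1] / np.var(a)
    intercept = o.mean() - b * a.mean()
    raw = o - (intercept + b * a)
    return pd.Series(raw, index=oob_mean.index, name="raw_score")


@dataclass
class AgingScoreTable:
    """Subject x block score tables: raw years, column z, and flags."""

    raw: pd.DataFrame  # subject x block, NaN where unmeasured
    z: pd.DataFrame
    flags: pd.DataFrame  # strings in {accelerated, decelerated, none, missing}
    z_cut: float = 1.5

    def flag_counts(self) -> pd.DataFrame:
        """Per-block counts of each flag value (columns sum to n subjects)."""
        return self.flags.apply(pd.Series.value_counts).fillna(0).astype(int)


def flag_acceleration(raw_scores: pd.DataFrame, z_cut: float = 1.5) -> AgingScoreTable:
    """Column-standardize raw scores and flag |z| > ``z_cut`` deviations.

    Standardization is over the non-missing entries of each block column;
    missing entries are flagged ``missing``. Raises on a zero-variance
    column (fewer than 2 non-missing values or all equal).
    """
    raw = raw_scores.copy()
    z = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        vals = raw[col]
        ok = vals.notna()
        if ok.sum() < 2:
            raise ValueError(f"column {col!r}: fewer than 2 non-missing scores")
        sd = vals[ok].std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {col!r}: zero variance; z-scores undefined")
        z[col] = (vals - vals[ok].mean()) / sd
    flags = pd.DataFrame(FLAG_NONE, index=raw.index, columns=raw.columns)
    flags = flags.mask(z > z_cut, FLAG_ACCELERATED)
    flags = flags.mask(z < -z_cut, FLAG_DECELERATED)
    flags = flags.mask(z.isna(), FLAG_MISSING)
    return AgingScoreTable(raw=raw, z=z, flags=flags, z_cut=z_cut)


def composite_scores(table: AgingScoreTable) -> pd.DataFrame:
    """Per-compartment composite: mean of the available omic z-scores.

    Block columns named ``"<compartment>_<omic>"`` are grouped by
    compartment; a subject's composite is the mean of their non-missing
    z-scores in that compartment (equals the single available score if one
    omic is missing; missing if both are).
    """
    groups: dict[str, list[str]] = {}
    for col in table.z.columns:
        groups.setdefault(block_compartment(col), []).append(col)
    out = pd.DataFrame(index=table.z.index)
    for comp, cols in groups.items():
        out[comp] = table.z[cols].mean(axis=1, skipna=True)
    return out


def score_correlation_matrix(
    scores: pd.DataFrame,
    method: str = "pearson",
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation of score columns on pairwise-complete subjects.

    Returns (correlation matrix, p-value matrix); symmetric with unit
    diagonal. Pairs with fewer than ``min_pairs`` complete observations are
    reported as NaN.
    """
    cols = list(scores.columns)
    corr = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, ci in enumerate(cols):
        corr.loc[ci, ci] = 1.0
        pval.loc[ci, ci] = 0.0
        for cj in cols[i + 1 :]:
            pair = scores[[ci, cj]].dropna()
            if len(pair) < min_pairs:
                continue
            if method == "spearman":
                r, p = stats.spearmanr(pair[ci], pair[cj])
            else:
                r, p = stats.pearsonr(pair[ci], pair[cj])
            corr.loc[ci, cj] = corr.loc[cj, ci] = float(r)
            pval.loc[ci, cj] = pval.loc[cj, ci] = float(p)
    return corr, pval
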