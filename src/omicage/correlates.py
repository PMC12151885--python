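"""Screen of composite aging scores against clinical covariates.

Following exploratory-cohort practice, each (compartment score, clinical
covariate) cell is a Spearman rank correlation on pairwise-complete data,
reported without multiple-testing correction at a relaxed p < 0.10
threshold. Physical-performance metrics that depend on stature (walking
distance/speed) are screened with height as an adjustment covariate via a
partial Spearman correlation: both variables are rank-transformed (average
ranks for ties), each is residualized on the ranked adjustment covariates
by OLS, and the Pearson correlation of the residuals is tested with a
t-approximation whose degrees of freedom are reduced by the number of
adjustment covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scores import AgingScoreTable

log = logging.getLogger(__name__)

__all__ = ["filter_min_blocks", "spearman_screen", "heatmap_table", "significance_tier"]


def filter_min_blocks(table: AgingScoreTable, min_blocks: int = 4) -> list[str]:
    """Subjects with scores in at least ``min_blocks`` blocks."""
    n_present = table.z.notna().sum(axis=1)
    return list(table.z.index[n_present >= min_blocks])


def significance_tier(p: float) -> str:
    """Star tier used in the correlate heat map legend."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "(0.05<p<0.10)"
    return ""


def _partial_spearman(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray
) -> tuple[float, float]:
    """Partial Spearman: rank, residualize both on ranked Z, correlate."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    RZ = np.column_stack([np.ones(len(x))] + [stats.rankdata(z) for z in Z.T])
    bx, *_ = np.linalg.lstsq(RZ, rx, rcond=None)
    by, *_ = np.linalg.lstsq(RZ, ry, rcond=None)
    ex = rx - RZ @ bx
    ey = ry - RZ @ by
    if np.std(ex) == 0 or np.std(ey) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(ex, ey)[0, 1])
    df = len(x) - 2 - Z.shape[1]
    if df <= 0 or abs(r) >= 1.0:
        return r, 0.0 if abs(r) >= 1.0 else float("nan")
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


@dataclass
class CorrelateResult:
    covariate: str
    compartment: str
    rho: float
    p_value: float
    tier: str
    n_used: int
    adjusted_for: tuple[str, ...]


def spearman_screen(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    adjust: dict[str, list[str]] | None = None,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman screen of every compartment score against every covariate.

    ``scores`` is subject x compartment, ``clinical`` subject x covariate;
    joined on subject ID, each cell uses pairwise-complete data. ``adjust``
    maps covariate names to lists of adjustment covariate names (drawn from
    ``clinical``), switching that cell to a partial Spearman. Constant
    covariates are reported with NaN rho.
    """
    adjust = adjust or {}
    rows = []
    for cov in clinical.columns:
        adj_names = tuple(adjust.get(cov, ()))
        if cov in adj_names:
            raise ValueError(f"covariate {cov!r} cannot adjust for itself")
        for comp in scores.columns:
            joined = pd.concat(
                [scores[comp], clinical[cov], clinical[list(adj_names)]], axis=1, join="inner"
            ).dropna()
            n = len(joined)
            if n < min_pairs or joined.iloc[:, 1].nunique() <= 1:
                rho, p = float("nan"), float("nan")
            elif adj_names:
                rho, p = _partial_spearman(
                    joined.iloc[:, 0].to_numpy(float),
                    joined.iloc[:, 1].to_numpy(float),
                    joined.iloc[:, 2:].to_numpy(float),
                )
            else:
                rho, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
                rho, p = float(rho), float(p)
            rows.append(
                CorrelateResult(
                    covariate=cov,
                    compartment=comp,
                    rho=rho,
                    p_value=p,
                    tier=significance_tier(p),
                    n_used=n,
                    adjusted_for=adj_names,
                )
            )
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["adjusted_for"] = out["adjusted_for"].map(lambda t: ";".join(t))
    return out


def heatmap_table(results: pd.DataFrame, p_max: float = 0.10) -> pd.DataFrame:
    """Long-format export of screen hits with p below ``p_max``.

    Keeps the signed rho and tier; ``multi_compartment`` marks covariates
    that pass the threshold in more than one compartment (rendered bold in
    the figure convention).
    """
    if results.empty:
        return results.assign(multi_compartment=pd.Series(dtype=bool))
    hits = results[results["p_value"] < p_max].copy()
    counts = hits.groupby("covariate")["compartment"].nunique()
    hits["multi_compartment"] = hits["covariate"].map(counts).fillna(0).astype(int) > 1
    return hits.sort_values(["covariate", "compartment"]).reset_index(drop=True)
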