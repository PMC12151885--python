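"""Per-feature covariate-adjusted age association.

Each feature's log abundance is regressed on chronological age plus nuisance
covariates (sex, race, BMI by default) with ordinary least squares; the
two-sided p-value of the age coefficient is Benjamini-Hochberg adjusted
across features of a block. Features with no missing values share one design
matrix, so their fits are computed in a single vectorised solve; features
with censored entries fall back to per-feature complete-case fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import OmicsBlock

log = logging.getLogger(__name__)

__all__ = [
    "fit_feature_lm",
    "bh_adjust",
    "classify_and_count",
    "compare_visits",
    "volcano_table",
]

DEFAULT_COVARIATES = ("sex", "race", "bmi")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Standard step-up: sort ascending, q_(i) = min over j >= i of
    p_(j) * m / j, capped at 1. Monotone in p and order-preserving under
    ties. Empty input returns an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _build_design(
    metadata: pd.DataFrame, covariates, age_col: str = "age"
) -> tuple[np.ndarray, list[str]]:
    cols = [age_col]
    for c in covariates:
        if c not in metadata.columns:
            raise KeyError(f"covariate {c!r} not in metadata")
        cols.append(c)
    X = metadata[cols].to_numpy(dtype=float)
    keep, names = [0], [age_col]
    for j, c in enumerate(covariates, start=1):
        col = X[:, j]
        if np.nanstd(col) == 0:
            warnings.warn(f"covariate {c!r} is constant; dropped from the design")
            continue
        keep.append(j)
        names.append(c)
    return X[:, keep], names


def _ols_age(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each column of Y on [1 | X]; returns (beta_age, se_age, p)."""
    n = X.shape[0]
    D = np.column_stack([np.ones(n), X])
    k = D.shape[1]
    XtX_inv = np.linalg.pinv(D.T @ D)
    B = XtX_inv @ (D.T @ Y)
    resid = Y - D @ B
    dof = n - k
    if dof <= 0:
        raise ValueError(f"not enough samples (n={n}) for {k} parameters")
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])  # age is column 1 (after intercept)
    beta = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p


def fit_feature_lm(
    block: OmicsBlock,
    metadata: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    age_col: str = "age",
) -> pd.DataFrame:
    """Age association of every feature, adjusted for the given covariates.

    Returns one row per fitted feature: ``beta_age`` (per-year effect on log
    abundance), ``se``, ``p_value``, ``q_value`` (BH across the fitted
    features), ``direction`` (``over``/``under`` by the sign of beta_age) and
    ``n_used``. Features with fewer complete observations than parameters + 1
    are skipped with a notice.
    """
    meta = metadata.loc[block.sample_ids]
    X, names = _build_design(meta, covariates, age_col=age_col)
    Y = block.values.to_numpy(dtype=float)
    n, p = Y.shape
    k = X.shape[1] + 1  # + intercept

    complete = ~np.isnan(Y).any(axis=0)
    out = {
        "feature_id": [], "beta_age": [], "se": [], "p_value": [], "n_used": [],
    }
    if complete.any():
        beta, se, pv = _ols_age(X, Y[:, complete])
        ids = np.asarray(block.feature_ids)[complete]
        out["feature_id"].extend(ids)
        out["beta_age"].extend(beta)
        out["se"].extend(se)
        out["p_value"].extend(pv)
        out["n_used"].extend([n] * ids.size)
    skipped = []
    for j in np.where(~complete)[0]:
        y = Y[:, j]
        ok = ~np.isnan(y)
        if ok.sum() < k + 1:
            skipped.append(block.feature_ids[j])
            continue
        beta, se, pv = _ols_age(X[ok], y[ok, None])
        out["feature_id"].append(block.feature_ids[j])
        out["beta_age"].append(beta[0])
        out["se"].append(se[0])
        out["p_value"].append(pv[0])
        out["n_used"].append(int(ok.sum()))
    if skipped:
        log.info(
            "fit_feature_lm[%s]: skipped %d features with < %d complete observations",
            block.name, len(skipped), k + 1,
        )
    results = pd.DataFrame(out)
    if len(results):
        results = results.set_index("feature_id").loc[
            [f for f in block.feature_ids if f in set(results["feature_id"])]
        ].reset_index()
        results["q_value"] = bh_adjust(results["p_value"].to_numpy())
        results["direction"] = np.where(results["beta_age"] >= 0, "over", "under")
    else:
        results["q_value"] = []
        results["direction"] = []
    results.attrs["covariates"] = names[1:]
    results.attrs["block"] = block.name
    return results


@dataclass
class AgeAssociationSummary:
    n_over: int
    n_under: int
    significant_ids: list[str]


def classify_and_count(
    results: pd.DataFrame, q_cut: float = 0.05, use: str = "q_value"
) -> AgeAssociationSummary:
    """Count significant features by direction.

    ``use`` selects the significance column (``"q_value"`` for BH FDR, the
    default, or ``"p_value"`` for raw p).
    """
    if results.empty:
        raise ValueError("classify_and_count: empty results")
    sig = results[results[use] < q_cut]
    n_over = int((sig["direction"] == "over").sum())
    n_under = int((sig["direction"] == "under").sum())
    return AgeAssociationSummary(n_over, n_under, sig["feature_id"].tolist())


@dataclass
class VisitComparison:
    r_all: float
    r_significant: float
    shared_features: list[str]
    shared_significant: list[str]


def compare_visits(
    results_v1: pd.DataFrame,
    results_v2: pd.DataFrame,
    q_cut: float = 0.05,
    use: str = "q_value",
) -> VisitComparison:
    """Correlate age coefficients between two visits.

    ``r_all`` is the Pearson correlation of beta_age over all shared
    features; ``r_significant`` over features significant at both visits.
    Correlations over fewer than 3 features are reported as NaN.
    """
    m = results_v1.merge(
        results_v2, on="feature_id", suffixes=("_v1", "_v2")
    )
    if m.empty:
        raise ValueError("compare_visits: no overlapping feature IDs")

    def _corr(sub: pd.DataFrame) -> float:
        if len(sub) < 3:
            return float("nan")
        return float(np.corrcoef(sub["beta_age_v1"], sub["beta_age_v2"])[0, 1])

    sig = m[(m[f"{use}_v1"] < q_cut) & (m[f"{use}_v2"] < q_cut)]
    return VisitComparison(
        r_all=_corr(m),
        r_significant=_corr(sig),
        shared_features=m["feature_id"].tolist(),
        shared_significant=sig["feature_id"].tolist(),
    )


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot-ready table: beta_age on x, -log10(p) on y."""
    out = results[["feature_id", "beta_age", "p_value", "q_value", "direction"]].copy()
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out
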