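"""Signature validation: LOOCV re-fit and cross-platform intersection.

Once a signature has been selected by the regularized clock, its predictive
value is checked by refitting an unregularized Gaussian linear model on the
signature features with leave-one-out cross-validation, and the correlation
between chronological age and the LOOCV predictions is reported. For
transfer to a different measurement platform, the signature is intersected
with the target platform's feature catalog by case-normalized exact ID
match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["loocv_predict", "intersect_features", "LoocvResult", "IntersectionReport"]


@dataclass
class LoocvResult:
    predictions: pd.Series
    r: float
    p_value: float


def loocv_predict(X_signature: pd.DataFrame, y: pd.Series) -> LoocvResult:
    """Leave-one-out OLS predictions of age from signature features.

    For each subject, an ordinary least-squares model (Gaussian GLM,
    identity link) is fit on the remaining n-1 subjects and used to predict
    the held-out subject. Requires the signature to be smaller than n-1;
    rank-deficient designs fall back to a tiny ridge penalty with a log
    notice. Missing entries are not allowed (impute upstream).
    """
    Xa = X_signature.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if ya.size != n:
        raise ValueError("X and y disagree on sample count")
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValueError("missing values in LOOCV inputs; impute first")
    if p >= n - 1:
        raise ValueError(f"signature size p={p} must be < n-1={n - 1}")
    D = np.column_stack([np.ones(n), Xa])
    preds = np.empty(n)
    ridge_used = False
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        A = D[keep].T @ D[keep]
        b = D[keep].T @ ya[keep]
        if np.linalg.matrix_rank(A) < A.shape[0]:
            A = A + 1e-8 * np.eye(A.shape[0])
            ridge_used = True
        coef = np.linalg.solve(A, b)
        preds[i] = D[i] @ coef
    if ridge_used:
        log.info("loocv_predict: rank-deficient design; tiny ridge fallback applied")
    r, pv = stats.pearsonr(ya, preds)
    return LoocvResult(
        predictions=pd.Series(preds, index=X_signature.index, name="loocv_pred"),
        r=float(r),
        p_value=float(pv),
    )


@dataclass
class IntersectionReport:
    overlap: list[str]
    dropped: list[str]

    @property
    def n_overlap(self) -> int:
        return len(self.overlap)


def intersect_features(signature: list[str], platform_catalog: list[str]) -> IntersectionReport:
    """Case-normalized exact-ID intersection of a signature with a catalog.

    Returns the overlapping features (original signature casing, original
    order) and the signature features absent from the catalog. An empty
    intersection is allowed with a warning.
    """
    catalog = {str(f).casefold() for f in platform_catalog}
    overlap = [f for f in signature if str(f).casefold() in catalog]
    dropped = [f for f in signature if str(f).casefold() not in catalog]
    if not overlap:
        log.warning("intersect_features: empty intersection (%d signature features)", len(signature))
    return IntersectionReport(overlap=overlap, dropped=dropped)
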