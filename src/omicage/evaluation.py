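"""Canned validation experiments for the clock and score pipeline.

Each function sets up a simulation whose correct answer is known by
construction — an algebraic degeneracy, a global null, a planted signal, or
ground-truth recovery — runs the relevant pipeline stage, and returns the
measured quantity. The pytest suite asserts on these values and the
acceptance script reports them, so the experiment definitions live here,
in one place, with the problem sizes spelled out.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from . import cross_sectional as cs
from . import enet
from . import pipeline as pl
from . import scores as sc
from . import synthetic as syn

__all__ = [
    "oracle_ols_equivalence",
    "bh_fixture_error",
    "null_model_calibration",
    "single_feature_signal",
    "null_fdr",
    "parameter_recovery",
    "flag_tail_rate",
    "scores_fixture_error",
    "loocv_fixture_error",
    "pipeline_determinism",
]


# ---------------------------------------------------------------------------
# algebraic degeneracies and hand fixtures


def oracle_ols_equivalence(seed: int = 3, n: int = 60, p: int = 10) -> float:
    """Max |OOB - k-fold OLS| when the elastic net degenerates to least squares.

    With mixing alpha = 0 and lambda -> 0 on full-rank n > p data the
    penalized fit is ordinary least squares, so the clock's out-of-bag
    predictions must match plain k-fold OLS predictions computed
    independently (sklearn ``LinearRegression``) on the same partitions.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    y = X @ rng.normal(0, 1, p) + rng.normal(0, 1, n)
    cfg = enet.EnetConfig(
        alpha_grid=(0.0,), lambda_grid=(1e-10,), n_runs=3, k_folds=5, n_perm=1,
        seed=seed + 1,
    )
    res = enet.run_cv_enet(X, y, cfg)
    preds = np.zeros((cfg.n_runs, n))
    for r in range(cfg.n_runs):
        rr = np.random.default_rng([cfg.seed, 9173, r])
        folds = enet.fold_assignment(n, cfg.k_folds, rr)
        for f in range(cfg.k_folds):
            te = folds == f
            m = LinearRegression().fit(X[~te], y[~te])
            preds[r, te] = m.predict(X[te])
    return float(np.abs(res.oob_mean[0] - preds.mean(axis=0)).max())


def bh_fixture_error() -> float:
    """Max |bh_adjust - hand step-up| on the 4-element fixtures.

    (0.01, 0.02, 0.03, 0.04): q_(i) = min_j>=i p_(j)*4/j = 0.04 for all.
    Equal ties (0.03 x 3): the i = m term dominates, all q = 0.03.
    """
    err = np.abs(cs.bh_adjust([0.01, 0.02, 0.03, 0.04]) - [0.04, 0.04, 0.04, 0.04]).max()
    err = max(err, np.abs(cs.bh_adjust([0.03, 0.03, 0.03]) - [0.03, 0.03, 0.03]).max())
    return float(err)


SCORES_FIXTURE_AGES = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 70.0])
# predictions on the identity line except the oldest subject at +10
SCORES_FIXTURE_PREDS = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 80.0])


def _scores_fixture_expected() -> np.ndarray:
    """Closed-form OLS residuals for the 6-point fixture.

    slope = S_xy/S_xx with S_xy = sum (x - xbar)(y - ybar); residuals follow
    from the normal equations directly, independent of compute_scores.
    """
    x, y = SCORES_FIXTURE_AGES, SCORES_FIXTURE_PREDS
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    return y - (ybar + slope * (x - xbar))


def scores_fixture_error() -> float:
    """Max |compute_scores - closed-form residual| on the 6-point fixture."""
    ids = [f"s{i}" for i in range(6)]
    raw = sc.compute_scores(
        pd.Series(SCORES_FIXTURE_PREDS, index=ids),
        pd.Series(SCORES_FIXTURE_AGES, index=ids),
    )
    return float(np.abs(raw.to_numpy() - _scores_fixture_expected()).max())


LOOCV_FIXTURE_X = np.array([1.0, 2.0, 3.0, 5.0])
LOOCV_FIXTURE_Y = np.array([2.0, 4.1, 5.9, 10.2])


def _loocv_fixture_expected() -> np.ndarray:
    """Hand leave-one-out simple regression on the 4-point fixture."""
    preds = np.empty(4)
    for i in range(4):
        keep = np.ones(4, dtype=bool)
        keep[i] = False
        x, y = LOOCV_FIXTURE_X[keep], LOOCV_FIXTURE_Y[keep]
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        preds[i] = y.mean() + slope * (LOOCV_FIXTURE_X[i] - x.mean())
    return preds


def loocv_fixture_error() -> float:
    """Max |loocv_predict - hand LOO regression| on the 4-point fixture."""
    from .validation import loocv_predict

    ids = [f"s{i}" for i in range(4)]
    res = loocv_predict(
        pd.DataFrame({"f": LOOCV_FIXTURE_X}, index=ids),
        pd.Series(LOOCV_FIXTURE_Y, index=ids),
    )
    return float(np.abs(res.predictions.to_numpy() - _loocv_fixture_expected()).max())


# ---------------------------------------------------------------------------
# null calibrations


def null_model_calibration(
    seed: int = 0,
    n_seeds: int = 20,
    n: int = 80,
    p: int = 300,
    n_runs: int = 20,
    n_perm: int = 25,
) -> np.ndarray:
    """Model-level empirical p-values on globally permuted responses.

    For each replicate, age is permuted against a pure-noise feature matrix
    before entering the clock, so the model p-value must be (super-)uniform.
    Returns the array of p-values, one per replicate.
    """
    root = np.random.default_rng(seed)
    pvals = np.empty(n_seeds)
    for s in range(n_seeds):
        rng = np.random.default_rng(root.integers(2**31))
        X = rng.normal(0, 1, (n, p))
        y = rng.permutation(rng.uniform(22, 92, n))
        cfg = enet.EnetConfig(
            alpha_grid=(0.5,), lambda_grid=(2.0,), n_runs=n_runs, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        res = enet.run_cv_enet(X, y, cfg)
        pvals[s] = res.model_p[0]
    return pvals


def null_fdr(
    seed: int = 0, n_reps: int = 20, n: int = 100, p: int = 2000, q_cut: float = 0.05
) -> float:
    """Mean realized false-discovery proportion on pure-null blocks.

    Every feature is null, so any BH discovery is false: the realized FDP of
    a replicate is 1 if anything is called at q < ``q_cut``, else 0, and the
    mean over replicates estimates the FDR, which BH controls at ``q_cut``.
    """
    root = np.random.default_rng(seed)
    fdp = np.empty(n_reps)
    for r in range(n_reps):
        cfg = syn.CohortConfig(
            n_subjects=n,
            age_bins=None,
            blocks=(
                syn.BlockConfig("null_block", p, frac_age_assoc=0.0, lod_quantile=0.0),
            ),
            latent_sd=0.0,
            seed=int(root.integers(2**31)),
        )
        blocks, meta, _ = syn.simulate_cohort(cfg)
        res = cs.fit_feature_lm(blocks[0], meta)
        n_disc = int((res["q_value"] < q_cut).sum())
        fdp[r] = 1.0 if n_disc > 0 else 0.0
    return float(fdp.mean())


def flag_tail_rate(seed: int = 0, n: int = 100_000, z_cut: float = 1.5) -> float:
    """Fraction of standard-normal scores flagged at |z| > ``z_cut``.

    The analytic rate is 2*(1 - Phi(1.5)) = 0.1336.
    """
    rng = np.random.default_rng(seed)
    raw = pd.DataFrame({"b_x": rng.normal(0, 1, n)})
    table = sc.flag_acceleration(raw, z_cut=z_cut)
    flagged = table.flags["b_x"].isin([sc.FLAG_ACCELERATED, sc.FLAG_DECELERATED])
    return float(flagged.mean())


# ---------------------------------------------------------------------------
# planted-signal detection and ground-truth recovery


def single_feature_signal(
    seed: int = 0,
    n: int = 100,
    p: int = 50,
    noise_sd: float = 2.0,
    n_runs: int = 20,
    n_perm: int = 25,
) -> dict:
    """Clock on one true feature (slope 1, given noise SD) among pure noise.

    Returns the best model's QF, the true feature's selection frequency, and
    its rank in the extracted signature (0 = first).
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(22, 92, n)
    X = rng.normal(0, 1, (n, p))
    X[:, 0] = age + rng.normal(0, noise_sd, n)
    cfg = enet.EnetConfig(
        alpha_grid=(0.5, 0.9), n_lambda=6, n_runs=n_runs, n_perm=n_perm, seed=seed + 1
    )
    res = enet.run_cv_enet(X, age, cfg)
    best = res.best_index()
    sig = enet.extract_signature(res)
    rank = (
        int(sig.index[sig["feature_id"] == "f0"][0]) if "f0" in set(sig["feature_id"]) else -1
    )
    return {
        "qf": float(res.qf[best]),
        "true_feature_freq": float(res.freq[best, 0]),
        "signature_rank": rank,
        "model_p": float(res.model_p[best]),
    }


def _recovery_config(seed: int) -> syn.CohortConfig:
    """Strong-signal recovery cohort: sigma_delta = 5y, loading 1 everywhere.

    Uses the six default compartment/omic blocks at their full default
    dimensions with moderate residual noise (0.5 log units) relative to
    per-feature age effects of ~0.03 log units/year; shrinking the blocks
    further would starve the smaller ones of signal features and make the
    latent deviation unidentifiable per compartment.
    """
    cfg = syn.default_config(seed=seed, scale=1.0)
    blocks = tuple(
        dataclasses.replace(b, loading=1.0, frac_age_assoc=max(b.frac_age_assoc, 0.25))
        for b in cfg.blocks
    )
    return dataclasses.replace(cfg, blocks=blocks, latent_sd=5.0)


def parameter_recovery(seed: int = 0, n_runs: int = 20) -> dict:
    """Recover the latent biological-age deviation from composite scores.

    Simulates the six-block cohort with a shared latent deviation delta, fits
    a reduced-schedule clock per block, residualizes OOB predictions into
    aging scores, and correlates the per-compartment composite z-scores with
    the true delta. Also summarizes the cross-block score correlation matrix,
    which must be positive when all blocks load on one latent factor.
    """
    cfg = _recovery_config(seed)
    blocks, meta, truth = syn.simulate_cohort(cfg)
    raw = pd.DataFrame(index=meta.index)
    for i, b in enumerate(blocks):
        X = b.values.copy()
        X["sex"] = meta.loc[b.sample_ids, "sex"].to_numpy(dtype=float)
        ecfg = enet.EnetConfig(
            alpha_grid=(0.1, 0.5), n_lambda=5, n_runs=n_runs, n_perm=1,
            seed=seed + 31 * (i + 1),
        )
        res = enet.run_cv_enet(X, meta.loc[b.sample_ids, "age"], ecfg)
        oob = pd.Series(res.oob_mean[res.best_index()], index=b.sample_ids)
        raw[b.name] = sc.compute_scores(oob, meta.loc[b.sample_ids, "age"])
    table = sc.flag_acceleration(raw)
    comp = sc.composite_scores(table)
    corr_delta = {}
    for c in comp.columns:
        ok = comp[c].notna()
        corr_delta[c] = float(np.corrcoef(comp.loc[ok, c], truth.delta[ok])[0, 1])
    # overall composite across compartments vs delta
    overall = comp.mean(axis=1)
    ok = overall.notna()
    overall_corr = float(np.corrcoef(overall[ok], truth.delta[ok])[0, 1])
    bcorr, _ = sc.score_correlation_matrix(table.z)
    off = bcorr.to_numpy()[~np.eye(len(bcorr), dtype=bool)]
    off = off[~np.isnan(off)]
    return {
        "corr_composite_delta": overall_corr,
        "corr_per_compartment": corr_delta,
        "mean_offdiag_corr": float(off.mean()),
        "min_offdiag_corr": float(off.min()),
    }


# ---------------------------------------------------------------------------
# end-to-end determinism


SMOKE_PIPELINE_CONFIG: dict = {
    "cohort": {
        "n_subjects": 60,
        "blocks": [
            {"name": "plasma_proteomics", "n_features": 80, "frac_age_assoc": 0.30},
            {"name": "plasma_metabolomics", "n_features": 40, "frac_age_assoc": 0.30},
            {"name": "urine_proteomics", "n_features": 60, "frac_age_assoc": 0.15,
             "frac_subjects": 0.9},
        ],
    },
    "enet": {"alpha_grid": [0.5], "n_lambda": 4, "n_runs": 5, "n_perm": 2},
    "correlates": {"min_blocks": 2},
}


def pipeline_determinism(seed: int, work_dir: str | Path) -> bool:
    """Run the smoke pipeline twice with one seed; compare output hashes."""
    work_dir = Path(work_dir)
    m1 = pl.run_pipeline(SMOKE_PIPELINE_CONFIG, work_dir / "run1", seed=seed)
    m2 = pl.run_pipeline(SMOKE_PIPELINE_CONFIG, work_dir / "run2", seed=seed)
    return m1["outputs_hash"] == m2["outputs_hash"]
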