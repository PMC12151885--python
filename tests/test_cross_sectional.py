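"""Per-feature age regression, BH adjustment, and visit comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from omicage import cross_sectional as cs
from omicage.blocks import OmicsBlock


def _block(values: np.ndarray, sample_ids, feature_ids=None):
    feature_ids = feature_ids or [f"f{j}" for j in range(values.shape[1])]
    return OmicsBlock(
        values=pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        name="plasma_proteomics",
    )


@pytest.fixture
def worked_fixture():
    """Six subjects, y = 0.5*age + sex with no noise: beta_age = 0.5 exactly."""
    ages = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 70.0])
    sex = np.array([0, 1, 0, 1, 0, 1])
    ids = [f"S{i}" for i in range(6)]
    meta = pd.DataFrame({"age": ages, "sex": sex}, index=ids)
    y = 0.5 * ages + sex
    return _block(y[:, None], ids), meta


def test_worked_fixture_exact_beta(worked_fixture):
    block, meta = worked_fixture
    res = cs.fit_feature_lm(block, meta, covariates=("sex",))
    assert res.loc[0, "beta_age"] == pytest.approx(0.5, abs=1e-12)
    assert res.loc[0, "direction"] == "over"
    assert res.loc[0, "n_used"] == 6


def test_feature_equal_to_age_has_unit_slope():
    rng = np.random.default_rng(0)
    ids = [f"S{i}" for i in range(40)]
    ages = rng.uniform(22, 92, 40)
    meta = pd.DataFrame(
        {"age": ages, "sex": rng.integers(0, 2, 40), "race": rng.integers(0, 2, 40),
         "bmi": rng.normal(25, 3, 40)},
        index=ids,
    )
    res = cs.fit_feature_lm(_block(ages[:, None], ids), meta)
    assert res.loc[0, "beta_age"] == pytest.approx(1.0, abs=1e-10)
    assert res.loc[0, "p_value"] < 1e-30


def test_null_feature_p_values_uniform():
    """Features driven only by sex (not age) give ~Uniform(0,1) age p-values."""
    rng = np.random.default_rng(1)
    n, p = 100, 400
    ids = [f"S{i}" for i in range(n)]
    sex = rng.integers(0, 2, n)
    meta = pd.DataFrame({"age": rng.uniform(22, 92, n), "sex": sex}, index=ids)
    Y = 3.0 * sex[:, None] + rng.normal(0, 1, (n, p))
    res = cs.fit_feature_lm(_block(Y, ids), meta, covariates=("sex",))
    ks = stats.kstest(res["p_value"], "uniform")
    assert ks.pvalue > 0.01
    assert res["beta_age"].abs().mean() < 0.02


def test_bh_hand_fixtures():
    np.testing.assert_allclose(
        cs.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(cs.bh_adjust([0.2]), [0.2])
    # all equal: the i = m term dominates, q = p for every entry
    np.testing.assert_allclose(cs.bh_adjust([0.03, 0.03, 0.03]), [0.03] * 3)
    assert cs.bh_adjust([]).size == 0
    with pytest.raises(ValueError):
        cs.bh_adjust([0.0, 0.5])


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.floats(min_value=1e-8, max_value=1.0, allow_nan=False), min_size=1, max_size=40
    )
)
def test_bh_matches_statsmodels_and_is_monotone(pvals):
    q = cs.bh_adjust(pvals)
    _, q_sm, _, _ = multipletests(pvals, method="fdr_bh")
    np.testing.assert_allclose(q, q_sm, rtol=1e-12)
    assert np.all(q >= np.asarray(pvals) - 1e-15)
    order = np.argsort(pvals)
    assert np.all(np.diff(q[order]) >= -1e-15)


def _results(betas, qs):
    return pd.DataFrame(
        {
            "feature_id": [f"f{j}" for j in range(len(betas))],
            "beta_age": betas,
            "q_value": qs,
            "p_value": qs,
            "direction": ["over" if b >= 0 else "under" for b in betas],
        }
    )


def test_classify_and_count():
    assert cs.classify_and_count(_results([1, -1], [1.0, 1.0])).significant_ids == []
    summary = cs.classify_and_count(_results([1, -1], [0.01, 0.01]))
    assert (summary.n_over, summary.n_under) == (1, 1)
    with pytest.raises(ValueError):
        cs.classify_and_count(_results([], []))


def test_compare_visits_trivial_and_degenerate():
    r1 = _results([1.0, 2.0, -1.0, 0.5], [0.01, 0.01, 0.2, 0.01])
    same = cs.compare_visits(r1, r1)
    assert same.r_all == pytest.approx(1.0)
    assert same.shared_significant == ["f0", "f1", "f3"]
    flipped = r1.copy()
    flipped["beta_age"] = -flipped["beta_age"]
    assert cs.compare_visits(r1, flipped).r_all == pytest.approx(-1.0)
    # fewer than 3 shared significant features -> NaN, reported as such
    r_small = cs.compare_visits(r1, _results([1.0, 2.0, -1.0, 0.5], [0.01, 0.9, 0.9, 0.9]))
    assert np.isnan(r_small.r_significant)


def test_two_noise_draws_share_signal_betas(small_cohort):
    """Independent redraws from one truth correlate on signal, not null, features."""
    import dataclasses

    from omicage import synthetic as syn

    cfg = syn.CohortConfig(
        n_subjects=80, age_bins=None, seed=21, latent_sd=0.0, clinical=(),
        blocks=(syn.BlockConfig("plasma_proteomics", 300, frac_age_assoc=0.5,
                                lod_quantile=0.0),),
    )
    b1, m1, t1 = syn.simulate_cohort(cfg)
    # same per-feature truth, fresh subjects and noise
    cfg2 = dataclasses.replace(
        cfg, seed=22,
        blocks=(dataclasses.replace(
            cfg.blocks[0],
            fixed_beta=tuple(t1.beta_age["plasma_proteomics"].to_numpy()),
        ),),
    )
    b2, m2, _ = syn.simulate_cohort(cfg2)
    r1 = cs.fit_feature_lm(b1[0], m1, covariates=("sex", "bmi"))
    r2 = cs.fit_feature_lm(b2[0], m2, covariates=("sex", "bmi"))
    m = r1.merge(r2, on="feature_id", suffixes=("_1", "_2"))
    sig = t1.signal_mask["plasma_proteomics"].reindex(m["feature_id"]).to_numpy()
    corr_sig = np.corrcoef(m.loc[sig, "beta_age_1"], m.loc[sig, "beta_age_2"])[0, 1]
    corr_null = np.corrcoef(m.loc[~sig, "beta_age_1"], m.loc[~sig, "beta_age_2"])[0, 1]
    assert corr_sig > 0.8 > abs(corr_null) + 0.5


def test_invariance_to_row_order_and_bmi_rescaling():
    rng = np.random.default_rng(5)
    n, p = 50, 8
    ids = [f"S{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"age": rng.uniform(22, 92, n), "sex": rng.integers(0, 2, n),
         "bmi": rng.normal(25, 3, n)},
        index=ids,
    )
    Y = rng.normal(0, 1, (n, p))
    base = cs.fit_feature_lm(_block(Y, ids), meta, covariates=("sex", "bmi"))

    order = rng.permutation(n)
    shuffled = cs.fit_feature_lm(
        _block(Y[order], [ids[i] for i in order]), meta, covariates=("sex", "bmi")
    )
    np.testing.assert_allclose(base["beta_age"], shuffled["beta_age"], atol=1e-10)

    meta_scaled = meta.assign(bmi=3.0 * meta["bmi"] - 10.0)
    scaled = cs.fit_feature_lm(_block(Y, ids), meta_scaled, covariates=("sex", "bmi"))
    np.testing.assert_allclose(base["p_value"], scaled["p_value"], atol=1e-10)


def test_constant_covariate_dropped_with_warning():
    rng = np.random.default_rng(6)
    ids = [f"S{i}" for i in range(20)]
    meta = pd.DataFrame(
        {"age": rng.uniform(20, 90, 20), "race": np.ones(20)}, index=ids
    )
    with pytest.warns(UserWarning, match="race"):
        res = cs.fit_feature_lm(_block(rng.normal(size=(20, 2)), ids), meta,
                                covariates=("race",))
    assert res.attrs["covariates"] == []


def test_features_with_too_few_observations_skipped():
    rng = np.random.default_rng(7)
    ids = [f"S{i}" for i in range(12)]
    meta = pd.DataFrame({"age": rng.uniform(20, 90, 12), "sex": rng.integers(0, 2, 12)},
                        index=ids)
    Y = rng.normal(size=(12, 2))
    Y[:10, 1] = np.nan  # 2 left, below parameters + 1
    res = cs.fit_feature_lm(_block(Y, ids), meta, covariates=("sex",))
    assert res["feature_id"].tolist() == ["f0"]
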