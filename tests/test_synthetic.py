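"""Generator correctness: determinism, planted structure, censoring, round-trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from omicage import cross_sectional as cs
from omicage import io as oio
from omicage import synthetic as syn


def _single_feature_config(**over):
    base = dict(
        n_subjects=30,
        age_bins=None,
        latent_sd=0.0,
        seed=4,
        clinical=(),
        blocks=(
            syn.BlockConfig(
                "plasma_proteomics", 1, fixed_beta=(1.0,), intercept_sd=0.0,
                noise_sd=0.0, loading=0.0, sex_effect_sd=0.0, bmi_effect_sd=0.0,
                lod_quantile=0.0,
            ),
        ),
    )
    base.update(over)
    return syn.CohortConfig(**base)


def test_same_seed_bit_identical_different_seed_differs():
    cfg = syn.default_config(seed=3, scale=0.05)
    b1, m1, t1 = syn.simulate_cohort(cfg)
    b2, m2, t2 = syn.simulate_cohort(cfg)
    pd.testing.assert_frame_equal(m1, m2)
    for x, y in zip(b1, b2):
        pd.testing.assert_frame_equal(x.values, y.values)
    pd.testing.assert_series_equal(t1.delta, t2.delta)

    b3, _, _ = syn.simulate_cohort(dataclasses.replace(cfg, seed=4))
    assert not np.array_equal(
        b1[0].values.to_numpy(), b3[0].values.to_numpy(), equal_nan=True
    )


def test_no_signal_config_has_empty_mask_and_null_betas():
    cfg = syn.default_config(seed=9, scale=0.1)
    cfg = dataclasses.replace(
        cfg,
        blocks=tuple(
            dataclasses.replace(b, frac_age_assoc=0.0, lod_quantile=0.0)
            for b in cfg.blocks
        ),
    )
    blocks, meta, truth = syn.simulate_cohort(cfg)
    for b in blocks:
        assert not truth.signal_mask[b.name].any()
        res = cs.fit_feature_lm(b, meta)
        # recovered age slopes scatter around zero at the residual-noise scale
        assert abs(res["beta_age"].mean()) < 0.01
        assert (res["q_value"] < 0.05).mean() < 0.1


def test_noise_free_unit_slope_feature_equals_age():
    blocks, meta, truth = syn.simulate_cohort(_single_feature_config())
    col = blocks[0].values.iloc[:, 0]
    np.testing.assert_allclose(col.to_numpy(), meta["age"].to_numpy(), atol=1e-10)
    assert truth.signal_mask["plasma_proteomics"].all()


def test_age_bins_respected():
    bins = ((20, 29, 4), (30, 39, 5), (70, 92, 6))
    cfg = syn.CohortConfig(n_subjects=15, age_bins=bins, blocks=(), seed=0)
    _, meta, _ = syn.simulate_cohort(cfg)
    ages = np.sort(meta["age"].to_numpy())
    counts = [((lo <= meta["age"]) & (meta["age"] <= hi)).sum() for lo, hi, _ in bins]
    assert counts == [4, 5, 6]
    assert ages.min() >= 20 and ages.max() <= 92


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_subjects=2),
        dict(n_subjects=10, age_bins=((20, 30, 4),)),  # counts don't sum to n
        dict(n_subjects=10, age_bins=((40, 30, 10),)),  # inverted bin
        dict(n_subjects=10, age_range=(90, 20), age_bins=None),
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        syn.simulate_cohort(syn.CohortConfig(blocks=(), **kwargs))


def test_censoring_fraction_matches_lod_quantile():
    cfg = syn.CohortConfig(
        n_subjects=200, age_bins=None, seed=5, clinical=(),
        blocks=(syn.BlockConfig("plasma_proteomics", 50, lod_quantile=0.2),),
    )
    blocks, _, _ = syn.simulate_cohort(cfg)
    frac = blocks[0].below_lod.mean(axis=0)
    assert np.allclose(frac, 0.2, atol=0.05)
    assert blocks[0].values.isna().equals(blocks[0].below_lod)


def test_default_detection_rate_tracks_signal_fraction():
    """BH discoveries on the default cohort land near the planted signal fraction."""
    cfg = syn.CohortConfig(
        n_subjects=100, age_bins=None, seed=2, latent_sd=0.0, clinical=(),
        blocks=(syn.BlockConfig("plasma_proteomics", 500, frac_age_assoc=0.33),),
    )
    blocks, meta, truth = syn.simulate_cohort(cfg)
    res = cs.fit_feature_lm(blocks[0], meta)
    frac_sig = (res["q_value"] < 0.05).mean()
    # 0.33 signal fraction x finite power, near-zero false positives
    assert 0.24 <= frac_sig <= 0.38
    sig_ids = set(res.loc[res["q_value"] < 0.05, "feature_id"])
    truth_ids = set(truth.signal_mask["plasma_proteomics"].index[
        truth.signal_mask["plasma_proteomics"]
    ])
    false = len(sig_ids - truth_ids)
    assert false <= 0.02 * len(sig_ids) + 2


def test_write_read_roundtrip(tmp_path, small_cohort):
    blocks, meta, truth = small_cohort
    syn.write_cohort(blocks, meta, truth, tmp_path, overwrite=True)
    blocks2, meta2, truth2 = syn.read_cohort(tmp_path)
    pd.testing.assert_frame_equal(meta, meta2, check_names=False)
    by_name = {b.name: b for b in blocks2}
    for b in blocks:
        pd.testing.assert_frame_equal(b.values, by_name[b.name].values)
        pd.testing.assert_frame_equal(b.below_lod, by_name[b.name].below_lod)
    pd.testing.assert_series_equal(truth.delta, truth2.delta, check_names=False)


def test_write_refuses_overwrite(tmp_path, small_cohort):
    blocks, meta, truth = small_cohort
    syn.write_cohort(blocks, meta, truth, tmp_path)
    with pytest.raises(FileExistsError):
        syn.write_cohort(blocks, meta, truth, tmp_path, overwrite=False)


def test_empty_block_list_writes_metadata_with_warning(tmp_path, small_cohort):
    _, meta, _ = small_cohort
    with pytest.warns(UserWarning):
        paths = syn.write_cohort([], meta, None, tmp_path)
    assert (tmp_path / "metadata.csv").exists()
    assert set(paths) == {"metadata"}


def test_reader_realigns_permuted_rows(tmp_path, small_cohort):
    """Row order on disk is immaterial: the mask is re-joined by sample ID."""
    blocks, meta, _ = small_cohort
    b = blocks[0]
    path = oio.write_block(b, tmp_path / f"{b.name}.csv")
    perm = b.values.sample(frac=1.0, random_state=0)
    perm.to_csv(path, index_label=oio.SAMPLE_COL)  # shuffle value rows only
    b2 = oio.read_block(path)
    # mask rows must follow the shuffled value rows, matched on ID
    pd.testing.assert_frame_equal(b2.below_lod, b.below_lod.loc[perm.index])
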