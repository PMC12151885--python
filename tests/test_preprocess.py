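"""QC filters, reference normalization, and the PCA overview."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from omicage import preprocess as pp
from omicage.blocks import OmicsBlock


def _block_with_lod_fracs(fracs, n=10):
    """One feature per entry of ``fracs``, censored in that many of n samples."""
    values = pd.DataFrame(
        np.ones((n, len(fracs))),
        index=[f"S{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(len(fracs))],
    )
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    for j, frac in enumerate(fracs):
        k = int(round(frac * n))
        mask.iloc[:k, j] = True
    return OmicsBlock(values=values.mask(mask), below_lod=mask, name="b")


def test_filter_lod_strict_boundary():
    """8/10 censored is dropped; exactly 7/10 sits on the strict > boundary and stays."""
    block = _block_with_lod_fracs([0.8, 0.7, 0.0])
    out, report = pp.filter_lod(block, max_frac_below=0.70)
    assert out.feature_ids == ["f1", "f2"]
    assert report.loc["f0", "dropped"] and not report.loc["f1", "dropped"]
    np.testing.assert_allclose(report["frac_below_lod"], [0.8, 0.7, 0.0])


def test_filter_lod_identity_and_idempotence():
    block = _block_with_lod_fracs([0.0, 0.0])
    out, _ = pp.filter_lod(block)
    pd.testing.assert_frame_equal(out.values, block.values)
    again, _ = pp.filter_lod(out)
    assert again.feature_ids == out.feature_ids
    # input not mutated
    assert block.n_features == 2


def test_qc_exclude_hand_computed_threshold():
    block = _block_with_lod_fracs([0.0, 0.0, 0.0])
    dev = pd.Series([0.0, 0.1, 9.0], index=block.feature_ids)
    # mean 3.03, population SD 4.22 -> threshold ~19.9: nothing removed
    out, report = pp.qc_exclude_assays(block, dev)
    assert out.feature_ids == block.feature_ids
    assert not report["dropped"].any()
    # one wild assay among many well-behaved ones exceeds mean + 4 SD
    # (with only 3 assays the max standardized deviation is sqrt(2) < 4,
    # so the rule can only ever bite in wider panels)
    wide = _block_with_lod_fracs([0.0] * 50)
    dev2 = pd.Series([0.0] * 49 + [100.0], index=wide.feature_ids)
    # mean 2, pop SD 14 -> threshold 58: the outlying assay is removed
    out2, rep2 = pp.qc_exclude_assays(wide, dev2)
    assert out2.n_features == 49
    assert rep2["dropped"].sum() == 1 and rep2.loc["f49", "dropped"]


def test_qc_exclude_degenerate_and_missing_control():
    block = _block_with_lod_fracs([0.0, 0.0])
    out, _ = pp.qc_exclude_assays(block, pd.Series([2.0, 2.0], index=block.feature_ids))
    assert out.feature_ids == block.feature_ids  # SD = 0, threshold = mean, strict >
    out2, report = pp.qc_exclude_assays(block, None)
    assert out2.feature_ids == block.feature_ids
    assert report.empty


def _random_block(n=8, p=5, seed=0, name="urine_proteomics"):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"S{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )
    return OmicsBlock(values=values, name=name)


def test_normalize_by_reference_trivial_cases():
    b = _random_block()
    dup = b.values.copy()
    for c in dup.columns:
        dup[c] = dup["f0"]
    all_equal = OmicsBlock(values=dup, name="b")
    out = pp.normalize_by_reference(all_equal, "f0")
    assert (out.values.to_numpy() == 0).all()
    assert "f0" not in out.feature_ids

    zeros = b.values.copy()
    zeros["f0"] = 0.0
    out2 = pp.normalize_by_reference(OmicsBlock(values=zeros, name="b"), "f0")
    pd.testing.assert_frame_equal(out2.values, zeros.drop(columns="f0"))


def test_normalize_by_reference_cancels_dilution():
    """Adding a per-sample log offset to every column leaves the output unchanged."""
    b = _random_block(seed=2)
    out = pp.normalize_by_reference(b, "f0")
    c = np.random.default_rng(3).normal(0, 2, b.n_samples)
    diluted = OmicsBlock(values=b.values.add(pd.Series(c, index=b.values.index), axis=0), name="b")
    out_d = pp.normalize_by_reference(diluted, "f0")
    pd.testing.assert_frame_equal(out.values, out_d.values)


def test_normalize_by_reference_commutes_with_reordering():
    b = _random_block(seed=4)
    out = pp.normalize_by_reference(b, "f1")
    order = list(reversed(b.sample_ids))
    shuffled = OmicsBlock(values=b.values.loc[order], name="b")
    out_s = pp.normalize_by_reference(shuffled, "f1")
    pd.testing.assert_frame_equal(out_s.values, out.values.loc[order])


def test_normalize_by_reference_errors():
    b = _random_block()
    with pytest.raises(KeyError, match="nope"):
        pp.normalize_by_reference(b, "nope")
    holed = b.values.copy()
    holed.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        pp.normalize_by_reference(OmicsBlock(values=holed, name="b"), "f0")


def test_pca_separates_shifted_blocks():
    rng = np.random.default_rng(0)
    cols = [f"f{j}" for j in range(20)]
    a = pd.DataFrame(rng.normal(0, 1, (30, 20)), columns=cols,
                     index=[f"A{i}" for i in range(30)])
    b = pd.DataFrame(rng.normal(6, 1, (30, 20)), columns=cols,
                     index=[f"B{i}" for i in range(30)])
    table, evr = pp.pca_overview(
        [OmicsBlock(values=a, name="plasma"), OmicsBlock(values=b, name="urine")]
    )
    labels = (table["block"] == "plasma").astype(int)
    assert silhouette_score(table[["PC1"]], labels) > 0.5
    assert evr.sum() <= 1.0 + 1e-12
    assert np.all(np.diff(evr) <= 1e-12)  # non-increasing


def test_pca_duplicated_samples_have_rank_one():
    row = np.random.default_rng(1).normal(size=10)
    values = pd.DataFrame(np.tile(row, (6, 1)), index=[f"S{i}" for i in range(6)])
    values.iloc[0] += 1.0  # rank 1 after centering
    table, evr = pp.pca_overview([OmicsBlock(values=values, name="b")], n_components=3)
    assert evr[0] > 1 - 1e-9
    assert np.all(evr[1:] < 1e-9)


def test_mean_impute_fills_with_feature_mean():
    b = _random_block()
    holed = b.values.copy()
    holed.iloc[0, 0] = np.nan
    out = pp.mean_impute(OmicsBlock(values=holed, name="b"))
    assert out.values.notna().all().all()
    assert out.values.iloc[0, 0] == pytest.approx(holed["f0"].mean())
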