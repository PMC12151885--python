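"""Clinical-correlate screen: rank invariance, adjustment, tiering, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicage import correlates as co
from omicage import scores as sc


def _table_with_missing():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(
        rng.normal(0, 1, (10, 6)),
        columns=[f"c{j}_x" for j in range(6)],
        index=[f"S{i}" for i in range(10)],
    )
    raw.iloc[0, :3] = np.nan  # S0 has 3 of 6
    raw.iloc[1, :2] = np.nan  # S1 has 4 of 6
    return sc.flag_acceleration(raw)


def test_filter_min_blocks():
    table = _table_with_missing()
    keep = co.filter_min_blocks(table, min_blocks=4)
    assert "S0" not in keep and "S1" in keep
    assert len(co.filter_min_blocks(table, min_blocks=0)) == 10
    assert co.filter_min_blocks(table, min_blocks=6) == [f"S{i}" for i in range(2, 10)]


def _screen(scores_vals, clin_vals, **kw):
    idx = [f"S{i}" for i in range(len(scores_vals))]
    scores = pd.DataFrame({"plasma": scores_vals}, index=idx)
    clinical = pd.DataFrame(clin_vals, index=idx)
    return co.spearman_screen(scores, clinical, **kw)


def test_monotone_covariate_has_unit_rho():
    vals = np.linspace(-2, 2, 12)
    res = _screen(vals, {"cov": np.exp(vals)})
    assert res.loc[0, "rho"] == pytest.approx(1.0)
    assert res.loc[0, "n_used"] == 12


@settings(derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_rho_invariant_to_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    score = rng.normal(0, 1, 15)
    cov = rng.normal(0, 1, 15)
    r1 = _screen(score, {"cov": cov}).loc[0, "rho"]
    r2 = _screen(np.exp(score), {"cov": cov**3 + 5 * cov}).loc[0, "rho"]
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_height_adjustment_removes_height_signal():
    rng = np.random.default_rng(1)
    n = 40
    height = rng.normal(165, 8, n)
    score = rng.normal(0, 1, n)
    idx = [f"S{i}" for i in range(n)]
    scores = pd.DataFrame({"plasma": score}, index=idx)
    # walk metric driven almost entirely by stature
    clinical = pd.DataFrame(
        {"walk": 0.01 * height + rng.normal(0, 0.001, n), "height": height}, index=idx
    )
    raw = co.spearman_screen(scores, clinical[["walk", "height"]])
    adj = co.spearman_screen(scores, clinical, adjust={"walk": ["height"]})
    walk_adj = adj[adj["covariate"] == "walk"].iloc[0]
    # residualizing on ranked height strips the shared component
    height_rho = raw[raw["covariate"] == "height"].iloc[0]["rho"]
    walk_raw = raw[raw["covariate"] == "walk"].iloc[0]["rho"]
    assert walk_raw == pytest.approx(height_rho, abs=0.05)
    assert abs(walk_adj["rho"]) < 0.25
    assert walk_adj["adjusted_for"] == "height"
    with pytest.raises(ValueError, match="itself"):
        co.spearman_screen(scores, clinical, adjust={"height": ["height"]})


def test_constant_covariate_reported_missing():
    res = _screen(np.arange(8.0), {"cov": np.ones(8)})
    assert np.isnan(res.loc[0, "rho"])


def test_tiering_matches_legend():
    assert co.significance_tier(0.0005) == "***"
    assert co.significance_tier(0.005) == "**"
    assert co.significance_tier(0.03) == "*"
    assert co.significance_tier(0.07) == "(0.05<p<0.10)"
    assert co.significance_tier(0.5) == ""


def test_heatmap_table_filters_and_bolds():
    results = pd.DataFrame(
        {
            "covariate": ["hgb", "hgb", "alp", "alp"],
            "compartment": ["plasma", "urine", "plasma", "urine"],
            "rho": [-0.4, -0.3, 0.5, 0.1],
            "p_value": [0.0005, 0.07, 0.02, 0.5],
        }
    )
    results["tier"] = results["p_value"].map(co.significance_tier)
    table = co.heatmap_table(results, p_max=0.10)
    assert len(table) == 3  # the p = 0.5 row is excluded
    assert set(table.loc[table["covariate"] == "hgb", "tier"]) == {"***", "(0.05<p<0.10)"}
    assert table.loc[table["covariate"] == "hgb", "multi_compartment"].all()
    assert not table.loc[table["covariate"] == "alp", "multi_compartment"].any()
    empty = co.heatmap_table(results.iloc[0:0])
    assert empty.empty


def test_null_coupling_hits_near_ten_percent():
    """With no score-covariate coupling, ~10% of cells pass p < 0.10."""
    hits, cells = 0, 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        idx = [f"S{i}" for i in range(40)]
        scores = pd.DataFrame(rng.normal(0, 1, (40, 2)), columns=["plasma", "urine"],
                              index=idx)
        clinical = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=list("abc"), index=idx)
        res = co.spearman_screen(scores, clinical)
        hits += (res["p_value"] < 0.10).sum()
        cells += len(res)
    rate = hits / cells
    assert 0.05 <= rate <= 0.16


def test_generator_coupling_signs_recovered(small_cohort):
    """Hemoglobin-like couples negatively, alkaline-phosphatase-like positively."""
    blocks, meta, truth = small_cohort
    idx = meta.index
    # idealized compartment scores: the latent deviation plus noise
    rng = np.random.default_rng(2)
    scores = pd.DataFrame(
        {"plasma": truth.delta + rng.normal(0, 2, len(idx))}, index=idx
    )
    res = co.spearman_screen(scores, meta[["hemoglobin", "alk_phosphatase"]])
    rho = res.set_index("covariate")["rho"]
    assert rho["hemoglobin"] < 0 < rho["alk_phosphatase"]
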