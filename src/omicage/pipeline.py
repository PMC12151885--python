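"""End-to-end pipeline: simulate -> QC -> cross-sectional -> clocks -> scores
-> clinical correlates -> signature validation.

Driven by a config mapping (or YAML/JSON file) with sections ``cohort``,
``qc``, ``cross_sectional``, ``enet``, ``scores``, ``correlates``,
``validation``. Every stage writes its tables under the output directory
and the run ends with a manifest (seed, config hash, package version,
SHA-256 of every numeric output) so reruns can be checked byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cross_sectional as cs
from . import correlates as corr
from . import enet
from . import preprocess as pp
from . import scores as sc
from . import synthetic
from . import validation as val

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError", "load_config", "DEFAULT_CONFIG"]

KNOWN_SECTIONS = {
    "cohort", "qc", "cross_sectional", "enet", "scores", "correlates",
    "validation", "seed",
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {"scale": 1.0},
    "qc": {"max_frac_below": 0.70},
    "cross_sectional": {"covariates": ["sex", "race", "bmi"], "q_cut": 0.05, "use": "q_value"},
    "enet": {
        "alpha_grid": [0.1, 0.5, 0.9],
        "n_lambda": 6,
        "n_runs": 20,
        "k_folds": 5,
        "n_perm": 5,
    },
    "scores": {"z_cut": 1.5},
    "correlates": {"min_blocks": 4, "p_max": 0.10, "adjust": {"walk_speed": ["height"]}},
    "validation": {"block": None, "freq_p_cut": 0.05, "max_signature": None},
}


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


def load_config(source) -> dict:
    """Load a config from a mapping or a YAML/JSON path; validate keys."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    unknown = set(cfg) - KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    for k, v in cfg.items():
        if isinstance(v, dict):
            merged[k] = {**merged.get(k, {}), **v}
        else:
            merged[k] = v
    return merged


def _cohort_config(section: dict, seed: int) -> synthetic.CohortConfig:
    section = dict(section)
    scale = section.pop("scale", 1.0)
    blocks = section.pop("blocks", None)
    cfg = synthetic.default_config(seed=seed, scale=scale)
    if blocks is not None:
        cfg = dataclasses.replace(
            cfg, blocks=tuple(synthetic.BlockConfig(**b) for b in blocks)
        )
    if "n_subjects" in section and "age_bins" not in section:
        section["age_bins"] = None
    if "age_bins" in section and section["age_bins"] is not None:
        section["age_bins"] = tuple(tuple(b) for b in section["age_bins"])
    return dataclasses.replace(cfg, **section)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    run_seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def _write(df: pd.DataFrame, rel: str, **kw) -> Path:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, **kw)
        outputs.append(path)
        return path

    stage = "simulate"
    try:
        ccfg = _cohort_config(cfg["cohort"], seed=run_seed)
        blocks, metadata, truth = synthetic.simulate_cohort(ccfg)
        paths = synthetic.write_cohort(blocks, metadata, truth, out / "cohort", overwrite=True)
        outputs.extend(paths.values())
        for b in blocks:
            mask_path = (out / "cohort" / f"{b.name}.csv").with_suffix(".lod.csv")
            if mask_path.exists():
                outputs.append(mask_path)

        stage = "preprocess"
        qc_reports = []
        clean_blocks = []
        for b in blocks:
            fb, report = pp.filter_lod(b, max_frac_below=cfg["qc"]["max_frac_below"])
            fb, _ = pp.qc_exclude_assays(fb, control_deviation=None)
            clean_blocks.append(fb)
            qc_reports.append(report.assign(block=b.name))
        _write(pd.concat(qc_reports), "qc/lod_filter_report.csv")
        # blocks have disjoint feature namespaces, so the sample overview PCA
        # runs within each block (shared-panel blocks could be stacked instead)
        pca_tables, var_rows = [], []
        for b in clean_blocks:
            pca_table, evr = pp.pca_overview([b])
            pca_tables.append(pca_table)
            var_rows.append(
                pd.DataFrame(
                    {"block": b.name, "component": np.arange(1, evr.size + 1),
                     "explained_variance_frac": evr}
                )
            )
        _write(pd.concat(pca_tables, ignore_index=True), "qc/pca_overview.csv", index=False)
        _write(pd.concat(var_rows, ignore_index=True), "qc/pca_variance.csv", index=False)

        stage = "cross_sectional"
        covariates = tuple(cfg["cross_sectional"]["covariates"])
        summaries = []
        for b in clean_blocks:
            res = cs.fit_feature_lm(b, metadata, covariates=covariates)
            _write(res, f"cross_sectional/{b.name}_age_association.csv", index=False)
            _write(cs.volcano_table(res), f"cross_sectional/{b.name}_volcano.csv", index=False)
            summary = cs.classify_and_count(
                res, q_cut=cfg["cross_sectional"]["q_cut"], use=cfg["cross_sectional"]["use"]
            )
            summaries.append(
                {"block": b.name, "n_over": summary.n_over, "n_under": summary.n_under,
                 "n_tested": len(res)}
            )
        _write(pd.DataFrame(summaries), "cross_sectional/summary.csv", index=False)

        stage = "enet_clock"
        esec = dict(cfg["enet"])
        raw_scores = {}
        clock_summaries = {}
        signatures = {}
        results_by_block = {}
        for i, b in enumerate(clean_blocks):
            ecfg = enet.EnetConfig(
                alpha_grid=tuple(esec.get("alpha_grid", (0.1, 0.5, 0.9))),
                lambda_grid=tuple(esec["lambda_grid"]) if esec.get("lambda_grid") else None,
                n_lambda=esec.get("n_lambda", 6),
                n_runs=esec.get("n_runs", 20),
                k_folds=esec.get("k_folds", 5),
                n_perm=esec.get("n_perm", 5),
                seed=run_seed + 101 * (i + 1),
            )
            # sex enters every clock as a (penalized) covariate feature
            X = b.values.copy()
            X["sex"] = metadata.loc[b.sample_ids, "sex"].to_numpy(dtype=float)
            res = enet.run_cv_enet(X, metadata.loc[b.sample_ids, "age"], ecfg)
            results_by_block[b.name] = res
            best = res.best_index()
            clock_summaries[b.name] = res.summary()
            oob = pd.Series(res.oob_mean[best], index=b.sample_ids, name="oob_mean")
            _write(
                pd.DataFrame(
                    {"oob_mean": res.oob_mean[best], "oob_sd": res.oob_sd[best],
                     "age": metadata.loc[b.sample_ids, "age"].to_numpy()},
                    index=pd.Index(b.sample_ids, name="sample_id"),
                ),
                f"clocks/{b.name}_oob_predictions.csv",
            )
            sig = enet.extract_signature(res, freq_p_cut=cfg["validation"]["freq_p_cut"])
            signatures[b.name] = sig
            _write(sig, f"clocks/{b.name}_signature.csv", index=False)
            raw_scores[b.name] = sc.compute_scores(oob, metadata.loc[b.sample_ids, "age"])
        clock_path = out / "clocks" / "model_summary.json"
        clock_path.write_text(json.dumps(clock_summaries, indent=2, sort_keys=True))
        outputs.append(clock_path)

        stage = "aging_scores"
        raw_table = pd.DataFrame(index=metadata.index)
        for name, s in raw_scores.items():
            raw_table[name] = s
        table = sc.flag_acceleration(raw_table, z_cut=cfg["scores"]["z_cut"])
        long = (
            table.raw.rename_axis("sample_id").reset_index()
            .melt(id_vars="sample_id", var_name="block", value_name="raw_score")
            .merge(
                table.z.rename_axis("sample_id").reset_index()
                .melt(id_vars="sample_id", var_name="block", value_name="z"),
                on=["sample_id", "block"],
            )
            .merge(
                table.flags.rename_axis("sample_id").reset_index()
                .melt(id_vars="sample_id", var_name="block", value_name="flag"),
                on=["sample_id", "block"],
            )
        )
        _write(long, "scores/aging_scores.csv", index=False)
        composites = sc.composite_scores(table)
        _write(composites, "scores/composite_scores.csv", index_label="sample_id")
        bcorr, bp = sc.score_correlation_matrix(table.z)
        _write(bcorr, "scores/block_score_correlation.csv")
        _write(bp, "scores/block_score_correlation_p.csv")
        ccorr, cp = sc.score_correlation_matrix(composites)
        _write(ccorr, "scores/compartment_score_correlation.csv")
        _write(cp, "scores/compartment_score_correlation_p.csv")

        stage = "clinical_correlates"
        keep = corr.filter_min_blocks(table, min_blocks=cfg["correlates"]["min_blocks"])
        clinical_cols = [
            c for c in metadata.columns if c not in ("age", "sex", "race", "bmi")
        ]
        screen = corr.spearman_screen(
            composites.loc[keep],
            metadata.loc[keep, clinical_cols],
            adjust=cfg["correlates"].get("adjust"),
        )
        _write(screen, "correlates/spearman_screen.csv", index=False)
        _write(
            corr.heatmap_table(screen, p_max=cfg["correlates"]["p_max"]),
            "correlates/heatmap_table.csv", index=False,
        )

        stage = "signature_validation"
        vblock = cfg["validation"]["block"]
        if vblock is None:
            vblock = clean_blocks[0].name
        block = next(b for b in clean_blocks if b.name == vblock)
        sig = signatures[vblock]
        if sig.empty:
            # reduced permutation schedules can leave the significance filter
            # empty; fall back to the top features by selection frequency
            res = results_by_block[vblock]
            best = res.best_index()
            order = np.argsort(-res.freq[best], kind="stable")
            top = [res.feature_ids[j] for j in order if res.freq[best, j] > 0][:25]
            sig = pd.DataFrame({"feature_id": top})
            log.info("validation[%s]: empty signature, using top %d by frequency",
                     vblock, len(top))
        features = [f for f in sig["feature_id"] if f in block.values.columns]
        max_sig = cfg["validation"]["max_signature"]
        limit = len(block.sample_ids) - 2
        if max_sig is not None:
            limit = min(limit, max_sig)
        if len(features) > limit:
            log.info("validation: truncating signature %d -> %d features", len(features), limit)
            features = features[:limit]
        if len(features) >= 1:
            Xsig = pp.mean_impute(block.subset_features(features)).values
            loo = val.loocv_predict(Xsig, metadata.loc[block.sample_ids, "age"])
            _write(
                pd.DataFrame(
                    {"loocv_pred": loo.predictions,
                     "age": metadata.loc[block.sample_ids, "age"]}
                ),
                f"validation/{vblock}_loocv_predictions.csv", index_label="sample_id",
            )
            loo_summary = {"block": vblock, "r": loo.r, "p_value": loo.p_value,
                           "n_features": len(features)}
        else:
            loo_summary = {"block": vblock, "r": None, "p_value": None, "n_features": 0}
        # synthetic alternate-platform catalog: every second feature of the block
        catalog = block.feature_ids[::2]
        inter = val.intersect_features(list(sig["feature_id"]), catalog)
        _write(
            pd.DataFrame({"feature_id": inter.overlap}),
            f"validation/{vblock}_platform_overlap.csv", index=False,
        )
        vpath = out / "validation" / "loocv_summary.json"
        vpath.write_text(json.dumps(loo_summary, indent=2, sort_keys=True))
        outputs.append(vpath)
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage name
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    file_hashes = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))
    }
    manifest = {
        "seed": run_seed,
        "config_hash": config_hash,
        "version": __version__,
        "outputs": file_hashes,
        "outputs_hash": hashlib.sha256(
            json.dumps(file_hashes, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
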