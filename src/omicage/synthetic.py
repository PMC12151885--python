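"""Synthetic multi-compartment aging cohorts with known ground truth.

The generator emulates the statistical structure of a healthy-aging
multi-omics study: ~100 adults spanning ages 22-92 sampled from demographic
age bins, six compartment/omic abundance blocks (plasma/urine/muscle x
proteomics/metabolomics) whose age-associated features respond linearly to a
subject's *effective* age, a subject-level latent biological-age deviation
delta shared across blocks, per-feature sex and BMI nuisance effects,
below-limit-of-detection censoring, and clinical phenotypes coupled to
delta with known signs (hemoglobin-like negative, alkaline-phosphatase-like
positive, strength-like negative).

Model, per block b, feature j, subject i::

    x_bij = beta0_bj + beta_bj * (age_i + loading_b * delta_i)
            + gamma_sex_bj * sex_i + gamma_bmi_bj * bmi_i + eps_bij

with ``delta_i ~ Normal(0, latent_sd)`` independent of age, ``beta_bj`` zero
for the ``1 - frac_age_assoc`` null features, and eps iid Normal(0,
noise_sd). Values below each feature's ``lod_quantile`` marginal quantile
are censored: flagged in the below-LOD mask and stored as missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import OmicsBlock
from . import io as oio

log = logging.getLogger(__name__)

__all__ = [
    "BlockConfig",
    "ClinicalConfig",
    "CohortConfig",
    "GroundTruth",
    "default_config",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

# Demographic age bins (low, high, count): 23/20/18/28/12 across
# 20-34 / 35-49 / 50-64 / 65-79 / 80+ for a 101-subject plasma cohort.
DEFAULT_AGE_BINS: tuple[tuple[int, int, int], ...] = (
    (22, 34, 23),
    (35, 49, 20),
    (50, 64, 18),
    (65, 79, 28),
    (80, 92, 12),
)


@dataclass
class BlockConfig:
    """Configuration for one compartment/omic block.

    ``frac_age_assoc`` is the fraction of features given a nonzero true age
    slope; ``effect_sd`` scales those slopes (log-abundance units per year);
    ``loading`` weights the shared latent deviation delta into this block's
    effective age; ``frac_subjects`` is the fraction of the cohort actually
    measured in this block (blocks differ in n, as real compartments do).
    """

    name: str
    n_features: int
    frac_age_assoc: float = 0.33
    effect_sd: float = 0.03
    loading: float = 1.0
    noise_sd: float = 0.5
    lod_quantile: float = 0.05
    frac_subjects: float = 1.0
    sex_effect_sd: float = 0.15
    bmi_effect_sd: float = 0.01
    intercept_sd: float = 1.0
    # explicit per-feature age slopes; overrides frac_age_assoc/effect_sd draws
    fixed_beta: tuple[float, ...] | None = None

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValueError(f"block {self.name!r}: n_features must be >= 1")
        for attr in ("frac_age_assoc", "lod_quantile", "frac_subjects"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"block {self.name!r}: {attr}={v} outside [0, 1]")
        for attr in ("effect_sd", "noise_sd", "sex_effect_sd", "bmi_effect_sd", "intercept_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"block {self.name!r}: {attr} must be >= 0")
        if self.fixed_beta is not None and len(self.fixed_beta) != self.n_features:
            raise ValueError(
                f"block {self.name!r}: fixed_beta length {len(self.fixed_beta)} "
                f"!= n_features {self.n_features}"
            )


@dataclass
class ClinicalConfig:
    """One simulated clinical covariate.

    ``value = intercept + age_slope*age + sex_shift*sex + delta_loading*delta
    + Normal(0, noise_sd)``. The sign of ``delta_loading`` encodes how the
    phenotype moves with accelerated biological aging.
    """

    name: str
    intercept: float
    age_slope: float
    sex_shift: float
    delta_loading: float
    noise_sd: float


DEFAULT_CLINICAL: tuple[ClinicalConfig, ...] = (
    # anemia-adjacent phenotype: lower with accelerated aging
    ClinicalConfig("hemoglobin", 14.0, -0.005, 1.3, -0.08, 0.6),
    # hepatic calcification marker: higher with accelerated aging
    ClinicalConfig("alk_phosphatase", 65.0, 0.10, 4.0, 1.5, 9.0),
    # muscle strength: lower with age and with accelerated aging
    ClinicalConfig("knee_strength", 42.0, -0.18, 11.0, -0.50, 4.0),
    # anthropometric used only as an adjustment covariate (no delta coupling)
    ClinicalConfig("height", 163.0, 0.0, 13.0, 0.0, 6.0),
    # gait metric; depends on stature, screened with height adjustment
    ClinicalConfig("walk_speed", 1.35, -0.004, 0.05, -0.012, 0.10),
)


@dataclass
class CohortConfig:
    """Full cohort specification; ``seed`` makes the draw reproducible."""

    n_subjects: int = 101
    age_range: tuple[float, float] = (22.0, 92.0)
    age_bins: tuple[tuple[float, float, int], ...] | None = DEFAULT_AGE_BINS
    blocks: tuple[BlockConfig, ...] = ()
    latent_sd: float = 5.0
    seed: int = 0
    clinical: tuple[ClinicalConfig, ...] = DEFAULT_CLINICAL
    male_frac: float = 0.55
    white_frac: float = 0.82
    bmi_mean: float = 25.6
    bmi_sd: float = 3.0
    bmi_range: tuple[float, float] = (18.0, 30.0)

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range low must be < high, got {self.age_range}")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")
        if self.age_bins is not None:
            counts = [c for (_, _, c) in self.age_bins]
            if any(c < 0 for c in counts):
                raise ValueError("age bin counts must be non-negative")
            if sum(counts) != self.n_subjects:
                raise ValueError(
                    f"age bin counts sum to {sum(counts)}, expected n_subjects={self.n_subjects}"
                )
            for blo, bhi, _ in self.age_bins:
                if not blo <= bhi:
                    raise ValueError(f"invalid age bin ({blo}, {bhi})")
        for b in self.blocks:
            b.validate()


def default_config(seed: int = 0, scale: float = 1.0) -> CohortConfig:
    """Default six-block cohort mirroring the study's compartment layout.

    ``scale`` multiplies feature counts so smoke tests can shrink the blocks
    without changing their statistical structure. Per-block signal fractions
    follow the observed cross-sectional detection rates (about a third of
    plasma proteins age-associated, about a tenth in urine).
    """

    def p(n: int) -> int:
        return max(10, int(round(n * scale)))

    blocks = (
        BlockConfig("plasma_proteomics", p(500), frac_age_assoc=0.33),
        BlockConfig("plasma_metabolomics", p(200), frac_age_assoc=0.30),
        BlockConfig("muscle_proteomics", p(400), frac_age_assoc=0.30, frac_subjects=0.50),
        BlockConfig("muscle_metabolomics", p(120), frac_age_assoc=0.25, frac_subjects=0.87),
        BlockConfig("urine_proteomics", p(350), frac_age_assoc=0.11, frac_subjects=0.94),
        BlockConfig("urine_metabolomics", p(90), frac_age_assoc=0.25, frac_subjects=0.80),
    )
    return CohortConfig(blocks=blocks, seed=seed)


@dataclass
class GroundTruth:
    """Latent quantities the generator knows and the pipeline must recover."""

    delta: pd.Series  # per-subject latent biological-age deviation (years)
    beta_age: dict[str, pd.Series] = field(default_factory=dict)  # block -> per-feature slope
    signal_mask: dict[str, pd.Series] = field(default_factory=dict)  # block -> slope != 0
    clinical_loadings: pd.Series | None = None  # covariate -> delta coupling


def _sample_ages(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    if config.age_bins is None:
        lo, hi = config.age_range
        return rng.uniform(lo, hi, size=config.n_subjects)
    ages = []
    for lo, hi, count in config.age_bins:
        ages.append(rng.uniform(lo, hi, size=count))
    ages = np.concatenate(ages) if ages else np.empty(0)
    rng.shuffle(ages)
    return ages


def _truncated_normal(mean, sd, lo, hi, size, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(size - filled, keep.size)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _simulate_block(
    cfg: BlockConfig,
    metadata: pd.DataFrame,
    delta: pd.Series,
    rng: np.random.Generator,
) -> tuple[OmicsBlock, pd.Series, pd.Series]:
    n_all = len(metadata)
    n_meas = max(3, int(round(cfg.frac_subjects * n_all)))
    idx = np.sort(rng.choice(n_all, size=n_meas, replace=False)) if n_meas < n_all else np.arange(n_all)
    meta = metadata.iloc[idx]
    feature_ids = [f"{cfg.name}_f{j:04d}" for j in range(cfg.n_features)]

    if cfg.fixed_beta is not None:
        beta = np.asarray(cfg.fixed_beta, dtype=float)
        signal = beta != 0.0
    else:
        n_signal = int(round(cfg.frac_age_assoc * cfg.n_features))
        signal = np.zeros(cfg.n_features, dtype=bool)
        signal[rng.choice(cfg.n_features, size=n_signal, replace=False)] = True
        beta = np.zeros(cfg.n_features)
        if n_signal:
            mag = np.abs(rng.normal(cfg.effect_sd, cfg.effect_sd / 2, size=n_signal))
            mag = np.maximum(mag, cfg.effect_sd / 4)  # keep slopes bounded away from 0
            # ~70% of age-associated features over-represented (rise with age)
            sign = np.where(rng.random(n_signal) < 0.7, 1.0, -1.0)
            beta[signal] = sign * mag

    beta0 = rng.normal(0.0, cfg.intercept_sd, size=cfg.n_features)
    gamma_sex = rng.normal(0.0, cfg.sex_effect_sd, size=cfg.n_features)
    gamma_bmi = rng.normal(0.0, cfg.bmi_effect_sd, size=cfg.n_features)

    eff_age = meta["age"].to_numpy() + cfg.loading * delta.loc[meta.index].to_numpy()
    x = (
        beta0[None, :]
        + np.outer(eff_age, beta)
        + np.outer(meta["sex"].to_numpy(), gamma_sex)
        + np.outer(meta["bmi"].to_numpy(), gamma_bmi)
        + rng.normal(0.0, cfg.noise_sd, size=(n_meas, cfg.n_features))
    )

    values = pd.DataFrame(x, index=meta.index, columns=feature_ids)
    mask = pd.DataFrame(False, index=meta.index, columns=feature_ids)
    if cfg.lod_quantile > 0:
        cutoffs = np.quantile(x, cfg.lod_quantile, axis=0)
        below = x < cutoffs[None, :]
        mask.loc[:, :] = below
        values = values.mask(mask)

    block = OmicsBlock(values=values, below_lod=mask, name=cfg.name)
    return (
        block,
        pd.Series(beta, index=feature_ids, name="beta_age"),
        pd.Series(signal, index=feature_ids, name="signal"),
    )


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[OmicsBlock], pd.DataFrame, GroundTruth]:
    """Draw a full multi-block cohort.

    Returns the blocks, a metadata table (age, sex, race, bmi and the
    clinical covariates) keyed by sample ID, and the :class:`GroundTruth`.
    Bit-identical for identical configs (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_subjects
    sample_ids = [f"S{i:03d}" for i in range(n)]
    ages = _sample_ages(config, rng)
    sex = (rng.random(n) < config.male_frac).astype(int)
    race = (rng.random(n) < config.white_frac).astype(int)
    bmi = _truncated_normal(
        config.bmi_mean, config.bmi_sd, *config.bmi_range, size=n, rng=rng
    )
    delta = pd.Series(
        rng.normal(0.0, config.latent_sd, size=n), index=sample_ids, name="delta"
    )

    metadata = pd.DataFrame(
        {"age": ages, "sex": sex, "race": race, "bmi": bmi}, index=pd.Index(sample_ids)
    )
    metadata.index.name = oio.SAMPLE_COL

    loadings = {}
    for c in config.clinical:
        vals = (
            c.intercept
            + c.age_slope * ages
            + c.sex_shift * sex
            + c.delta_loading * delta.to_numpy()
            + rng.normal(0.0, c.noise_sd, size=n)
        )
        metadata[c.name] = vals
        loadings[c.name] = c.delta_loading

    truth = GroundTruth(
        delta=delta, clinical_loadings=pd.Series(loadings, name="delta_loading")
    )
    blocks: list[OmicsBlock] = []
    for bcfg in config.blocks:
        block, beta, signal = _simulate_block(bcfg, metadata, delta, rng)
        blocks.append(block)
        truth.beta_age[bcfg.name] = beta
        truth.signal_mask[bcfg.name] = signal
    return blocks, metadata, truth


def write_cohort(
    blocks: list[OmicsBlock],
    metadata: pd.DataFrame,
    truth: GroundTruth | None,
    dir_path: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write one CSV per block (+ mask), the metadata, and the ground truth."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    if not blocks:
        warnings.warn("write_cohort called with no blocks; writing metadata only")
    paths: dict[str, Path] = {}
    for block in blocks:
        paths[block.name] = oio.write_block(
            block, dir_path / f"{block.name}.csv", overwrite=overwrite
        )
    paths["metadata"] = oio.write_metadata(
        metadata, dir_path / "metadata.csv", overwrite=overwrite
    )
    if truth is not None:
        tp = dir_path / "ground_truth_delta.csv"
        if tp.exists() and not overwrite:
            raise FileExistsError(f"{tp} exists and overwrite=False")
        truth.delta.rename_axis(oio.SAMPLE_COL).to_csv(tp)
        paths["ground_truth_delta"] = tp
        if truth.beta_age:
            rows = []
            for bname, beta in truth.beta_age.items():
                sig = truth.signal_mask[bname]
                rows.append(
                    pd.DataFrame(
                        {
                            "block": bname,
                            "feature_id": beta.index,
                            "beta_age": beta.to_numpy(),
                            "signal": sig.to_numpy().astype(int),
                        }
                    )
                )
            fp = dir_path / "ground_truth_features.csv"
            if fp.exists() and not overwrite:
                raise FileExistsError(f"{fp} exists and overwrite=False")
            pd.concat(rows, ignore_index=True).to_csv(fp, index=False)
            paths["ground_truth_features"] = fp
        if truth.clinical_loadings is not None:
            cp = dir_path / "ground_truth_clinical.csv"
            truth.clinical_loadings.rename_axis("covariate").to_csv(cp)
            paths["ground_truth_clinical"] = cp
    return paths


def read_cohort(dir_path: str | Path) -> tuple[list[OmicsBlock], pd.DataFrame, GroundTruth | None]:
    """Read back a cohort written by :func:`write_cohort`."""
    dir_path = Path(dir_path)
    metadata = oio.read_metadata(dir_path / "metadata.csv")
    blocks = []
    skip = {"metadata.csv", "ground_truth_delta.csv", "ground_truth_features.csv",
            "ground_truth_clinical.csv"}
    for path in sorted(dir_path.glob("*.csv")):
        if path.name in skip or path.name.endswith(".lod.csv"):
            continue
        blocks.append(oio.read_block(path))
    truth = None
    dp = dir_path / "ground_truth_delta.csv"
    if dp.exists():
        delta = pd.read_csv(dp, index_col=0)["delta"]
        delta.index = delta.index.astype(str)
        truth = GroundTruth(delta=delta)
        fp = dir_path / "ground_truth_features.csv"
        if fp.exists():
            feats = pd.read_csv(fp)
            for bname, grp in feats.groupby("block"):
                truth.beta_age[bname] = pd.Series(
                    grp["beta_age"].to_numpy(), index=grp["feature_id"], name="beta_age"
                )
                truth.signal_mask[bname] = pd.Series(
                    grp["signal"].to_numpy().astype(bool), index=grp["feature_id"], name="signal"
                )
        cp = dir_path / "ground_truth_clinical.csv"
        if cp.exists():
            truth.clinical_loadings = pd.read_csv(cp, index_col=0)["delta_loading"]
    return blocks, metadata, truth
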