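"""Synthetic multi-region expression cohorts with known ground truth.

The generator emulates the design of a repeated-measures brain-expression
study: a case/control cohort in which each subject contributes samples from
several brain regions (with some subject–region samples missing), FPKM-scale
expression with a decreasing mean–variance trend, within-subject correlation
induced by a subject random intercept, age and sex covariate effects, and a
configurable fraction of truly differentially expressed genes.

On the log2 scale each observation is

    y_gij = b_g + d_g·[case] + r_{g,region} + a·(age−mean age) + s·[female]
            + u_{g,subject} + e_gij

with ``u ~ N(0, τ²)`` and ``e ~ N(0, trend(b_g)²)``; the emitted matrix is
FPKM-scale, ``max(2^y − offset, 0)``. The ground truth records which genes
were planted and their exact log2 fold change, enabling parameter-recovery
and calibration tests downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataio import (
    METADATA_COLUMNS,
    write_expression_matrix,
    write_metadata,
    read_expression_matrix,
)

__all__ = [
    "CohortDesign",
    "SimulationParams",
    "GroundTruth",
    "default_trend",
    "generate_metadata",
    "simulate_expression",
    "write_fixture",
]

#: Default brain regions: hippocampus, temporal cortex, parietal cortex,
#: forebrain white matter.
DEFAULT_REGIONS = ("HIP", "TCx", "PCx", "FWM")


def default_trend(mu: np.ndarray) -> np.ndarray:
    """Default mean–variance trend: residual sd as a function of mean log2
    expression, ``sd(μ) = 0.2 + 1.5·exp(−0.4·μ)``.

    Decreasing and strictly positive, mimicking RNA-seq-like
    heteroskedasticity where low-expressed genes are noisier.
    """
    return 0.2 + 1.5 * np.exp(-0.4 * np.asarray(mu, dtype=float))


@dataclass
class CohortDesign:
    """Design of the subject cohort and its regional sampling.

    Defaults mirror a cohort of 15 case and 30 control subjects sampled in
    four brain regions, with a uniform per-(subject, region) missingness
    rate of 1/12 so that the expected sample count is 165 of the 180
    possible subject–region pairs.
    """

    n_case: int = 15
    n_control: int = 30
    regions: Sequence[str] = DEFAULT_REGIONS
    missing_rate: float = 1.0 / 12.0
    age_mean: float = 88.0
    age_sd: float = 6.0
    sex_balance: float = 0.44  # probability of female
    apoe4_rate_case: float = 1.0 / 3.0
    apoe4_rate_control: float = 0.10
    braak_mean_case: float = 4.1
    braak_mean_control: float = 2.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control subject")
        if len(self.regions) == 0:
            raise ValueError("regions must be non-empty")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region labels must be unique")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance must lie in [0, 1]")


@dataclass
class SimulationParams:
    """Parameters of the generative model for expression values.

    All effect sizes are on the log2 scale. ``effect_size`` is the magnitude
    δ of the planted case/control difference (each DE gene gets exactly ±δ);
    ``subject_sd`` is the random-intercept standard deviation τ; ``trend``
    maps baseline log2 mean to residual standard deviation.
    """

    n_genes: int = 2000
    de_fraction: float = 0.012
    effect_size: float = 0.653
    up_fraction: float = 0.8  # fraction of DE genes upregulated in cases
    subject_sd: float = 0.5
    trend: Callable[[np.ndarray], np.ndarray] = default_trend
    region_effect_sd: float = 0.25
    age_slope: float = 0.01  # log2 units per year
    sex_shift: float = 0.1  # log2 units, female vs male
    baseline_mean: float = 4.0
    baseline_sd: float = 2.0
    baseline_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None
    fpkm_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValueError("up_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Which genes were planted as DE and with what log2 fold change."""

    gene_ids: list[str]
    de_flags: np.ndarray
    true_logfc: np.ndarray
    true_params: SimulationParams

    def __post_init__(self) -> None:
        flags = np.asarray(self.de_flags, dtype=bool)
        lfc = np.asarray(self.true_logfc, dtype=float)
        if not np.array_equal(flags, lfc != 0):
            raise ValueError("de_flags must be true exactly where true_logfc != 0")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "is_de": self.de_flags.astype(int),
             "true_logfc": self.true_logfc}
        )


def generate_metadata(design: CohortDesign) -> pd.DataFrame:
    """Draw the sample-metadata table for a cohort design.

    One row per retained subject–region pair. Subject attributes are drawn
    once per subject: age from Normal(age_mean, age_sd) truncated below at
    60, sex from Bernoulli(sex_balance), APOE ε4 carrier status from the
    per-group rates, and an integer Braak stage in 0–6. Missingness removes
    each subject–region pair independently with probability
    ``missing_rate``; a subject who would lose every region has their
    missingness pattern resampled, so every subject retains at least one
    sample. Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    groups = [("AD", design.n_case, design.apoe4_rate_case, design.braak_mean_case),
              ("control", design.n_control, design.apoe4_rate_control,
               design.braak_mean_control)]
    for diagnosis, n_subj, apoe_rate, braak_mean in groups:
        prefix = "AD" if diagnosis == "AD" else "CT"
        for i in range(n_subj):
            subject_id = f"{prefix}{i + 1:03d}"
            age = float(rng.normal(design.age_mean, design.age_sd))
            while age < 60.0:  # truncation: ages below 60 are resampled
                age = float(rng.normal(design.age_mean, design.age_sd))
            sex = "F" if rng.random() < design.sex_balance else "M"
            apoe4 = int(rng.random() < apoe_rate)
            braak = int(np.clip(round(rng.normal(braak_mean, 1.4)), 0, 6))
            keep = rng.random(len(design.regions)) >= design.missing_rate
            while not keep.any():  # no subject loses all regions
                keep = rng.random(len(design.regions)) >= design.missing_rate
            for region, k in zip(design.regions, keep):
                if not k:
                    continue
                rows.append({
                    "sample_id": f"{subject_id}_{region}",
                    "subject_id": subject_id,
                    "region": region,
                    "diagnosis": diagnosis,
                    "age": round(age, 2),
                    "sex": sex,
                    "apoe4": apoe4,
                    "braak": braak,
                })
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


def _plant_effects(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Per-gene true log2 fold changes: ±effect_size for DE genes, else 0."""
    n_de = round(params.de_fraction * params.n_genes)
    logfc = np.zeros(params.n_genes)
    if n_de == 0:
        return logfc
    de_idx = rng.choice(params.n_genes, size=n_de, replace=False)
    n_up = round(params.up_fraction * n_de)
    signs = np.full(n_de, -1.0)
    signs[:n_up] = 1.0
    rng.shuffle(signs)
    logfc[de_idx] = signs * params.effect_size
    return logfc


def simulate_expression(
    meta: pd.DataFrame,
    params: SimulationParams,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an FPKM-scale expression matrix for a metadata table.

    Returns the genes × samples matrix and the ground truth. ``seed``
    defaults to a fixed value so results are reproducible by default.
    """
    if meta.empty:
        raise ValueError("metadata table is empty")
    rng = np.random.default_rng(0 if seed is None else seed)
    G = params.n_genes
    n = len(meta)

    if params.baseline_dist is not None:
        baseline = np.asarray(params.baseline_dist(rng, G), dtype=float)
    else:
        baseline = rng.normal(params.baseline_mean, params.baseline_sd, G)
    resid_sd = np.asarray(params.trend(baseline), dtype=float)
    if (resid_sd <= 0).any():
        raise ValueError("trend must be strictly positive over the baseline support")

    true_logfc = _plant_effects(params, rng)

    subjects = meta["subject_id"].to_numpy()
    uniq_subjects, subj_codes = np.unique(subjects, return_inverse=True)
    regions = meta["region"].to_numpy()
    uniq_regions, region_codes = np.unique(regions, return_inverse=True)
    is_case = (meta["diagnosis"].to_numpy() == "AD").astype(float)
    age = meta["age"].to_numpy(dtype=float)
    female = (meta["sex"].astype(str).str.upper().isin({"F", "FEMALE", "1"})
              ).to_numpy().astype(float)

    # gene-specific region offsets and subject random intercepts
    region_eff = rng.normal(0.0, params.region_effect_sd, (G, len(uniq_regions)))
    u_subject = rng.normal(0.0, params.subject_sd, (G, len(uniq_subjects)))
    eps = rng.normal(0.0, 1.0, (G, n)) * resid_sd[:, None]

    signal = (
        baseline[:, None]
        + true_logfc[:, None] * is_case[None, :]
        + region_eff[:, region_codes]
        + params.age_slope * (age - age.mean())[None, :]
        + params.sex_shift * female[None, :]
        + u_subject[:, subj_codes]
        + eps
    )
    fpkm = np.maximum(np.exp2(signal) - params.fpkm_offset, 0.0)

    gene_ids = [f"G{i + 1:05d}" for i in range(G)]
    matrix = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"),
                          columns=meta["sample_id"].to_numpy())
    truth = GroundTruth(gene_ids=gene_ids, de_flags=true_logfc != 0,
                        true_logfc=true_logfc, true_params=params)
    return matrix, truth


def write_fixture(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write expression TSV, metadata CSV and ground-truth CSV to a directory.

    Validates that the matrix columns and metadata sample IDs agree, and
    refuses to overwrite existing files unless told to.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if list(matrix.columns) != list(meta["sample_id"]):
        raise ValueError("sample IDs of expression matrix and metadata disagree")
    paths = {
        "expression": out_dir / "expression.tsv",
        "metadata": out_dir / "metadata.csv",
        "truth": out_dir / "truth.csv",
    }
    for p in paths.values():
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
    write_expression_matrix(matrix, paths["expression"], overwrite=overwrite)
    write_metadata(meta, paths["metadata"], overwrite=overwrite)
    truth.as_frame().to_csv(paths["truth"], index=False, float_format="%.12g")
    return paths


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
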