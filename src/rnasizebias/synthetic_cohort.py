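"""Synthetic cohorts with known transcript-size bias.

The generator emulates the matrix-level structure the diagnostics assume: a
reference of log10-normal transcript lengths (with a lncRNA mode near 550
bp), log-normal true abundances, a power-law size bias on expected TPM (the
quantity the expression-size regression estimates), logistic short-transcript
dropout of capture efficiency, size-dependent log-normal measurement noise,
and a 0.1-TPM detection floor.  Every generative parameter is recorded so
pipeline estimates can be compared against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DimensionError, ValidationError
from .expression_io import ExpressionMatrix, TPM
from .reference_sizes import Biotype, TranscriptSizeTable

#: length bounds of the reference inventory (shortest and longest annotated
#: mRNA transcripts, 180 bp to 43,816 bp); simulated lengths are clipped here.
LENGTH_MIN_BP = 180
LENGTH_MAX_BP = 43_816


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    Size model: per-biotype normal components in log10 bp.  Abundance model:
    log10 true abundance ~ Normal(abundance_log10_mean, abundance_log10_sd),
    emulating a common-core panel of moderately-to-well-expressed genes.
    Expected TPM is proportional to abundance x (L/1000)^bias_beta x pi(L),
    where pi is a logistic capture-efficiency curve in log10 length rising
    around ``dropout_mid_bp``.  Observed log10 TPM adds normal noise with
    SD sigma_g = noise_sigma0 + noise_gamma * (log10 L_g - mean log10 L).
    """

    n_genes: int = 10_000
    n_samples: int = 12
    lncrna_fraction: float = 0.255
    mrna_log10_mean: float = 3.4
    mrna_log10_sd: float = 0.35
    lncrna_log10_mean: float = math.log10(550.0)
    lncrna_log10_sd: float = 0.25
    abundance_log10_mean: float = 1.5
    abundance_log10_sd: float = 0.6
    bias_beta: float = -0.65
    dropout_mid_bp: float = 800.0
    dropout_steepness: float = 4.0
    dropout_bernoulli: bool = False
    noise_sigma0: float = 0.15
    noise_gamma: float = 0.0
    detection_floor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not 0.0 <= self.lncrna_fraction <= 1.0:
            raise ValidationError("lncrna_fraction must be in [0, 1]")
        for name in ("mrna_log10_sd", "lncrna_log10_sd", "abundance_log10_sd",
                     "noise_sigma0"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("dropout_mid_bp", "dropout_steepness"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.detection_floor < 0:
            raise ValidationError("detection_floor must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A simulated dataset together with its full generative record."""

    table: TranscriptSizeTable
    true_abundance: pd.Series
    expected_tpm: pd.Series
    matrix: ExpressionMatrix
    config: SimulationConfig


def capture_efficiency(lengths_bp: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Logistic capture probability pi(L) rising around dropout_mid_bp."""
    x = np.log10(np.asarray(lengths_bp, dtype=float)) - math.log10(cfg.dropout_mid_bp)
    return 1.0 / (1.0 + np.exp(-cfg.dropout_steepness * x))


def simulate_reference(cfg: SimulationConfig) -> TranscriptSizeTable:
    """Draw a transcript-size table from the per-biotype length mixture."""
    rng = np.random.default_rng([cfg.seed, 1])
    n_lnc = int(round(cfg.n_genes * cfg.lncrna_fraction))
    n_mrna = cfg.n_genes - n_lnc
    log_mrna = rng.normal(cfg.mrna_log10_mean, cfg.mrna_log10_sd, n_mrna)
    log_lnc = rng.normal(cfg.lncrna_log10_mean, cfg.lncrna_log10_sd, n_lnc)
    lengths = np.concatenate([10.0 ** log_mrna, 10.0 ** log_lnc])
    lengths = np.clip(np.rint(lengths), LENGTH_MIN_BP, LENGTH_MAX_BP).astype(int)
    biotypes = [Biotype.MRNA.value] * n_mrna + [Biotype.LNCRNA.value] * n_lnc
    width = len(str(cfg.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    df = pd.DataFrame(
        {"length_bp": lengths, "biotype": biotypes},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return TranscriptSizeTable(df, source_label=f"synthetic(seed={cfg.seed})")


def simulate_cohort(cfg: SimulationConfig, table: TranscriptSizeTable | None = None) -> SyntheticCohort:
    """Simulate an observed TPM matrix over a (possibly shared) size table.

    Expected TPM is abundance x (L/1000)^beta x pi(L), column-rescaled to sum
    1e6; observed values add log10-normal noise per cell, are rescaled again,
    and cells below the detection floor are set to 0.
    """
    if table is None:
        table = simulate_reference(cfg)
    if len(table) != cfg.n_genes:
        raise DimensionError(
            f"config expects {cfg.n_genes} genes, table has {len(table)}"
        )
    rng = np.random.default_rng([cfg.seed, 2])
    lengths = table.entries["length_bp"].to_numpy(float)
    log_len = np.log10(lengths)

    abundance = 10.0 ** rng.normal(cfg.abundance_log10_mean, cfg.abundance_log10_sd, cfg.n_genes)
    expected = abundance * (lengths / 1000.0) ** cfg.bias_beta
    if cfg.dropout_bernoulli:
        keep = rng.random((cfg.n_genes, cfg.n_samples)) < capture_efficiency(lengths, cfg)[:, None]
    else:
        expected = expected * capture_efficiency(lengths, cfg)
        keep = None
    expected = expected / expected.sum() * 1e6

    sigma = cfg.noise_sigma0 + cfg.noise_gamma * (log_len - log_len.mean())
    sigma = np.clip(sigma, 0.0, None)
    noise = rng.normal(0.0, 1.0, (cfg.n_genes, cfg.n_samples)) * sigma[:, None]
    observed = expected[:, None] * 10.0 ** noise
    if keep is not None:
        observed = observed * keep
    col_sums = observed.sum(axis=0)
    if (col_sums <= 0).any():
        raise DimensionError("a simulated sample has zero total signal")
    observed = observed / col_sums * 1e6  # rescale before flooring
    observed[observed < cfg.detection_floor] = 0.0

    sample_ids = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]
    matrix = ExpressionMatrix(
        pd.DataFrame(observed, index=table.gene_ids, columns=sample_ids),
        unit=TPM,
        dataset_label=f"synthetic(seed={cfg.seed},beta={cfg.bias_beta})",
    )
    return SyntheticCohort(
        table=table,
        true_abundance=pd.Series(abundance, index=table.gene_ids, name="true_abundance"),
        expected_tpm=pd.Series(expected, index=table.gene_ids, name="expected_tpm"),
        matrix=matrix,
        config=cfg,
    )


def ground_truth_report(cohort: SyntheticCohort) -> dict:
    """Generative parameters plus realized summaries of a cohort.

    Includes the realized slope of log10 expected TPM on log10 length (what
    an ideal, noise-free pipeline would estimate) and the fraction of genes
    whose expected TPM lies below the detection floor.
    """
    cfg = cohort.config
    lengths = cohort.table.entries["length_bp"].to_numpy(float)
    expected = cohort.expected_tpm.to_numpy(float)
    pos = expected > 0
    fit = sps.linregress(np.log10(lengths[pos]), np.log10(expected[pos]))
    return {
        "config": cfg.to_dict(),
        "realized": {
            "expected_tpm_slope": float(fit.slope),
            "expected_tpm_intercept": float(fit.intercept),
            "subfloor_fraction": float((expected < cfg.detection_floor).mean()),
            "n_genes": int(cfg.n_genes),
            "n_samples": int(cfg.n_samples),
        },
    }


def write_truth_record(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_record(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
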