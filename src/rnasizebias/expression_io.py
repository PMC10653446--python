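"""Expression-matrix I/O, unit conversion, normalization, and filtering.

The filtering cascade mirrors a fixed, documented order: genes are first
screened on mean raw counts, counts are converted to TPM, individual TPM
values below the detection floor are designated 0, and genes whose post-floor
mean TPM falls below the omission threshold are dropped.  Median-of-ratios
size factors and scaling to a common total are available as explicit,
separately applied normalizations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateSampleError,
    MissingLengthError,
    NoReferenceGeneError,
    UnitError,
    ValidationError,
)
from .reference_sizes import TranscriptSizeTable

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
TPM = "tpm"
_UNITS = {RAW_COUNTS, TPM}


@dataclass
class ExpressionMatrix:
    """Gene x sample nonnegative expression values with a unit tag.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    """

    values: pd.DataFrame
    unit: str
    dataset_label: str = ""

    def __post_init__(self):
        if self.unit not in _UNITS:
            raise UnitError(f"unit must be one of {sorted(_UNITS)}, got {self.unit!r}")
        v = self.values
        if not v.index.is_unique:
            # duplicate gene ids are legal on input; collapse_duplicate_genes
            # resolves them, so only warn here
            logger.warning(
                "matrix %r has %d duplicated gene id(s)",
                self.dataset_label,
                int(v.index.duplicated().sum()),
            )
        if not v.columns.is_unique:
            raise ValidationError("sample ids must be unique")
        arr = v.to_numpy(dtype=float)
        if arr.size and (np.nanmin(arr) < 0 or not np.isfinite(arr).all()):
            raise ValidationError("expression values must be finite and nonnegative")
        self.values = v.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_unit(self, unit: str, op: str) -> None:
        if self.unit != unit:
            raise UnitError(f"{op} requires a {unit} matrix, got {self.unit}")

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, unit=self.unit, dataset_label=self.dataset_label)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering / normalization cascade.

    tpm_floor
        Per-cell TPM below which a measurement is designated 0 (detection
        floor, default 0.1).
    mean_tpm_min
        Genes with post-floor mean TPM below this are omitted (default 0.1).
    raw_mean_min
        Genes with mean raw count below this never enter the analysis
        (default 3).
    low_expr_threshold
        Mean-TPM cutoff for the "weakly expressed" profile (default 1).
    common_total
        Per-sample total that cross-dataset comparisons are rescaled to
        (default 200,000).
    """

    tpm_floor: float = 0.1
    mean_tpm_min: float = 0.1
    raw_mean_min: float = 3.0
    low_expr_threshold: float = 1.0
    common_total: float = 200_000.0

    def __post_init__(self):
        for name in ("tpm_floor", "mean_tpm_min", "raw_mean_min", "low_expr_threshold", "common_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class FilterReport:
    """Per-step removal counts of :func:`apply_filters`."""

    n_genes_in: int
    n_dropped_raw_mean: int
    n_cells_floored: int
    n_dropped_mean_tpm: int
    n_genes_out: int
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def tpm_from_counts(matrix: ExpressionMatrix, table: TranscriptSizeTable) -> ExpressionMatrix:
    """Convert raw counts to TPM: per sample, 1e6 * (c_g/L_g) / sum_h (c_h/L_h)."""
    matrix.require_unit(RAW_COUNTS, "tpm_from_counts")
    missing = matrix.gene_ids.difference(table.gene_ids)
    if len(missing):
        raise MissingLengthError(missing.tolist())
    lengths = table.entries.loc[matrix.gene_ids, "length_bp"].astype(float)
    rate = matrix.values.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    dead = denom.index[denom <= 0]
    if len(dead):
        raise DegenerateSampleError(dead.tolist())
    tpm = rate.div(denom, axis=1) * 1e6
    return ExpressionMatrix(tpm, unit=TPM, dataset_label=matrix.dataset_label)


def median_of_ratios_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Per-sample size factors: the median over reference genes of the ratio
    of each gene's count to its across-sample geometric mean.

    Reference genes are those with strictly positive counts in every sample.
    """
    matrix.require_unit(RAW_COUNTS, "median_of_ratios_factors")
    v = matrix.values
    eligible = (v > 0).all(axis=1)
    if not eligible.any():
        raise NoReferenceGeneError("no gene has positive counts in every sample")
    sub = v.loc[eligible]
    log_gm = np.log(sub).mean(axis=1)
    ratios = sub.div(np.exp(log_gm), axis=0)
    factors = ratios.median(axis=0)
    factors.name = "size_factor"
    return factors


def normalize_median_of_ratios(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its median-of-ratios size factor."""
    factors = median_of_ratios_factors(matrix)
    return matrix.with_values(matrix.values.div(factors, axis=1))


def scale_to_common_total(
    matrix: ExpressionMatrix, common_total: float = 200_000.0
) -> ExpressionMatrix:
    """Rescale each sample so its column sum equals ``common_total``."""
    matrix.require_unit(TPM, "scale_to_common_total")
    sums = matrix.values.sum(axis=0)
    dead = sums.index[sums <= 0]
    if len(dead):
        raise DegenerateSampleError(dead.tolist())
    scaled = matrix.values.div(sums, axis=1) * common_total
    return matrix.with_values(scaled)


def apply_filters(
    raw: ExpressionMatrix,
    tpm: ExpressionMatrix,
    cfg: FilterConfig | None = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply the three-step filtering cascade.

    1. Drop genes with mean raw count < ``raw_mean_min``.
    2. Designate TPM cells below ``tpm_floor`` as 0.
    3. Omit genes whose post-floor mean TPM < ``mean_tpm_min``.

    ``raw`` and ``tpm`` must share gene and sample indices.  Running the
    cascade on its own output is the identity (idempotence).
    """
    cfg = cfg or FilterConfig()
    raw.require_unit(RAW_COUNTS, "apply_filters")
    tpm.require_unit(TPM, "apply_filters")
    if not raw.gene_ids.equals(tpm.gene_ids) or not raw.sample_ids.equals(tpm.sample_ids):
        raise AlignmentError("raw and tpm matrices must share gene and sample indices")

    n_in = tpm.n_genes
    keep1 = raw.values.mean(axis=1) >= cfg.raw_mean_min
    step1 = tpm.values.loc[keep1]
    n_drop_raw = int(n_in - keep1.sum())

    floored_mask = (step1 < cfg.tpm_floor) & (step1 > 0)
    n_floored = int(floored_mask.to_numpy().sum())
    step2 = step1.where(step1 >= cfg.tpm_floor, 0.0)

    keep3 = step2.mean(axis=1) >= cfg.mean_tpm_min
    out = step2.loc[keep3]
    n_drop_mean = int(len(step2) - keep3.sum())

    report = FilterReport(
        n_genes_in=n_in,
        n_dropped_raw_mean=n_drop_raw,
        n_cells_floored=n_floored,
        n_dropped_mean_tpm=n_drop_mean,
        n_genes_out=len(out),
        config=asdict(cfg),
    )
    logger.info(
        "filter cascade %r: %d genes in, %d dropped (raw mean < %g), %d cells floored "
        "(< %g TPM), %d dropped (mean TPM < %g), %d out",
        tpm.dataset_label, n_in, n_drop_raw, cfg.raw_mean_min, n_floored,
        cfg.tpm_floor, n_drop_mean, cfg.mean_tpm_min, len(out),
    )
    return ExpressionMatrix(out, unit=TPM, dataset_label=tpm.dataset_label), report


def collapse_duplicate_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Merge rows sharing a gene id by summation, preserving first-seen order."""
    v = matrix.values
    if v.index.is_unique:
        return matrix
    order = v.index.drop_duplicates()
    collapsed = v.groupby(level=0, sort=False).sum().loc[order]
    return matrix.with_values(collapsed)


# -- I/O ---------------------------------------------------------------------

def read_expression_matrix(
    path,
    unit: str,
    dataset_label: str | None = None,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a gene x sample matrix (first column gene id, header sample ids).

    The delimiter is inferred from the extension (.csv vs .tsv/.txt) unless
    given; gzip compression is handled transparently.
    """
    name = str(path)
    if sep is None:
        stem = name[:-3] if name.endswith(".gz") else name
        sep = "," if stem.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, unit=unit, dataset_label=dataset_label or name)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")
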