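"""Size-resolved extraction-bias diagnostics.

The central question: are TPM counts, and their variability, proportional to
transcript size?  Under uniform extraction the OLS slope of log10 mean TPM on
log10 length should sit near 0, and the coefficient of variation should show
no size trend.  Negative expression-size slopes indicate relative loss of
signal tied to transcript length; positive CV-size slopes indicate that
longer transcripts are measured less reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ArityError,
    InsufficientDataError,
    InsufficientReplicationError,
    UndefinedFractionError,
)
from .expression_io import ExpressionMatrix, TPM
from .reference_sizes import Biotype, SizeBinning, TranscriptSizeTable, assign_bins

logger = logging.getLogger(__name__)


@dataclass
class TranscriptStats:
    """Per-transcript summaries across samples.

    ``frame`` is indexed by gene id with columns ``mean_tpm``, ``sd_tpm``
    (n-1 denominator), ``cv`` (sd/mean, NaN where mean is 0), and
    ``n_detected`` (samples with TPM above the floor).
    """

    frame: pd.DataFrame
    floor: float
    n_samples: int

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index


@dataclass
class RegressionResult:
    """Ordinary least-squares fit in log10-log10 space."""

    slope: float
    intercept: float
    slope_se: float
    n_points: int
    r_squared: float
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "n_points": self.n_points,
            "r_squared": self.r_squared,
            "n_excluded": self.n_excluded,
        }


@dataclass
class CvRegressionResult(RegressionResult):
    """CV-size fit plus the pooled mean CV of the included genes."""

    mean_cv: float = float("nan")

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["mean_cv"] = self.mean_cv
        return d


@dataclass
class SampleRegressionSet:
    """Per-sample expression-size fits for one dataset."""

    dataset_label: str
    sample_ids: list[str]
    slopes: np.ndarray
    intercepts: np.ndarray
    n_transcripts: np.ndarray
    excluded_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dataset_label": self.dataset_label,
            "sample_ids": list(self.sample_ids),
            "slopes": [float(s) for s in self.slopes],
            "intercepts": [float(b) for b in self.intercepts],
            "n_transcripts": [int(n) for n in self.n_transcripts],
            "excluded_samples": list(self.excluded_samples),
        }


@dataclass
class LowExpressionProfile:
    """Size profile of weakly expressed genes (0 < mean TPM < threshold)."""

    bin_counts: np.ndarray
    total: int
    n_unbinned: int
    threshold: float


@dataclass
class CommonCore:
    """Intersection of per-dataset detected-gene sets with Venn-style counts."""

    intersection: set
    region_counts: dict[str, int]
    exclusive_counts: list[int]


def transcript_stats(matrix: ExpressionMatrix, floor: float = 0.1) -> TranscriptStats:
    """Per-gene mean, SD, CV, and detection count over all samples.

    Zeros (floored cells) are included in the mean and SD; the CV is left
    undefined (NaN) for genes whose mean is 0.
    """
    matrix.require_unit(TPM, "transcript_stats")
    if matrix.n_samples < 2:
        raise InsufficientReplicationError(
            f"need >= 2 samples, got {matrix.n_samples}"
        )
    v = matrix.values
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    cv = sd.where(mean > 0) / mean.where(mean > 0)
    n_detected = (v > floor).sum(axis=1)
    frame = pd.DataFrame(
        {"mean_tpm": mean, "sd_tpm": sd, "cv": cv, "n_detected": n_detected}
    )
    return TranscriptStats(frame=frame, floor=floor, n_samples=matrix.n_samples)


def _ols_log10(x: np.ndarray, y: np.ndarray, n_excluded: int) -> RegressionResult:
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 points for a fit, got {x.size}")
    fit = sps.linregress(np.log10(x), np.log10(y))
    r2 = float(fit.rvalue) ** 2
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        n_points=int(x.size),
        r_squared=0.0 if np.isnan(r2) else r2,
        n_excluded=n_excluded,
    )


def expression_size_regression(
    stats: TranscriptStats, table: TranscriptSizeTable
) -> RegressionResult:
    """OLS of log10 mean TPM on log10 length.

    Genes with zero mean TPM or no reference length are excluded and counted
    in ``n_excluded``.  A slope near 0 is the proportional-recovery ideal.
    """
    df = stats.frame.join(table.entries["length_bp"], how="left")
    usable = (df["mean_tpm"] > 0) & df["length_bp"].notna()
    n_excl = int((~usable).sum())
    if n_excl:
        logger.info("expression_size_regression: excluded %d gene(s)", n_excl)
    sub = df.loc[usable]
    return _ols_log10(
        sub["length_bp"].to_numpy(float), sub["mean_tpm"].to_numpy(float), n_excl
    )


def cv_size_regression(
    stats: TranscriptStats, table: TranscriptSizeTable
) -> CvRegressionResult:
    """OLS of log10 CV on log10 length, plus the pooled mean CV."""
    df = stats.frame.join(table.entries["length_bp"], how="left")
    usable = (df["cv"] > 0) & df["length_bp"].notna()
    n_excl = int((~usable).sum())
    sub = df.loc[usable]
    base = _ols_log10(
        sub["length_bp"].to_numpy(float), sub["cv"].to_numpy(float), n_excl
    )
    return CvRegressionResult(
        **base.to_dict(), mean_cv=float(sub["cv"].mean())
    )


def per_sample_regressions(
    matrix: ExpressionMatrix,
    table: TranscriptSizeTable,
    floor: float = 0.1,
) -> SampleRegressionSet:
    """Per-sample OLS of log10 TPM on log10 length over cells above the floor.

    Uses individual per-cell TPM values, not per-transcript means; samples
    with fewer than 3 usable genes are flagged, excluded, and logged.
    """
    matrix.require_unit(TPM, "per_sample_regressions")
    lengths = table.entries["length_bp"].reindex(matrix.gene_ids)
    has_len = lengths.notna().to_numpy()
    log_len = np.log10(lengths.to_numpy(float))
    sample_ids, slopes, intercepts, ns, excluded = [], [], [], [], []
    for sample in matrix.sample_ids:
        col = matrix.values[sample].to_numpy(float)
        use = has_len & (col > floor)
        if use.sum() < 3:
            logger.warning(
                "sample %r has %d usable gene(s); excluded from per-sample fits",
                sample, int(use.sum()),
            )
            excluded.append(str(sample))
            continue
        fit = sps.linregress(log_len[use], np.log10(col[use]))
        sample_ids.append(str(sample))
        slopes.append(float(fit.slope))
        intercepts.append(float(fit.intercept))
        ns.append(int(use.sum()))
    return SampleRegressionSet(
        dataset_label=matrix.dataset_label,
        sample_ids=sample_ids,
        slopes=np.array(slopes, float),
        intercepts=np.array(intercepts, float),
        n_transcripts=np.array(ns, int),
        excluded_samples=excluded,
    )


def low_expression_profile(
    stats: TranscriptStats,
    table: TranscriptSizeTable,
    binning: SizeBinning | None = None,
    threshold: float = 1.0,
) -> LowExpressionProfile:
    """Per-size-bin counts of weakly expressed genes (0 < mean TPM < threshold).

    ``total`` counts every such gene; genes without a reference length cannot
    be binned and are reported in ``n_unbinned``.
    """
    binning = binning or SizeBinning()
    df = stats.frame.join(table.entries["length_bp"], how="left")
    low = (df["mean_tpm"] > 0) & (df["mean_tpm"] < threshold)
    total = int(low.sum())
    binnable = low & df["length_bp"].notna()
    counts = np.zeros(binning.n_bins, dtype=int)
    if binnable.any():
        idx = assign_bins(df.loc[binnable, "length_bp"].to_numpy(float), binning)
        np.add.at(counts, idx, 1)
    return LowExpressionProfile(
        bin_counts=counts,
        total=total,
        n_unbinned=int(total - binnable.sum()),
        threshold=threshold,
    )


def recovery_fraction(
    detected_ids: Iterable[str],
    table: TranscriptSizeTable,
    lo_bp: int,
    hi_bp: int,
    biotype: Biotype | str,
) -> float:
    """Fraction of reference transcripts in [lo_bp, hi_bp] that were detected."""
    lengths = table.lengths(biotype)
    in_range = lengths.index[(lengths >= lo_bp) & (lengths <= hi_bp)]
    if len(in_range) == 0:
        raise UndefinedFractionError(
            f"no {Biotype.coerce(biotype).value} reference transcripts in "
            f"[{lo_bp}, {hi_bp}] bp"
        )
    detected = set(detected_ids)
    return sum(1 for g in in_range if g in detected) / len(in_range)


def common_core(id_sets: Sequence[Iterable[str]]) -> CommonCore:
    """Intersection of detected-gene sets plus Venn-style region counts.

    For 2 or 3 sets, ``region_counts`` keys are membership strings like
    ``"110"`` (in sets 1 and 2, not 3); for more sets only the intersection
    and per-set exclusive counts are reported.
    """
    sets = [set(s) for s in id_sets]
    if len(sets) < 2:
        raise ArityError(f"need >= 2 sets, got {len(sets)}")
    inter = set.intersection(*sets)
    region_counts: dict[str, int] = {}
    if len(sets) <= 3:
        universe = set.union(*sets)
        for gene in universe:
            key = "".join("1" if gene in s else "0" for s in sets)
            region_counts[key] = region_counts.get(key, 0) + 1
    exclusive = [
        len(s - set.union(*(o for j, o in enumerate(sets) if j != i)))
        for i, s in enumerate(sets)
    ]
    return CommonCore(intersection=inter, region_counts=region_counts, exclusive_counts=exclusive)


def write_diagnostics_tsv(stats: TranscriptStats, table: TranscriptSizeTable, path) -> None:
    """Per-gene stats joined to reference lengths and biotypes."""
    df = stats.frame.join(table.entries, how="left")
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def plot_size_scatter(stats: TranscriptStats, table: TranscriptSizeTable, path,
                      response: str = "mean_tpm") -> None:
    """Optional log-log scatter of mean TPM (or CV) against length."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = stats.frame.join(table.entries["length_bp"], how="inner")
    df = df[(df[response] > 0) & df["length_bp"].notna()]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.log10(df["length_bp"]), np.log10(df[response]), s=2, alpha=0.3)
    ax.set_xlabel("log10 transcript length (bp)")
    ax.set_ylabel(f"log10 {response}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
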