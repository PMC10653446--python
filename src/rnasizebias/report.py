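"""Pipeline orchestration and the cross-dataset comparison report.

`run_qc` drives the per-dataset cascade — filters, per-transcript statistics,
expression-size and CV-size regressions, per-sample fits, low-expression
profile — and writes a diagnostics bundle per dataset.  `run_compare` joins
bundles: common-core intersection, ANOVA and SNK on per-sample slopes and
intercepts, and a consolidated JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ArityError, PipelineHaltError, ValidationError
from .expression_io import (
    ExpressionMatrix,
    FilterConfig,
    FilterReport,
    RAW_COUNTS,
    TPM,
    apply_filters,
    collapse_duplicate_genes,
    read_expression_matrix,
    scale_to_common_total,
    tpm_from_counts,
)
from .reference_sizes import (
    Biotype,
    SizeBinning,
    TranscriptSizeTable,
    read_size_table_tsv,
)
from .size_diagnostics import (
    CvRegressionResult,
    LowExpressionProfile,
    RegressionResult,
    SampleRegressionSet,
    common_core,
    cv_size_regression,
    expression_size_regression,
    low_expression_profile,
    per_sample_regressions,
    recovery_fraction,
    transcript_stats,
    write_diagnostics_tsv,
)
from .group_stats import AnovaResult, SnkResult, oneway_anova, snk_test

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class DatasetSpec:
    """One input matrix: path (or in-memory matrix), unit tag, label."""

    label: str
    path: str | None = None
    unit: str = RAW_COUNTS
    matrix: ExpressionMatrix | None = None

    def load(self) -> ExpressionMatrix:
        if self.matrix is not None:
            if self.matrix.dataset_label != self.label:
                return ExpressionMatrix(
                    self.matrix.values, unit=self.matrix.unit, dataset_label=self.label
                )
            return self.matrix
        if self.path is None:
            raise ValidationError(f"dataset {self.label!r} has neither path nor matrix")
        return read_expression_matrix(self.path, unit=self.unit, dataset_label=self.label)


@dataclass
class RunConfig:
    """Everything `run_qc` needs: inputs, thresholds, binning, output dir."""

    sizes_path: str | None = None
    size_table: TranscriptSizeTable | None = None
    datasets: list[DatasetSpec] = field(default_factory=list)
    filters: FilterConfig = field(default_factory=FilterConfig)
    binning: SizeBinning = field(default_factory=SizeBinning)
    alpha: float = 0.05
    recovery_range_bp: tuple[int, int] = (200, 1260)
    recovery_biotype: str = Biotype.MRNA.value
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    def load_table(self) -> TranscriptSizeTable:
        if self.size_table is not None:
            return self.size_table
        if self.sizes_path is None:
            raise ValidationError("config has neither sizes_path nor size_table")
        return read_size_table_tsv(self.sizes_path)


@dataclass
class DiagnosticsBundle:
    """Per-dataset outputs of the QC cascade."""

    label: str
    n_detected: int
    n_binned: int
    n_unknown_length: int
    dataset_regression: RegressionResult
    cv_regression: CvRegressionResult
    sample_regressions: SampleRegressionSet
    low_profile: LowExpressionProfile
    recovery: float | None
    filter_report: FilterReport
    detected_ids: list[str]
    stats: "object | None" = None  # TranscriptStats; not serialized

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "label": self.label,
            "n_detected": self.n_detected,
            "n_binned": self.n_binned,
            "n_unknown_length": self.n_unknown_length,
            "dataset_regression": self.dataset_regression.to_dict(),
            "cv_regression": self.cv_regression.to_dict(),
            "sample_regressions": self.sample_regressions.to_dict(),
            "low_expression_total": self.low_profile.total,
            "low_expression_threshold": self.low_profile.threshold,
            "recovery_fraction": self.recovery,
            "filter_report": dataclasses.asdict(self.filter_report),
        }


@dataclass
class CohortComparison:
    """Cross-dataset report: common core, ANOVA + SNK on slopes/intercepts."""

    labels: list[str]
    common_core_size: int
    common_core_regions: dict[str, int]
    slope_anova: AnovaResult | None
    slope_snk: SnkResult | None
    intercept_anova: AnovaResult | None
    intercept_snk: SnkResult | None
    per_dataset: list[dict]
    alpha: float

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "labels": self.labels,
            "common_core_size": self.common_core_size,
            "common_core_regions": self.common_core_regions,
            "slope_anova": self.slope_anova.to_dict() if self.slope_anova else None,
            "slope_snk": self.slope_snk.to_dict() if self.slope_snk else None,
            "intercept_anova": self.intercept_anova.to_dict() if self.intercept_anova else None,
            "intercept_snk": self.intercept_snk.to_dict() if self.intercept_snk else None,
            "per_dataset": self.per_dataset,
            "alpha": self.alpha,
        }


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def qc_dataset(
    matrix: ExpressionMatrix,
    table: TranscriptSizeTable,
    config: RunConfig,
) -> DiagnosticsBundle:
    """Run the full cascade on one dataset and collect its diagnostics."""
    matrix = collapse_duplicate_genes(matrix)
    if matrix.unit == RAW_COUNTS:
        known = matrix.gene_ids.intersection(table.gene_ids)
        dropped = matrix.n_genes - len(known)
        if dropped:
            logger.info(
                "%s: %d gene(s) without reference length dropped before TPM",
                matrix.dataset_label, dropped,
            )
        raw = matrix.with_values(matrix.values.loc[known])
        tpm = tpm_from_counts(raw, table)
        filtered, filter_report = apply_filters(raw, tpm, config.filters)
    else:
        # already TPM: the raw-count screen cannot be applied; run the floor
        # and mean-TPM steps by passing the TPM matrix as its own raw proxy
        # with the raw screen disabled
        cfg = dataclasses.replace(config.filters, raw_mean_min=0.0)
        proxy = ExpressionMatrix(
            matrix.values, unit=RAW_COUNTS, dataset_label=matrix.dataset_label
        )
        filtered, filter_report = apply_filters(proxy, matrix, cfg)
    if filtered.n_genes == 0:
        raise PipelineHaltError(
            f"{matrix.dataset_label}: no gene survived the filter cascade"
        )
    scaled = scale_to_common_total(filtered, config.filters.common_total)

    stats = transcript_stats(scaled, floor=config.filters.tpm_floor)
    detected = stats.frame.index[stats.frame["mean_tpm"] > 0]
    lengths = table.entries["length_bp"].reindex(detected)
    n_binned = int(lengths.notna().sum())

    bundle = DiagnosticsBundle(
        label=matrix.dataset_label,
        n_detected=len(detected),
        n_binned=n_binned,
        n_unknown_length=len(detected) - n_binned,
        dataset_regression=expression_size_regression(stats, table),
        cv_regression=cv_size_regression(stats, table),
        sample_regressions=per_sample_regressions(
            scaled, table, floor=config.filters.tpm_floor
        ),
        low_profile=low_expression_profile(
            stats, table, config.binning, config.filters.low_expr_threshold
        ),
        recovery=_try_recovery(detected, table, config),
        filter_report=filter_report,
        detected_ids=[str(g) for g in detected],
        stats=stats,
    )
    return bundle


def _try_recovery(detected, table, config: RunConfig) -> float | None:
    lo, hi = config.recovery_range_bp
    try:
        return recovery_fraction(detected, table, lo, hi, config.recovery_biotype)
    except Exception:  # reference range empty in this table: not an error
        return None


def run_qc(config: RunConfig) -> list[DiagnosticsBundle]:
    """Execute the cascade for every dataset in the config; write bundles."""
    if not config.datasets:
        raise ValidationError("config lists no datasets")
    table = config.load_table()
    out_root = Path(config.out_dir) if config.out_dir else None
    bundles = []
    for spec in config.datasets:
        matrix = spec.load()
        bundle = qc_dataset(matrix, table, config)
        bundles.append(bundle)
        if out_root is not None:
            _write_bundle(bundle, table, config, out_root / bundle.label)
    return bundles


def _write_bundle(
    bundle: DiagnosticsBundle,
    table: TranscriptSizeTable,
    config: RunConfig,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = bundle.to_dict()
    summary["thresholds"] = dataclasses.asdict(config.filters)
    summary["package_version"] = __version__
    _write_json(summary, out_dir / "regression_summary.json")
    profile = pd.DataFrame(
        {
            "bin_index": np.arange(config.binning.n_bins),
            "log10_left": config.binning.edges[:-1],
            "log10_right": config.binning.edges[1:],
            "count": bundle.low_profile.bin_counts,
        }
    )
    profile.to_csv(out_dir / "low_expression_profile.tsv", sep="\t", index=False,
                   float_format="%.6f")
    bundle.filter_report.to_json(out_dir / "filter_report.json")
    if bundle.stats is not None:
        write_diagnostics_tsv(bundle.stats, table, out_dir / "diagnostics.tsv")
    with open(out_dir / "detected_ids.txt", "w") as fh:
        fh.write("\n".join(bundle.detected_ids) + "\n")


def load_bundle(bundle_dir) -> DiagnosticsBundle:
    """Reload a bundle written by :func:`run_qc` for use in `run_compare`."""
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "regression_summary.json") as fh:
        d = json.load(fh)
    with open(bundle_dir / "detected_ids.txt") as fh:
        detected = [line.strip() for line in fh if line.strip()]
    sr = d["sample_regressions"]
    return DiagnosticsBundle(
        label=d["label"],
        n_detected=d["n_detected"],
        n_binned=d["n_binned"],
        n_unknown_length=d["n_unknown_length"],
        dataset_regression=RegressionResult(**d["dataset_regression"]),
        cv_regression=CvRegressionResult(**d["cv_regression"]),
        sample_regressions=SampleRegressionSet(
            dataset_label=sr["dataset_label"],
            sample_ids=sr["sample_ids"],
            slopes=np.array(sr["slopes"], float),
            intercepts=np.array(sr["intercepts"], float),
            n_transcripts=np.array(sr["n_transcripts"], int),
            excluded_samples=sr["excluded_samples"],
        ),
        low_profile=LowExpressionProfile(
            bin_counts=np.array([], int),
            total=d["low_expression_total"],
            n_unbinned=0,
            threshold=d["low_expression_threshold"],
        ),
        recovery=d["recovery_fraction"],
        filter_report=FilterReport(**d["filter_report"]),
        detected_ids=detected,
    )


def run_compare(
    bundles: Sequence[DiagnosticsBundle],
    alpha: float = 0.05,
    out_path=None,
) -> CohortComparison:
    """Cross-dataset comparison: common core plus ANOVA/SNK on sample fits."""
    if len(bundles) < 2:
        raise ArityError(f"need >= 2 bundles, got {len(bundles)}")
    labels = [b.label for b in bundles]
    core = common_core([b.detected_ids for b in bundles])

    slope_groups = [b.sample_regressions.slopes for b in bundles]
    intercept_groups = [b.sample_regressions.intercepts for b in bundles]
    can_test = all(len(g) >= 2 for g in slope_groups)
    slope_anova = slope_snk = intercept_anova = intercept_snk = None
    if can_test:
        slope_anova = oneway_anova(slope_groups)
        slope_snk = snk_test(slope_groups, alpha=alpha, labels=labels)
        intercept_anova = oneway_anova(intercept_groups)
        intercept_snk = snk_test(intercept_groups, alpha=alpha, labels=labels)
    else:
        logger.warning("a dataset has < 2 per-sample fits; ANOVA/SNK skipped")

    comparison = CohortComparison(
        labels=labels,
        common_core_size=len(core.intersection),
        common_core_regions=core.region_counts,
        slope_anova=slope_anova,
        slope_snk=slope_snk,
        intercept_anova=intercept_anova,
        intercept_snk=intercept_snk,
        per_dataset=[b.to_dict() for b in bundles],
        alpha=alpha,
    )
    if out_path is not None:
        _write_json(comparison.to_dict(), Path(out_path))
    return comparison
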