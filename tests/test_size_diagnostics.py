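"""Per-transcript statistics, size regressions, profiles, and set operations."""

import numpy as np
import pandas as pd
import pytest

from rnasizebias import (
    SimulationConfig,
    SizeBinning,
    TPM,
    TranscriptSizeTable,
    common_core,
    cv_size_regression,
    expression_size_regression,
    low_expression_profile,
    per_sample_regressions,
    recovery_fraction,
    simulate_cohort,
    transcript_stats,
)
from rnasizebias.errors import (
    ArityError,
    InsufficientDataError,
    InsufficientReplicationError,
    UndefinedFractionError,
)
from rnasizebias.size_diagnostics import TranscriptStats
from .conftest import make_matrix


def stats_from(frame):
    return TranscriptStats(frame=frame, floor=0.1, n_samples=3)


def table_of(lengths, genes=None, biotype="mRNA"):
    genes = genes or [f"g{i}" for i in range(len(lengths))]
    return TranscriptSizeTable(
        pd.DataFrame(
            {"length_bp": lengths, "biotype": biotype},
            index=pd.Index(genes, name="gene_id"),
        )
    )


class TestTranscriptStats:
    def test_constant_row(self):
        m = make_matrix([[2.0, 2.0, 2.0]], unit=TPM)
        s = transcript_stats(m).frame
        assert s.loc["g0", "mean_tpm"] == 2.0
        assert s.loc["g0", "sd_tpm"] == 0.0
        assert s.loc["g0", "cv"] == 0.0

    def test_textbook_sample_sd(self):
        m = make_matrix([[1.0, 2.0, 3.0]], unit=TPM)
        s = transcript_stats(m).frame
        assert s.loc["g0", "mean_tpm"] == 2.0
        assert s.loc["g0", "sd_tpm"] == pytest.approx(1.0)
        assert s.loc["g0", "cv"] == pytest.approx(0.5)

    def test_cv_undefined_for_zero_mean(self):
        m = make_matrix([[0.0, 0.0, 0.0]], unit=TPM)
        s = transcript_stats(m).frame
        assert np.isnan(s.loc["g0", "cv"])

    def test_n_detected_counts_cells_above_floor(self):
        m = make_matrix([[0.05, 0.2, 5.0]], unit=TPM)
        s = transcript_stats(m, floor=0.1).frame
        assert s.loc["g0", "n_detected"] == 2

    def test_matches_bruteforce_two_pass(self, rng):
        values = rng.exponential(2.0, (30, 6))
        m = make_matrix(values, unit=TPM)
        s = transcript_stats(m).frame
        for g in range(30):
            row = values[g]
            mean = sum(row) / 6
            sd = (sum((x - mean) ** 2 for x in row) / 5) ** 0.5
            assert s.iloc[g]["mean_tpm"] == pytest.approx(mean, rel=1e-12)
            assert s.iloc[g]["sd_tpm"] == pytest.approx(sd, rel=1e-9)

    def test_single_sample_errors(self):
        m = make_matrix([[1.0]], unit=TPM)
        with pytest.raises(InsufficientReplicationError):
            transcript_stats(m)


class TestExpressionSizeRegression:
    def test_exact_collinear_fit(self):
        frame = pd.DataFrame(
            {
                "mean_tpm": [10.0, 1.0, 0.1],
                "sd_tpm": [0.0] * 3,
                "cv": [0.0] * 3,
                "n_detected": [3] * 3,
            },
            index=["a", "b", "c"],
        )
        table = table_of([100, 1000, 10000], genes=["a", "b", "c"])
        fit = expression_size_regression(stats_from(frame), table)
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(3.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_means_give_zero_slope(self):
        frame = pd.DataFrame(
            {"mean_tpm": [5.0] * 4, "sd_tpm": [0.0] * 4, "cv": [0.0] * 4, "n_detected": [3] * 4},
            index=list("abcd"),
        )
        table = table_of([100, 500, 2000, 9000], genes=list("abcd"))
        fit = expression_size_regression(stats_from(frame), table)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_genes_are_excluded_and_counted(self):
        frame = pd.DataFrame(
            {"mean_tpm": [1.0, 0.0, 2.0, 4.0], "sd_tpm": 0.0, "cv": 0.0, "n_detected": 3},
            index=list("abcd"),
        )
        table = table_of([100, 500, 2000, 9000], genes=list("abcd"))
        fit = expression_size_regression(stats_from(frame), table)
        assert fit.n_points == 3
        assert fit.n_excluded == 1

    def test_too_few_points_errors(self):
        frame = pd.DataFrame(
            {"mean_tpm": [1.0, 2.0], "sd_tpm": 0.0, "cv": 0.0, "n_detected": 3},
            index=list("ab"),
        )
        with pytest.raises(InsufficientDataError):
            expression_size_regression(stats_from(frame), table_of([100, 200], genes=list("ab")))

    def test_recovers_injected_bias_without_dropout(self):
        """beta = -0.6, no dropout: fitted slope within 3 SE of truth."""
        cfg = SimulationConfig(bias_beta=-0.6, dropout_mid_bp=1.0, seed=7)
        cohort = simulate_cohort(cfg)
        stats = transcript_stats(cohort.matrix, floor=cfg.detection_floor)
        fit = expression_size_regression(stats, cohort.table)
        assert abs(fit.slope - (-0.6)) < 3 * fit.slope_se + 3 * 0.01

    def test_intercept_shifts_with_constant_log_offset(self):
        """Scaling all means by 10 adds 1 to the intercept, slope unchanged."""
        frame = pd.DataFrame(
            {"mean_tpm": [2.0, 8.0, 5.0, 1.0], "sd_tpm": 0.0, "cv": 0.0, "n_detected": 3},
            index=list("abcd"),
        )
        table = table_of([100, 500, 2000, 9000], genes=list("abcd"))
        base = expression_size_regression(stats_from(frame), table)
        shifted_frame = frame.assign(mean_tpm=frame["mean_tpm"] * 10.0)
        shifted = expression_size_regression(stats_from(shifted_frame), table)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-9)
        assert shifted.intercept == pytest.approx(base.intercept + 1.0, rel=1e-9)


class TestCvSizeRegression:
    def test_constant_cv(self):
        frame = pd.DataFrame(
            {"mean_tpm": [1.0] * 4, "sd_tpm": 0.31, "cv": [0.31] * 4, "n_detected": 3},
            index=list("abcd"),
        )
        table = table_of([100, 500, 2000, 9000], genes=list("abcd"))
        fit = cv_size_regression(stats_from(frame), table)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.mean_cv == pytest.approx(0.31)

    def test_power_law_cv_recovers_exponent(self):
        lengths = np.array([100, 500, 2000, 9000], float)
        frame = pd.DataFrame(
            {
                "mean_tpm": 1.0,
                "sd_tpm": 0.0,
                "cv": lengths**0.2,
                "n_detected": 3,
            },
            index=list("abcd"),
        )
        fit = cv_size_regression(stats_from(frame), table_of(lengths, genes=list("abcd")))
        assert fit.slope == pytest.approx(0.2, rel=1e-9)

    def test_noise_trend_gives_positive_slope(self):
        cfg = SimulationConfig(
            n_genes=5000, bias_beta=0.0, dropout_mid_bp=1.0, noise_gamma=0.1, seed=3
        )
        cohort = simulate_cohort(cfg)
        stats = transcript_stats(cohort.matrix, floor=cfg.detection_floor)
        fit = cv_size_regression(stats, cohort.table)
        assert fit.slope > 0

    def test_flat_noise_slope_near_zero(self):
        cfg = SimulationConfig(
            n_genes=5000, bias_beta=0.0, dropout_mid_bp=1.0, noise_gamma=0.0, seed=3
        )
        cohort = simulate_cohort(cfg)
        stats = transcript_stats(cohort.matrix, floor=cfg.detection_floor)
        fit = cv_size_regression(stats, cohort.table)
        assert abs(fit.slope) < 3 * fit.slope_se + 0.01


class TestPerSampleRegressions:
    def test_copied_samples_share_fit(self):
        values = np.array([[1.0, 1.0], [4.0, 4.0], [9.0, 9.0]])
        m = make_matrix(values, unit=TPM)
        got = per_sample_regressions(m, table_of([100, 1000, 10000]))
        assert got.slopes[0] == pytest.approx(got.slopes[1])
        assert got.intercepts[0] == pytest.approx(got.intercepts[1])

    def test_tpm_equal_length_gives_unit_slope(self):
        lengths = [150, 1200, 8000]
        m = make_matrix(np.array([[float(l)] * 2 for l in lengths]), unit=TPM)
        got = per_sample_regressions(m, table_of(lengths))
        np.testing.assert_allclose(got.slopes, 1.0, rtol=1e-9)
        np.testing.assert_allclose(got.intercepts, 0.0, atol=1e-9)

    def test_sparse_sample_excluded_and_flagged(self):
        values = np.array(
            [[1.0, 0.0], [4.0, 0.0], [9.0, 0.0], [16.0, 5.0]]
        )
        m = make_matrix(values, unit=TPM)
        got = per_sample_regressions(m, table_of([100, 1000, 10000, 20000]))
        assert got.excluded_samples == ["s1"]
        assert got.sample_ids == ["s0"]

    def test_sample_slope_mean_recovers_common_beta(self):
        """12 samples with common beta = -0.65: mean slope within 3 SD/sqrt(n)."""
        cfg = SimulationConfig(bias_beta=-0.65, dropout_mid_bp=1.0, seed=11)
        cohort = simulate_cohort(cfg)
        got = per_sample_regressions(cohort.matrix, cohort.table, floor=0.1)
        mean_slope = got.slopes.mean()
        margin = 3 * got.slopes.std(ddof=1) / np.sqrt(len(got.slopes)) + 3 * 0.015
        assert abs(mean_slope - (-0.65)) < margin

    def test_global_rescaling_leaves_slopes_unchanged(self):
        """Size-bias scores are normalization-invariant under common scaling."""
        cfg = SimulationConfig(n_genes=500, n_samples=4, seed=5)
        cohort = simulate_cohort(cfg)
        base = per_sample_regressions(cohort.matrix, cohort.table)
        scaled = cohort.matrix.with_values(cohort.matrix.values * 3.7)
        got = per_sample_regressions(scaled, cohort.table)
        np.testing.assert_allclose(got.slopes, base.slopes, rtol=1e-9)


class TestLowExpressionProfile:
    def make_stats(self, means):
        frame = pd.DataFrame(
            {"mean_tpm": means, "sd_tpm": 0.0, "cv": 0.0, "n_detected": 3},
            index=[f"g{i}" for i in range(len(means))],
        )
        return stats_from(frame)

    def test_threshold_rule(self):
        stats = self.make_stats([0.5, 2.0, 0.9])
        table = table_of([300, 400, 500])
        profile = low_expression_profile(stats, table, threshold=1.0)
        assert profile.total == 2

    def test_zero_threshold_empty_profile(self):
        stats = self.make_stats([0.5, 2.0])
        profile = low_expression_profile(stats, table_of([300, 400]), threshold=0.0)
        assert profile.total == 0
        assert profile.bin_counts.sum() == 0

    def test_totals_reconcile_with_detected(self, rng):
        means = rng.exponential(1.0, 200)
        stats = self.make_stats(means)
        table = table_of(rng.integers(180, 40000, 200))
        profile = low_expression_profile(stats, table, threshold=1.0)
        n_detected = int((means > 0).sum())
        n_at_or_above = int((means >= 1.0).sum())
        assert profile.total + n_at_or_above == n_detected

    def test_dropout_depletes_short_transcript_detections(self):
        """Capture dropout removes weakly expressed short transcripts entirely.

        With a weak-expression tail, transcripts far below the dropout
        midpoint fall under the detection floor in every sample, so fewer
        short transcripts are detected at all; moderately suppressed genes
        migrate into the weak (< 1 TPM) band instead, which is why the
        sub-threshold profile alone is not monotone in the dropout setting.
        """
        detected_short = {}
        for mid, key in [(1.0, "off"), (1500.0, "on")]:
            cfg = SimulationConfig(
                n_genes=8000, bias_beta=0.0, dropout_mid_bp=mid,
                dropout_steepness=6.0, abundance_log10_sd=1.0, seed=23,
            )
            cohort = simulate_cohort(cfg)
            stats = transcript_stats(cohort.matrix, floor=cfg.detection_floor)
            short = cohort.table.entries["length_bp"] < 500
            detected_short[key] = int((short & (stats.frame["mean_tpm"] > 0)).sum())
        assert detected_short["on"] < detected_short["off"]


class TestRecoveryFraction:
    def test_half_detected(self):
        table = table_of(range(200, 210), genes=[f"g{i}" for i in range(10)])
        frac = recovery_fraction([f"g{i}" for i in range(5)], table, 200, 300, "mRNA")
        assert frac == 0.5

    def test_superset_gives_one(self):
        table = table_of([250, 260], genes=["a", "b"])
        assert recovery_fraction(["a", "b", "zzz"], table, 200, 300, "mRNA") == 1.0

    def test_empty_reference_range_errors(self):
        table = table_of([250], genes=["a"])
        with pytest.raises(UndefinedFractionError):
            recovery_fraction(["a"], table, 5000, 6000, "mRNA")


class TestCommonCore:
    def test_three_set_intersection(self):
        core = common_core([{"a", "b", "c"}, {"b", "c", "d"}, {"b", "c"}])
        assert core.intersection == {"b", "c"}
        assert core.region_counts["111"] == 2
        assert core.exclusive_counts == [1, 1, 0]

    def test_self_intersection_is_identity(self):
        s = {"x", "y"}
        core = common_core([s, set(s)])
        assert core.intersection == s

    def test_matches_bruteforce_membership_scan(self, rng):
        sets = [set(rng.integers(0, 2000, 1000).tolist()) for _ in range(3)]
        core = common_core(sets)
        expected = {x for x in sets[0] if x in sets[1] and x in sets[2]}
        assert core.intersection == expected
        total = sum(core.region_counts.values())
        assert total == len(sets[0] | sets[1] | sets[2])

    def test_single_set_errors(self):
        with pytest.raises(ArityError):
            common_core([{"a"}])
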