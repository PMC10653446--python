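"""Cross-cohort inference: one-way ANOVA and the Student-Newman-Keuls test.

The SNK procedure compares ordered group means stepwise: the widest span of
means is tested first against the studentized-range quantile for that span,
and narrower spans are tested only when no enclosing span has already been
retained as homogeneous.  The studentized-range distribution itself is
computed here by numerical integration: the range of k standard-normal means
is studentized by an independent chi-based scale with the ANOVA's
within-group degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import gammaln

from .errors import DomainError, InsufficientDataError, ValidationError


@dataclass
class AnovaResult:
    """Classical one-way fixed-effects decomposition."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: list[float]
    group_sizes: list[int]
    mse: float  # within-group mean square

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_value,
            "group_means": self.group_means,
            "group_sizes": self.group_sizes,
            "mse": self.mse,
        }


@dataclass
class SnkComparison:
    """One ordered-pair comparison in the SNK procedure."""

    pair: tuple[str, str]  # (lower-mean label, higher-mean label)
    span: int  # number of ordered means stretched over
    q: float
    q_critical: float
    reject: bool
    tested: bool  # False when protected by an enclosing homogeneous span

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "span": self.span,
            "q": self.q,
            "q_critical": self.q_critical,
            "reject": self.reject,
            "tested": self.tested,
        }


@dataclass
class SnkResult:
    """Stepwise SNK outcome: ordered labels, comparisons, homogeneous subsets."""

    ordered_labels: list[str]
    ordered_means: list[float]
    comparisons: list[SnkComparison]
    homogeneous_subsets: list[list[str]]
    alpha: float

    def to_dict(self) -> dict:
        return {
            "ordered_labels": self.ordered_labels,
            "ordered_means": self.ordered_means,
            "comparisons": [c.to_dict() for c in self.comparisons],
            "homogeneous_subsets": self.homogeneous_subsets,
            "alpha": self.alpha,
        }


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise InsufficientDataError(f"need >= 2 groups, got {len(groups)}")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, arr in enumerate(arrays):
        if arr.size < 2:
            raise InsufficientDataError(f"group {i} has {arr.size} observation(s); need >= 2")
        if not np.isfinite(arr).all():
            raise ValidationError(f"group {i} contains non-finite values")
    return arrays


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA via the between/within sum-of-squares split."""
    arrays = _validate_groups(groups)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0.0:
        f = 0.0 if msb == 0.0 else math.inf
        p = 1.0 if msb == 0.0 else 0.0
    else:
        f = msb / msw
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_stat=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means=[float(a.mean()) for a in arrays],
        group_sizes=[int(a.size) for a in arrays],
        mse=float(msw),
    )


# Fixed Gauss-Legendre rule for the inner normal-range integral; phi(z)
# truncates the integrand to |z| <= 9 (tail mass < 1e-18), and 256 nodes
# resolve the smooth integrand far below the 1e-6 accuracy target.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(256)
_Z_LO, _Z_HI = -9.0, 9.0
_Z = 0.5 * (_Z_HI - _Z_LO) * _GL_NODES + 0.5 * (_Z_HI + _Z_LO)
_WZ = 0.5 * (_Z_HI - _Z_LO) * _GL_WEIGHTS
_PHI_Z = np.exp(-0.5 * _Z * _Z) / math.sqrt(2.0 * math.pi)
_NORM_CDF_Z = sps.norm.cdf(_Z)


def _normal_range_cdf(r, k: int):
    """P(range of k iid standard normals <= r), vectorized over r."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    pos = r > 0
    if pos.any():
        bracket = _NORM_CDF_Z[None, :] - sps.norm.cdf(_Z[None, :] - r[pos, None])
        vals = (k * _PHI_Z[None, :] * bracket ** (k - 1)) @ _WZ
        out[pos] = np.minimum(vals, 1.0)
    return out if out.size > 1 else float(out[0])


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """P(Q <= q) for the studentized range of k normal means with df error dof.

    The range of k independent standard normals is divided by an independent
    scale s = chi_df / sqrt(df); the CDF marginalizes the conditional normal-
    range probability over the density of s by adaptive quadrature.  ``df``
    may be ``math.inf``, collapsing to the plain normal-range CDF.
    """
    if k < 2:
        raise DomainError(f"k must be >= 2, got {k}")
    if df <= 0:
        raise DomainError(f"df must be positive, got {df}")
    if q < 0:
        raise DomainError(f"q must be >= 0, got {q}")
    if q == 0.0:
        return 0.0
    if math.isinf(df):
        return _normal_range_cdf(q, k)

    # density of s = chi_df / sqrt(df); outer integral by adaptive quadrature
    log_norm = (df / 2.0) * math.log(df) - gammaln(df / 2.0) - (df / 2.0 - 1.0) * math.log(2.0)

    def integrand(s):
        if s <= 0.0:
            return 0.0
        log_dens = log_norm + (df - 1.0) * math.log(s) - df * s * s / 2.0
        return math.exp(log_dens) * _normal_range_cdf(q * s, k)

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-8, limit=200)
    return float(min(val, 1.0))


@lru_cache(maxsize=4096)
def studentized_range_quantile(p: float, k: int, df: float) -> float:
    """Inverse of :func:`studentized_range_cdf` in q, by bisection (tol 1e-8)."""
    if not 0.0 < p < 1.0:
        raise DomainError(f"p must be in (0, 1), got {p}")
    lo, hi = 1e-9, 10.0
    while studentized_range_cdf(hi, k, df) < p:
        hi *= 2.0
        if hi > 1e4:
            raise DomainError("quantile search did not bracket")
    return float(brentq(lambda q: studentized_range_cdf(q, k, df) - p, lo, hi, xtol=1e-8))


def snk_test(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> SnkResult:
    """Student-Newman-Keuls stepwise range test on group means.

    For a pair spanning r ordered means, q = (mean_hi - mean_lo) /
    sqrt(MSW / n_h) with n_h the harmonic mean of the two group sizes
    (Tukey-Kramer-style adaptation for unbalanced designs), compared with the
    studentized-range quantile at (1 - alpha, r, df_within).  A span is tested
    only if no enclosing span was already retained as homogeneous; protected
    pairs are recorded with ``tested=False`` and never declared different.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    arrays = _validate_groups(groups)
    k = len(arrays)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    elif len(labels) != k:
        raise ValidationError("labels length must match number of groups")

    anova = oneway_anova(arrays)
    order = np.argsort([a.mean() for a in arrays], kind="stable")
    means = [float(arrays[i].mean()) for i in order]
    sizes = [int(arrays[i].size) for i in order]
    ordered_labels = [str(labels[i]) for i in order]
    df_w = anova.df_within

    comparisons: list[SnkComparison] = []
    homogeneous_spans: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            protected = any(a <= i and j <= b for a, b in homogeneous_spans)
            n_h = 2.0 / (1.0 / sizes[i] + 1.0 / sizes[j])
            diff = means[j] - means[i]
            if anova.mse > 0:
                q = diff / math.sqrt(anova.mse / n_h)
            else:
                q = 0.0 if diff == 0.0 else math.inf
            q_crit = studentized_range_quantile(1.0 - alpha, span, float(df_w))
            if protected:
                reject = False
            else:
                reject = q > q_crit
                if not reject:
                    homogeneous_spans.append((i, j))
            comparisons.append(
                SnkComparison(
                    pair=(ordered_labels[i], ordered_labels[j]),
                    span=span,
                    q=float(q),
                    q_critical=float(q_crit),
                    reject=bool(reject),
                    tested=not protected,
                )
            )

    # maximal homogeneous spans plus singletons for groups in none of them
    subsets: list[list[str]] = []
    maximal = [
        (a, b)
        for a, b in homogeneous_spans
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in homogeneous_spans)
    ]
    maximal.sort()
    covered = set()
    for a, b in maximal:
        subsets.append(ordered_labels[a : b + 1])
        covered.update(range(a, b + 1))
    for i in range(k):
        if i not in covered:
            subsets.append([ordered_labels[i]])
    subsets.sort(key=lambda s: ordered_labels.index(s[0]))

    return SnkResult(
        ordered_labels=ordered_labels,
        ordered_means=means,
        comparisons=comparisons,
        homogeneous_subsets=subsets,
        alpha=alpha,
    )
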