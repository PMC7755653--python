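"""Confusion metrics, McNemar tests, relative predictive values, and Holm.

Paired comparisons of two binary tests on the same subjects: sensitivity and
specificity are compared with the McNemar test on the discordant pairs (exact
binomial for few discordances, continuity-corrected chi-square otherwise), and
positive/negative predictive values with a Wald test on the log relative
predictive value (rPPV = PPV_A / PPV_B), whose variance follows from the delta
method applied to the paired 2 (test A) x 2 (test B) x 2 (disease) multinomial
— the approach of Moskowitz & Pepe for paired screening studies.  Families of
p-values are adjusted with Holm's step-down method.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInputError, DomainError

__all__ = [
    "ConfusionCounts",
    "Metric",
    "PerformanceMetrics",
    "PairedTable",
    "RelativePvResult",
    "round_half_up_pct",
    "metrics_from_counts",
    "mcnemar_exact",
    "mcnemar_chi2",
    "mcnemar_test",
    "relative_pv_test",
    "holm",
]

#: discordant-pair count at or below which the exact McNemar variant is used
MCNEMAR_EXACT_LIMIT = 25


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_calls(cls, calls: Sequence[bool], disease: Sequence[bool]) -> "ConfusionCounts":
        calls = np.asarray(calls, dtype=bool)
        disease = np.asarray(disease, dtype=bool)
        return cls(
            tp=int((calls & disease).sum()),
            fp=int((calls & ~disease).sum()),
            tn=int((~calls & ~disease).sum()),
            fn=int((~calls & disease).sum()),
        )


def round_half_up_pct(numerator: int, denominator: int) -> int:
    """Integer percent with exact half-up rounding (106/108 -> 98)."""
    if denominator == 0:
        raise DegenerateInputError("cannot render a percentage with zero denominator")
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Metric:
    """One proportion with its counts, Clopper-Pearson 95% CI, and rendering."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = proportion_confint(self.numerator, self.denominator, alpha=0.05, method="beta")
        return float(lo), float(hi)

    @property
    def pct(self) -> int:
        return round_half_up_pct(self.numerator, self.denominator)

    def render(self) -> str:
        return f"{self.pct}% ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sens/spec/PPV/NPV; a metric is None when its denominator is zero."""

    sensitivity: Metric | None
    specificity: Metric | None
    ppv: Metric | None
    npv: Metric | None


def metrics_from_counts(c: ConfusionCounts) -> PerformanceMetrics:
    def _metric(num: int, den: int) -> Metric | None:
        return Metric(num, den) if den > 0 else None

    return PerformanceMetrics(
        sensitivity=_metric(c.tp, c.tp + c.fn),
        specificity=_metric(c.tn, c.tn + c.fp),
        ppv=_metric(c.tp, c.tp + c.fp),
        npv=_metric(c.tn, c.tn + c.fn),
    )


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided binomial McNemar p-value on discordant counts (b, c)."""
    if b < 0 or c < 0:
        raise DomainError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
    return min(1.0, float(p))


def mcnemar_chi2(b: int, c: int) -> float:
    """Continuity-corrected chi-square McNemar p-value."""
    if b < 0 or c < 0:
        raise DomainError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    stat = (abs(b - c) - 1) ** 2 / n
    return float(stats.chi2.sf(stat, df=1))


def mcnemar_test(b: int, c: int) -> float:
    """Exact variant for b + c <= 25, chi-square with continuity correction above."""
    if b + c <= MCNEMAR_EXACT_LIMIT:
        return mcnemar_exact(b, c)
    return mcnemar_chi2(b, c)


# ---------------------------------------------------------------------------
# Paired tables and relative predictive values
# ---------------------------------------------------------------------------


class PairedTable:
    """Counts n[a, b, d] over test-A call, test-B call, and disease (1 = +)."""

    def __init__(self, counts):
        counts = np.asarray(counts, dtype=int)
        if counts.shape != (2, 2, 2):
            raise ValueError("paired table must have shape (2, 2, 2)")
        if (counts < 0).any():
            raise DomainError("paired-table cells must be non-negative")
        self.counts = counts

    @classmethod
    def from_vectors(cls, a_calls, b_calls, disease) -> "PairedTable":
        a = np.asarray(a_calls, dtype=bool)
        b = np.asarray(b_calls, dtype=bool)
        d = np.asarray(disease, dtype=bool)
        if not (a.shape == b.shape == d.shape):
            raise ValueError("call and disease vectors must align")
        counts = np.zeros((2, 2, 2), dtype=int)
        for ai in (0, 1):
            for bi in (0, 1):
                for di in (0, 1):
                    counts[ai, bi, di] = int(((a == ai) & (b == bi) & (d == di)).sum())
        return cls(counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def margin(self, test: str) -> ConfusionCounts:
        n = self.counts
        if test == "a":
            pos, neg = n[1], n[0]
        elif test == "b":
            pos, neg = n[:, 1], n[:, 0]
        else:
            raise ValueError("test must be 'a' or 'b'")
        return ConfusionCounts(
            tp=int(pos[..., 1].sum()),
            fp=int(pos[..., 0].sum()),
            tn=int(neg[..., 0].sum()),
            fn=int(neg[..., 1].sum()),
        )

    def swapped(self) -> "PairedTable":
        return PairedTable(self.counts.transpose(1, 0, 2))


@dataclass(frozen=True)
class RelativePvResult:
    rppv: float
    rnpv: float
    p_ppv: float
    p_npv: float
    se_log_rppv: float
    se_log_rnpv: float


def _log_ratio_wald(n: np.ndarray, s1, s2, s3, s4, what: str) -> tuple[float, float, float]:
    """Wald test of log(X1/X2) - log(X3/X4) where each X is a cell-set total.

    Cell sets may overlap; the delta-method variance for the multinomial
    reduces to sum_k n_k * a_k^2 with a_k the per-cell gradient (the linear
    term vanishes because the gradient is centered).
    """
    sums = []
    for sel in (s1, s2, s3, s4):
        sums.append(float(n[sel].sum()))
    x1, x2, x3, x4 = sums
    names = ("numerator of test A", "positive calls of test A", "numerator of test B", "positive calls of test B")
    for x, label in zip(sums, names):
        if x == 0:
            raise DegenerateInputError(f"{what} is undefined: zero {label}")
    g = np.log(x1) - np.log(x2) - np.log(x3) + np.log(x4)
    grad = np.zeros((2, 2, 2))
    grad[s1] += 1.0 / x1
    grad[s2] -= 1.0 / x2
    grad[s3] -= 1.0 / x3
    grad[s4] += 1.0 / x4
    var = float((n * grad**2).sum())
    se = np.sqrt(var)
    if se == 0.0:
        # both margins identical cell-by-cell: the ratio is exactly 1
        return float(np.exp(g)), 0.0, 1.0
    z = g / se
    return float(np.exp(g)), float(se), float(2.0 * stats.norm.sf(abs(z)))


def relative_pv_test(table: PairedTable) -> RelativePvResult:
    """Paired Wald tests on log relative PPV and log relative NPV (A vs B)."""
    n = table.counts
    ax = np.index_exp  # readability: slices over (a, b, d)
    rppv, se_p, p_ppv = _log_ratio_wald(
        n,
        ax[1, :, 1],  # A+ and diseased
        ax[1, :, :],  # A+
        ax[:, 1, 1],  # B+ and diseased
        ax[:, 1, :],  # B+
        "relative PPV",
    )
    rnpv, se_n, p_npv = _log_ratio_wald(
        n,
        ax[0, :, 0],  # A- and healthy
        ax[0, :, :],  # A-
        ax[:, 0, 0],  # B- and healthy
        ax[:, 0, :],  # B-
        "relative NPV",
    )
    return RelativePvResult(
        rppv=rppv, rnpv=rnpv, p_ppv=p_ppv, p_npv=p_npv, se_log_rppv=se_p, se_log_rnpv=se_n
    )


# ---------------------------------------------------------------------------
# Holm step-down adjustment
# ---------------------------------------------------------------------------


def holm(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(adjusted), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
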