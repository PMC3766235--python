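"""Method-agreement statistics and nonparametric test battery.

Bias is the median signed difference (estimate minus reference),
precision the IQR of differences and the Bland-Altman 95% limits of
agreement, accuracy the fraction of estimates within 15/30/50% of the
reference (strict inequality, reference in the denominator).

Rank tests use exact enumeration at small sample sizes (signed-rank and
rank-sum: total n <= 12; McNemar: discordant total <= 25) and normal /
chi-square approximations with tie corrections otherwise. Degenerate
inputs (all-zero differences, no discordant pairs, no variation) yield
flagged degenerate results with p = 1 rather than exceptions.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .estimators import stage_groups

__all__ = [
    "AgreementSummary",
    "BlandAltmanResult",
    "TestResult",
    "differences",
    "accuracy_within",
    "agreement_summary",
    "bland_altman",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "kruskal_wallis",
    "kruskal_wallis_posthoc",
    "mcnemar",
    "chi_square_2xk",
    "bonferroni_adjust",
    "bonferroni_adjust_rounded",
    "stage_concordance",
]

EXACT_RANK_N = 12  # enumeration limit for signed-rank / rank-sum tests
EXACT_MCNEMAR_N = 25  # enumeration limit for discordant totals


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class AgreementSummary:
    """Bias / precision / accuracy of one estimator against the reference."""

    n: int
    median_diff: float
    diff_iqr: Tuple[float, float]
    median_abs_diff: float
    abs_diff_iqr: Tuple[float, float]
    p15_count: int
    p30_count: int
    p50_count: int
    p15_pct: float
    p30_pct: float
    p50_pct: float

    def __post_init__(self):
        if not (0 <= self.p15_count <= self.p30_count <= self.p50_count <= self.n):
            raise ValueError("accuracy counts must nest: p15 <= p30 <= p50 <= n")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["diff_iqr"] = list(self.diff_iqr)
        d["abs_diff_iqr"] = list(self.abs_diff_iqr)
        return d


@dataclasses.dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_width: float
    means: np.ndarray = dataclasses.field(repr=False, compare=False)
    diffs: np.ndarray = dataclasses.field(repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "loa_width": self.loa_width,
        }


def _paired(egfr, sgfr) -> Tuple[np.ndarray, np.ndarray]:
    e = np.asarray(egfr, dtype=float).ravel()
    s = np.asarray(sgfr, dtype=float).ravel()
    if len(e) != len(s):
        raise ValueError(f"length mismatch: {len(e)} vs {len(s)}")
    if len(e) == 0:
        raise ValueError("input vectors must be nonempty")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("reference values must be positive and finite")
    return e, s


def differences(egfr, sgfr) -> np.ndarray:
    """Per-pair signed difference, estimate minus reference."""
    e, s = _paired(egfr, sgfr)
    return e - s


def accuracy_within(egfr, sgfr, tol: float) -> Tuple[int, float]:
    """Count and percent of estimates differing from the reference by
    strictly less than ``tol`` (relative, reference in the denominator)."""
    if not (0.0 < tol < 1.0):
        raise ValueError(f"tol must be in (0, 1), got {tol}")
    e, s = _paired(egfr, sgfr)
    count = int(np.sum(np.abs(e - s) / s < tol))
    return count, 100.0 * count / len(e)


def _quartiles(values: np.ndarray) -> Tuple[float, float]:
    # linear interpolation at positions 1 + (n-1)p, the numpy default
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q1), float(q3)


def agreement_summary(egfr, sgfr) -> AgreementSummary:
    """Full bias/precision/accuracy summary for one estimator."""
    e, s = _paired(egfr, sgfr)
    d = e - s
    ad = np.abs(d)
    counts = {}
    for tol in (0.15, 0.30, 0.50):
        counts[tol] = int(np.sum(ad / s < tol))
    n = len(d)
    return AgreementSummary(
        n=n,
        median_diff=float(np.median(d)),
        diff_iqr=_quartiles(d),
        median_abs_diff=float(np.median(ad)),
        abs_diff_iqr=_quartiles(ad),
        p15_count=counts[0.15],
        p30_count=counts[0.30],
        p50_count=counts[0.50],
        p15_pct=100.0 * counts[0.15] / n,
        p30_pct=100.0 * counts[0.30] / n,
        p50_pct=100.0 * counts[0.50] / n,
    )


def bland_altman(egfr, sgfr) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD)."""
    e, s = _paired(egfr, sgfr)
    if len(e) < 2:
        raise ValueError("Bland-Altman analysis requires n >= 2")
    d = e - s
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        loa_width=2 * 1.96 * sd_diff,
        means=(e + s) / 2.0,
        diffs=d,
    )


# ---------------------------------------------------------------------------
# rank tests


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    return sps.rankdata(np.abs(d))


def wilcoxon_signed_rank(d) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. Exact p by enumeration of all 2^n sign
    patterns for n <= 12 (valid with ties); normal approximation with tie
    correction otherwise. All-zero input gives a flagged degenerate
    result with p = 1.
    """
    d = np.asarray(d, dtype=float).ravel()
    if len(d) == 0:
        raise ValueError("empty difference vector")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", exact=True, degenerate=True)
    ranks = _signed_ranks(d)
    w_plus = float(np.sum(ranks[d > 0]))
    if n <= EXACT_RANK_N:
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        lo = np.mean(sums <= w_plus + 1e-12)
        hi = np.mean(sums >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(w_plus, p, "wilcoxon_signed_rank", exact=True)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon_signed_rank", exact=False, degenerate=True)
    z = (w_plus - mean) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(w_plus, p, "wilcoxon_signed_rank", exact=False)


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of all group assignments when the pooled size
    is <= 12 and there are no cross-sample ties; otherwise normal
    approximation with tie correction. The statistic reported is U for
    the first sample.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = float(np.sum(ranks[:nx]) - nx * (nx + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if nx + ny <= EXACT_RANK_N and not has_ties:
        stats = []
        idx = range(nx + ny)
        for combo in itertools.combinations(idx, nx):
            r = np.sum(ranks[list(combo)])
            stats.append(r - nx * (nx + 1) / 2.0)
        stats = np.asarray(stats)
        lo = np.mean(stats <= u_x + 1e-12)
        hi = np.mean(stats >= u_x - 1e-12)
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(u_x, p, "mann_whitney_u", exact=True)
    n = nx + ny
    mean = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(u_x, 1.0, "mann_whitney_u", exact=False, degenerate=True)
    z = (u_x - mean) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(u_x, p, "mann_whitney_u", exact=False)


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square reference."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if len(np.unique(pooled)) == 1:
        return TestResult(0.0, 1.0, "kruskal_wallis", exact=False, degenerate=True)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = np.sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts ** 3 - tie_counts)) / (n ** 3 - n)
    h /= correction
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult(float(h), p, "kruskal_wallis", exact=False)


def kruskal_wallis_posthoc(groups: Sequence, alpha: float = 0.05) -> dict:
    """Pairwise Mann-Whitney post hoc at a Bonferroni-adjusted level.

    Returns the omnibus result, the adjusted per-comparison level, and a
    dict mapping group-index pairs to rank-sum results.
    """
    omnibus = kruskal_wallis(groups)
    pairs = list(itertools.combinations(range(len(groups)), 2))
    level = bonferroni_adjust(alpha, len(pairs))
    pairwise = {pair: mann_whitney_u(groups[pair[0]], groups[pair[1]]) for pair in pairs}
    return {"omnibus": omnibus, "adjusted_level": level, "pairwise": pairwise}


def mcnemar(b: int, c: int) -> TestResult:
    """McNemar test on the two discordant counts of a paired 2x2 table.

    Exact two-sided binomial p when b + c <= 25; continuity-corrected
    chi-square otherwise. b = c = 0 gives a flagged degenerate result.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    m = b + c
    if m == 0:
        return TestResult(0.0, 1.0, "mcnemar", exact=True, degenerate=True)
    if m <= EXACT_MCNEMAR_N:
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), m, 0.5)))
        return TestResult(float(min(b, c)), p, "mcnemar", exact=True)
    stat = (abs(b - c) - 1.0) ** 2 / m
    p = float(sps.chi2.sf(stat, 1))
    return TestResult(float(stat), p, "mcnemar", exact=False)


def chi_square_2xk(table) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0) or np.any(obs != np.floor(obs)):
        raise ValueError("table entries must be nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all table margins must be positive")
    expected = np.outer(row, col) / obs.sum()
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, p, "chi_square", exact=False)


def bonferroni_adjust(alpha: float, k: int) -> float:
    """Per-comparison level alpha / k."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return alpha / k


def bonferroni_adjust_rounded(alpha: float, k: int, decimals: int = 4) -> float:
    """Reporting helper: adjusted level rounded for display (0.05/3 -> 0.0167)."""
    return round(bonferroni_adjust(alpha, k), decimals)


def stage_concordance(egfr, sgfr):
    """Per-patient CKD stage difference and its signed-rank test.

    Both vectors are mapped through the stage grouping rule encoded
    ordinally (I/II = 1, III = 2, IV/V = 3). Returns the per-patient
    stage difference (estimated minus reference), the Wilcoxon
    signed-rank result on those differences, and the 3x3
    cross-classification table (rows = reference, columns = estimated).
    """
    e, s = _paired(egfr, sgfr)
    if np.any(e <= 0):
        raise ValueError("estimates must be positive for stage classification")
    est = stage_groups(e)
    ref = stage_groups(s)
    diff = est - ref
    test = wilcoxon_signed_rank(diff)
    table = np.zeros((3, 3), dtype=int)
    for r, c in zip(ref, est):
        table[r - 1, c - 1] += 1
    return diff, test, table
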