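"""Statistical comparison battery for paired benchmark results.

Wilcoxon signed-rank (exact by enumeration for small samples, normal
approximation with continuity correction beyond), Holm-Bonferroni step-down
multiple-comparison control, BCa bootstrap confidence intervals, paired
Cohen's d, Levene's variance-equality test, and rank/linear correlation for
dimensionality-sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "PairedResults",
    "HolmResult",
    "BootstrapCI",
    "wilcoxon_signed_rank",
    "holm_bonferroni",
    "bca_bootstrap_ci",
    "cohens_d",
    "levene_test",
    "rank_and_linear_correlation",
]

EXACT_ENUMERATION_LIMIT = 25  # nonzero pairs at or below this use the exact null


@dataclass
class PairedResults:
    """Two equal-length vectors of per-run results (e.g. accuracies)."""

    method_a: np.ndarray
    method_b: np.ndarray

    def __post_init__(self):
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if self.method_a.shape != self.method_b.shape or self.method_a.ndim != 1:
            raise ValueError("paired results must be equal-length vectors")
        if self.method_a.size < 2:
            raise ValueError("need at least 2 paired observations")

    @property
    def differences(self) -> np.ndarray:
        return self.method_a - self.method_b


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic under random signs.

    Equivalent to enumerating all 2^n sign assignments.  Midranks from ties
    are handled by doubling (all doubled ranks are integers), and the
    distribution of W+ is built by dynamic programming over the polynomial
    prod_i (1 + x^(2 r_i)).
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(paired: PairedResults, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention).  With at most
    25 nonzero pairs the p-value is exact (full sign-assignment null,
    midranks for ties); above that a normal approximation with continuity
    correction and tie correction is used.  Returns (W+, two-sided p).
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    d = paired.differences
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_LIMIT:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction on the variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w_plus, min(p, 1.0)


@dataclass
class HolmResult:
    """Step-down multiple-comparison outcome in sorted-p order."""

    sorted_p: np.ndarray
    order: np.ndarray  # original index of each sorted entry
    thresholds: np.ndarray  # alpha / (k - i + 1) at rank i (1-based)
    rejected: np.ndarray  # boolean, aligned with sorted_p
    stop_rank: int  # 1-based rank of the first failure; k+1 if none
    alpha: float


def holm_bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Holm-Bonferroni sequential rejection.

    Sort p-values ascending; rank i (1-based) is compared against
    alpha/(k-i+1) and rejected only while every earlier rank was also
    rejected — the first failure stops all later rejections.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ranks = np.arange(1, k + 1)
    thresholds = alpha / (k - ranks + 1)
    rejected = np.zeros(k, dtype=bool)
    stop_rank = k + 1
    for i in range(k):
        if sorted_p[i] <= thresholds[i]:
            rejected[i] = True
        else:
            stop_rank = i + 1
            break
    return HolmResult(sorted_p, order, thresholds, rejected, stop_rank, alpha)


@dataclass
class BootstrapCI:
    """BCa bootstrap interval with its bias-correction and acceleration."""

    point_estimate: float
    lower: float
    upper: float
    level: float
    resamples: int
    z0: float
    acceleration: float
    seed: int


def bca_bootstrap_ci(
    data: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    resamples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    force_percentile: bool = False,
) -> BootstrapCI:
    """Bias-corrected and accelerated bootstrap confidence interval.

    z0 comes from the fraction of bootstrap replicates below the point
    estimate; the acceleration a from the jackknife third-moment (skewness)
    formula.  ``force_percentile`` pins z0 = a = 0, reducing the interval to
    plain percentile endpoints (used for validation).
    """
    x = np.asarray(data, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    theta_hat = float(statistic(x))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(resamples, x.size))
    boot = np.array([statistic(x[row]) for row in idx])

    if np.allclose(boot, boot[0]) and np.isclose(boot[0], theta_hat):
        return BootstrapCI(theta_hat, theta_hat, theta_hat, level, resamples, 0.0, 0.0, seed)

    if force_percentile:
        z0 = 0.0
        a = 0.0
    else:
        frac_below = np.mean(boot < theta_hat)
        frac_below = min(max(frac_below, 1.0 / (2 * resamples)), 1 - 1.0 / (2 * resamples))
        z0 = float(sps.norm.ppf(frac_below))
        # jackknife acceleration
        jack = np.array([statistic(np.delete(x, i)) for i in range(x.size)])
        centered = jack.mean() - jack
        denom = (centered**2).sum() ** 1.5
        a = float((centered**3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    alpha_tail = (1.0 - level) / 2.0
    z_lo = sps.norm.ppf(alpha_tail)
    z_hi = sps.norm.ppf(1.0 - alpha_tail)
    adj = []
    for z in (z_lo, z_hi):
        num = z0 + z
        q = sps.norm.cdf(z0 + num / (1.0 - a * num))
        adj.append(min(max(q, 0.0), 1.0))
    lower, upper = np.quantile(boot, adj)
    return BootstrapCI(theta_hat, float(lower), float(upper), level, resamples, z0, a, seed)


def cohens_d(paired: PairedResults) -> float:
    """Paired Cohen's d: mean difference over the differences' SD (ddof=1)."""
    d = paired.differences
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0
        raise ValueError("zero spread with nonzero mean difference: d is unbounded")
    return mean / sd


def levene_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical Levene test (mean centering) for equality of variances."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    w, p = sps.levene(*arrays, center="mean")
    return float(w), float(p)


def rank_and_linear_correlation(x, y) -> tuple[float, float, float, float]:
    """Spearman rho (Pearson on midranks) and Pearson r, with t-approximation
    p-values.  Returns (rho, rho_p, r, r_p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, rho_p = sps.spearmanr(x, y)
    r, r_p = sps.pearsonr(x, y)
    return float(rho), float(rho_p), float(r), float(r_p)
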