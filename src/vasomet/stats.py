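"""Nonparametric inference: Spearman correlation, Mann-Whitney U, Wilcoxon.

These are the three rank-based procedures the cohort layer uses, with the
small-sample conventions made explicit: midranks for ties, zero differences
dropped before signed-ranking, exact null distributions in the desk-scale
regime (total n <= 12 without ties by default) and the usual large-sample
approximations otherwise.  Each function returns a :class:`TestResult`
recording the statistic, the two-sided p-value, the sample sizes and which
branch (exact or asymptotic) produced the p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

__all__ = ["TestResult", "spearman_rho", "mann_whitney_u", "wilcoxon_signed_rank"]

#: Largest total sample size at which the exact branches are used by default.
EXACT_MAX_N = 12

Method = Literal["auto", "exact", "asymptotic"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``statistic`` is rho for Spearman, U (first sample) for Mann-Whitney and
    W (smaller signed-rank sum convention of scipy) for Wilcoxon.  ``n2`` is
    None for one-sample/paired procedures.  ``approach`` records whether the
    p-value came from an exact null distribution or an approximation.
    """

    method: str
    statistic: float
    p_value: float
    n1: int
    n2: Optional[int] = None
    approach: str = "asymptotic"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.statistic)


def _as_1d(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def spearman_rho(x: Sequence[float], y: Sequence[float], method: Method = "auto") -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive midranks.  The p-value uses the t-distribution
    approximation; ``method="exact"`` (available for n <= 9) enumerates all
    n! rank permutations instead.  Constant input yields an undefined
    correlation, returned as a NaN-statistic result rather than an error.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("spearman", float("nan"), float("nan"), x.size, None, "undefined")
    if method == "exact":  # opt-in: "auto" always uses the t-approximation
        return _spearman_exact(x, y)
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), x.size, None, "asymptotic")


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> TestResult:
    n = x.size
    if n > 9:
        raise ValidationError("exact Spearman permutation is limited to n <= 9")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def rho_of(perm_ry: np.ndarray) -> float:
        return float(np.corrcoef(rx, perm_ry)[0, 1])

    observed = rho_of(ry)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(rho_of(ry[list(perm)])) >= abs(observed) - 1e-12:
            count += 1
    return TestResult("spearman", observed, count / total, n, None, "exact")


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], method: Method = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    The reported U counts pairs won by the first sample, with ties worth
    one half.  ``method="auto"`` uses the exact null distribution when
    n1 + n2 <= 12 and the pooled data are tie-free, and the normal
    approximation with continuity and tie correction otherwise.
    """
    a, b = _as_1d(a, "a"), _as_1d(b, "b")
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if method == "auto":
        exact = a.size + b.size <= EXACT_MAX_N and not _has_ties(np.concatenate([a, b]))
        method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        "mann-whitney", float(res.statistic), float(res.pvalue), a.size, b.size, method
    )


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], method: Method = "auto"
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped before ranking (the classical convention);
    ``n1`` in the result is the number of informative (nonzero) pairs.
    ``method="auto"`` uses the exact distribution for <= 12 informative,
    tie-free |differences| and the normal approximation otherwise.

    Raises
    ------
    DegenerateDataError
        If every difference is zero.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    if method == "auto":
        method = "exact" if d.size <= EXACT_MAX_N else "asymptotic"
    if method == "asymptotic":
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="approx")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = _wilcoxon_exact(d)
    return TestResult("wilcoxon", stat, p, int(d.size), None, method)


def _wilcoxon_exact(d: np.ndarray) -> tuple[float, float]:
    """Sign-flip enumeration of the signed-rank null; valid with midrank ties.

    Enumerates all 2^n sign patterns of the |difference| midranks and reports
    the smaller rank sum W = min(W+, W-) with p = P(min(W+, W-) <= W), which
    coincides with the doubled-tail convention on the symmetric null.
    """
    n = d.size
    if n > 16:
        raise ValidationError("exact Wilcoxon enumeration is limited to 16 informative pairs")
    ranks = sps.rankdata(np.abs(d))
    total = ranks.sum()
    w_plus = ranks[d > 0].sum()
    observed = min(w_plus, total - w_plus)
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w = signs @ ranks
    w_min = np.minimum(w, total - w)
    p = float((w_min <= observed + 1e-12).mean())
    return float(observed), p
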