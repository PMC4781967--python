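"""Statistical kernels used by every pipeline stage.

Five primitives cover the whole analysis: Spearman and Pearson correlation
(age screening and microbiome linkage), the pooled two-sample Student t
(disease overlap), the two-tailed Fisher exact test (enrichment contrasts)
and the hypergeometric upper tail (compendium overlap).

Conventions, fixed here once and relied on everywhere:

* Spearman uses mid-rank (average-rank) tie handling.  The two-sided p-value
  is computed by full permutation enumeration for n <= 9 and by the classical
  t-distribution approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` for
  n >= 10 (the study cohort has n = 22, well inside the approximation
  regime).
* The Student t is the classical pooled-variance (equal-variance) two-sample
  test, two-sided.  Zero pooled variance is resolved by convention: equal
  means give p = 1.0, unequal means give p = 0.0.
* Fisher's exact two-tailed p follows the method of small p-values: the sum
  of hypergeometric probabilities of all tables with the observed margins
  that are no more probable than the observed table.  The computation is
  exact integer arithmetic (binomial-coefficient weights), so no floating
  tolerance enters the tail-membership comparison.
* Missing values (NaN) are removed listwise before any correlation.

No multiple-testing correction is applied by default anywhere in the
pipeline; the screening thresholds are deliberately uncorrected trend
cutoffs.  :func:`bh_adjust` is available for callers that want
Benjamini-Hochberg q-values on top.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateInputError

__all__ = [
    "CorrelationResult",
    "TwoByTwo",
    "spearman",
    "pearson",
    "student_t_test",
    "fisher_exact_two_tailed",
    "hypergeom_upper_tail",
    "bh_adjust",
]

# Exact permutation enumeration is used at or below this sample size.
EXACT_SPEARMAN_N = 9


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation estimate with its two-sided p-value.

    Attributes
    ----------
    estimate : float
        Spearman rho or Pearson r, in [-1, 1].
    p_value : float
        Two-sided p-value in [0, 1].
    n_used : int
        Number of (x, y) pairs remaining after listwise missing removal.
    """

    estimate: float
    p_value: float
    n_used: int


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table [[a, b], [c, d]] of non-negative counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError(f"counts must be non-negative integers, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    return x, y


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _t_approx_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _sps.t.sf(abs(t), df=n - 2))


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n), as an (n!, n) index array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all n! orderings of the y ranks."""
    n = xr.size
    perms = _perm_matrix(n)
    yp = yr[perms]  # (n!, n)
    xc = xr - xr.mean()
    yc = yp - yp.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * np.einsum("ij,ij->i", yc, yc))
    rhos = (yc @ xc) / denom
    hits = np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12)
    return hits / len(perms)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n <= 9 the p-value is exact (full
    permutation enumeration over the observed rank multiset); for n >= 10 it
    uses the t-distribution approximation.

    Raises
    ------
    DegenerateInputError
        If either vector is constant after missing removal.
    ValueError
        If fewer than 3 complete pairs remain.
    """
    x, y = _clean_pairs(x, y)
    n = x.size
    xr = _sps.rankdata(x)
    yr = _sps.rankdata(y)
    rho = _pearson_r(xr, yr)
    if n <= EXACT_SPEARMAN_N:
        p = _exact_spearman_p(xr, yr, rho)
    else:
        p = _t_approx_p(rho, n)
    return CorrelationResult(estimate=rho, p_value=p, n_used=n)


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x, y = _clean_pairs(x, y)
    r = _pearson_r(x, y)
    return CorrelationResult(estimate=r, p_value=_t_approx_p(r, x.size), n_used=x.size)


def student_t_test(group1, group2) -> float:
    """Two-sided pooled-variance (classical Student) two-sample t-test.

    Returns only the p-value, which is what every caller consumes.

    Zero pooled variance is resolved by convention rather than error:
    identical means give p = 1.0, different means give p = 0.0.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1 = g1[~np.isnan(g1)]
    g2 = g2[~np.isnan(g2)]
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 values, have {n1} and {n2}")
    m1, m2 = g1.mean(), g2.mean()
    ss = float(((g1 - m1) ** 2).sum() + ((g2 - m2) ** 2).sum())
    df = n1 + n2 - 2
    if ss == 0.0:
        return 1.0 if m1 == m2 else 0.0
    sp2 = ss / df
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * _sps.t.sf(abs(t), df=df))


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 table (method of small p-values).

    ``table`` is a :class:`TwoByTwo` or any [[a, b], [c, d]] nest.  The p-value
    is the sum, over all tables sharing the observed margins, of the
    hypergeometric probabilities that do not exceed the observed table's
    probability.  Weights are exact integers (products of binomial
    coefficients) so the <= comparison involves no rounding.

    A table with any zero margin has a single-point support and returns 1.0.
    """
    if not isinstance(table, TwoByTwo):
        (a, b), (c, d) = table
        table = TwoByTwo(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        return 1.0
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    # weight(k) = C(row1, k) * C(row2, col1 - k); P(k) = weight(k) / C(total, col1)
    weights = [math.comb(row1, k) * math.comb(total - row1, col1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    tail = sum(w for w in weights if w <= w_obs)
    return float(tail / math.comb(total, col1))


def hypergeom_upper_tail(overlap: int, size_a: int, size_b: int, universe: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, size_a, size_b).

    The probability that two uniformly random subsets of the given sizes,
    drawn from a universe of ``universe`` items, intersect in at least
    ``overlap`` items.
    """
    if not (0 <= size_a <= universe and 0 <= size_b <= universe):
        raise ValueError("set sizes must lie within the universe")
    if overlap < 0 or overlap > min(size_a, size_b):
        raise ValueError(
            f"overlap {overlap} impossible for set sizes {size_a}, {size_b}"
        )
    if overlap == 0:
        return 1.0
    return float(_sps.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out
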