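"""Hypergeometric gene-list overlap statistics and universe calibration.

The overlap of two gene lists of sizes a and b drawn from a universe of N
genes is tested one-sided (enrichment): with K = |A intersect B|,

    p = sum_{i = k}^{min(a, b)} C(a, i) C(N - a, b - i) / C(N, b),

equivalent to the upper tail of Fisher's exact test on the 2x2 table.  The
sum is evaluated in log space (log-gamma binomials + logsumexp) so it is
exact and stable for universes up to millions of genes and p-values far
below the double underflow of individual terms' products.

Published overlap reports often print a, b, k and p but not N; the
calibration routine inverts the test by bisection on N (p is strictly
decreasing in N in the enrichment regime k > a b / N), recovering the
universe a printed p-value implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "OverlapQuery",
    "OverlapResult",
    "hypergeometric_upper_tail",
    "log10_hypergeometric_upper_tail",
    "fisher_overlap",
    "calibrate_universe",
    "membership_table",
]


@dataclass
class OverlapQuery:
    """Two gene sets and the universe they were drawn from."""

    list_a: set
    list_b: set
    universe_n: int
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        self.list_a = set(self.list_a)
        self.list_b = set(self.list_b)
        if len(self.list_a) > self.universe_n or len(self.list_b) > self.universe_n:
            raise ValueError("list larger than the stated universe")


@dataclass(frozen=True)
class OverlapResult:
    label_a: str
    label_b: str
    a: int
    b: int
    k: int
    universe_n: int
    p_upper: float
    odds_ratio: float
    jaccard: float


def _check_table(k: int, a: int, b: int, N: int) -> None:
    if not (0 <= k <= min(a, b)):
        raise ValueError(f"need 0 <= k <= min(a, b); got k={k}, a={a}, b={b}")
    if a > N or b > N:
        raise ValueError(f"list sizes must not exceed the universe (a={a}, b={b}, N={N})")
    if a + b - k > N:
        raise ValueError(
            f"infeasible 2x2 table: a + b - k = {a + b - k} exceeds N = {N}"
        )


def _log_upper_tail(k: int, a: int, b: int, N: int) -> float:
    i = np.arange(k, min(a, b) + 1)

    def logC(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    terms = logC(a, i) + logC(N - a, b - i) - logC(N, b)
    return float(logsumexp(terms))


def hypergeometric_upper_tail(k: int, a: int, b: int, N: int) -> float:
    """P(overlap >= k) for lists of sizes a, b in a universe of N genes."""
    _check_table(k, a, b, N)
    if k == 0:
        return 1.0
    return min(1.0, math.exp(_log_upper_tail(k, a, b, N)))


def log10_hypergeometric_upper_tail(k: int, a: int, b: int, N: int) -> float:
    """log10 of the upper-tail p (usable far below double underflow)."""
    _check_table(k, a, b, N)
    if k == 0:
        return 0.0
    return min(0.0, _log_upper_tail(k, a, b, N) / math.log(10.0))


def fisher_overlap(query: OverlapQuery) -> OverlapResult:
    """One-sided (enrichment) overlap test between two gene lists."""
    a, b = len(query.list_a), len(query.list_b)
    k = len(query.list_a & query.list_b)
    N = query.universe_n
    p = hypergeometric_upper_tail(k, a, b, N)
    if a == k or b == k:
        odds = math.inf
    elif k == 0:
        odds = 0.0
    else:
        odds = (k * (N - a - b + k)) / ((a - k) * (b - k))
    jaccard = k / (a + b - k) if (a + b - k) else 0.0
    return OverlapResult(query.label_a, query.label_b, a, b, k, N, p, odds, jaccard)


def calibrate_universe(
    a: int,
    b: int,
    k: int,
    p_target: float,
    n_range: tuple[int, int] | None = None,
) -> tuple[int, float]:
    """Find the integer universe N whose overlap p best matches ``p_target``.

    Bisection on log10 p(N) (strictly decreasing in N in the enrichment
    regime), then a local scan, minimizing |log10 p(N) - log10 p_target|.
    Returns (N, achieved log10 p).  Raises when the target is outside the
    attainable range, reporting the bracketing values.
    """
    if not 0 < p_target < 1:
        raise ValueError("p_target must be in (0, 1)")
    if k == 0:
        raise ValueError("cannot calibrate a universe for k = 0 (p = 1 for all N)")
    lo = max(a, b, a + b - k)
    hi = 10_000_000
    if n_range is not None:
        lo, hi = max(lo, n_range[0]), n_range[1]
    if hi <= lo:
        raise ValueError(f"empty universe range [{lo}, {hi}]")
    target = math.log10(p_target)
    f = lambda N: log10_hypergeometric_upper_tail(k, a, b, N)
    f_lo, f_hi = f(lo), f(hi)
    # p must decrease in N over the bracket for bisection to be meaningful
    probes = np.unique(np.geomspace(lo, hi, 8).astype(int))
    vals = [f(int(N)) for N in probes]
    if any(y > x + 1e-12 for x, y in zip(vals, vals[1:])):
        raise ValueError(
            "p is not decreasing in N over the range; the overlap is not in "
            "the enrichment regime (need k > a*b/N)"
        )
    if not (f_hi - 1e-12 <= target <= f_lo + 1e-12):
        raise ValueError(
            f"p_target {p_target:g} unattainable in [{lo}, {hi}]: "
            f"log10 p spans [{f_hi:.4f}, {f_lo:.4f}], target {target:.4f}"
        )
    nlo, nhi = lo, hi
    while nhi - nlo > 1:
        mid = (nlo + nhi) // 2
        if f(mid) > target:
            nlo = mid
        else:
            nhi = mid
    candidates = range(max(lo, nlo - 3), min(hi, nhi + 3) + 1)
    best = min(candidates, key=lambda N: abs(f(N) - target))
    return int(best), f(int(best))


def membership_table(lists: dict[str, set]) -> pd.DataFrame:
    """Gene-by-label boolean membership table with a per-gene count column.

    Rows are the union of all lists in sorted order; one boolean column per
    label plus ``n_analyses``; column sums equal the input list sizes.
    """
    if not isinstance(lists, dict):
        pairs = list(lists)
        labels = [lab for lab, _ in pairs]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        lists = dict(pairs)
    if not lists:
        raise ValueError("need at least one gene list")
    labels = list(lists)
    genes = sorted(set().union(*lists.values()))
    table = pd.DataFrame(
        {label: [g in lists[label] for g in genes] for label in labels},
        index=pd.Index(genes, name="gene_id"),
    )
    table["n_analyses"] = table[labels].sum(axis=1)
    return table
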