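"""Exact combinatorial statistics for enrichment testing.

Every enrichment question in this package reduces to a 2x2 contingency
table (is a CpG in the focal set? is it in the candidate set?) tested with
Fisher's exact test, followed by Benjamini-Hochberg control of the false
discovery rate across many such tables.  Both primitives are implemented
here from their definitions: the Fisher p-value by summing the
hypergeometric probability mass over all tables with the observed margins
that are no more probable than the observed one, and BH-FDR by the step-up
rule.  All factorials go through the log-gamma function; probabilities are
exponentiated only at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "TestResult",
    "hypergeom_pmf",
    "fisher_exact_two_sided",
    "bh_fdr",
]

#: relative tolerance used when comparing probability masses for the
#: two-sided rule; absorbs floating-point ties between equally likely tables
TIE_REL_TOL = 1e-7

ENRICHED = "enriched"
DEPLETED = "depleted"
NONE = "none"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of non-negative counts.

    ``a`` is the focal-and-focal cell: rows are membership in set 1,
    columns membership in set 2, so ``a`` counts items in both sets.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"cell {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"cell {name!r} must be >= 0, got {v}")
        if self.n == 0:
            raise ValueError("all-zero table: the test is undefined")

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def col1(self) -> int:
        return self.a + self.c

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable":
        """Swap the roles of the two sets (rows <-> columns)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided Fisher exact test.

    ``odds_ratio`` is the sample odds ratio ``(a*d)/(b*c)``; it is
    ``math.inf`` when exactly one of the cross products is zero with the
    other positive, and ``math.nan`` when both are zero (no information).
    ``direction`` is ``"enriched"`` iff the odds ratio exceeds 1,
    ``"depleted"`` iff it is below 1, else ``"none"``.
    """

    odds_ratio: float
    p_two_sided: float
    direction: str


def _log_pmf_support(row1: int, col1: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Log hypergeometric pmf over the full support of ``a`` given margins."""
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    # log C(row1, a) + log C(n-row1, col1-a) - log C(n, col1)
    log_pmf = (
        gammaln(row1 + 1)
        - gammaln(support + 1)
        - gammaln(row1 - support + 1)
        + gammaln(n - row1 + 1)
        - gammaln(col1 - support + 1)
        - gammaln(n - row1 - col1 + support + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )
    return support, log_pmf


def hypergeom_pmf(a: int, row1: int, col1: int, n: int) -> float:
    """P(X = a) for X hypergeometric with margins ``row1``, ``col1``, total ``n``.

    Computed in log space for numerical stability at large counts.
    """
    if row1 < 0 or col1 < 0 or n < 1 or row1 > n or col1 > n:
        raise ValueError(
            f"inconsistent margins: row1={row1}, col1={col1}, N={n}"
        )
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    if not lo <= a <= hi:
        raise ValueError(f"a={a} outside the support [{lo}, {hi}]")
    support, log_pmf = _log_pmf_support(row1, col1, n)
    return float(np.exp(log_pmf[a - support[0]]))


def _odds_ratio(t: ContingencyTable) -> float:
    ad = t.a * t.d
    bc = t.b * t.c
    if bc == 0 and ad == 0:
        return math.nan
    if bc == 0:
        return math.inf
    return ad / bc


def _direction(odds_ratio: float) -> str:
    if math.isnan(odds_ratio):
        return NONE
    if odds_ratio > 1:
        return ENRICHED
    if odds_ratio < 1:
        return DEPLETED
    return NONE


def fisher_exact_two_sided(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums the hypergeometric pmf over every table sharing the
    observed margins whose probability does not exceed the observed
    probability by more than a relative tolerance of ``TIE_REL_TOL``
    (the usual pmf-comparison two-sided rule with floating-point tie
    handling).
    """
    support, log_pmf = _log_pmf_support(table.row1, table.col1, table.n)
    obs = log_pmf[table.a - support[0]]
    include = log_pmf <= obs + math.log1p(TIE_REL_TOL)
    p = float(np.exp(log_pmf[include]).sum())
    p = min(p, 1.0)
    odds = _odds_ratio(table)
    return TestResult(odds_ratio=odds, p_two_sided=p, direction=_direction(odds))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` on the sorted p-values, capped
    at 1.  Input p-values must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q
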