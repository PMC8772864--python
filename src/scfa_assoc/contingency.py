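"""2×2 contingency statistics: odds ratio, Woolf CI, exact p, recovery.

The 2×2 table is laid out as

        exposed   unexposed
  row1     a          b
  row2     c          d

with OR = (a·d)/(b·c) and the Woolf (log-normal) 95% interval
exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d)). Tables containing a zero
cell get the Haldane–Anscombe correction (+0.5 to every cell), flagged
in the result. The two-sided exact p follows Fisher's minimum-likelihood
convention (every table at least as improbable as the observed one);
the tail-doubling convention is available as an option.

``recover_table`` inverts the reporting direction: given printed row
margins, an OR and a CI, it scans every integer table with those margins
and returns the ones reproducing the printed numbers — which is how the
unprinted tables behind published ORs are reconstructed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

from scipy import stats

__all__ = ["ContingencyResult", "odds_ratio", "woolf_ci", "exact_p",
           "woolf_p", "recover_table", "contingency_result"]


class ContingencyError(ValueError):
    pass


def _validate(a, b, c, d):
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ContingencyError("counts must be non-negative")
    if sum(cells) == 0:
        raise ContingencyError("all-zero table")
    return cells


def _corrected(a, b, c, d) -> Tuple[Tuple[float, float, float, float], bool]:
    if min(a, b, c, d) == 0:
        return (a + 0.5, b + 0.5, c + 0.5, d + 0.5), True
    return (float(a), float(b), float(c), float(d)), False


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a·d)/(b·c); Haldane–Anscombe corrected when a cell is zero."""
    _validate(a, b, c, d)
    (a_, b_, c_, d_), _ = _corrected(a, b, c, d)
    return (a_ * d_) / (b_ * c_)


def woolf_ci(a: int, b: int, c: int, d: int,
             level: float = 0.95) -> Tuple[float, float]:
    """Woolf log-normal confidence interval for the odds ratio."""
    _validate(a, b, c, d)
    if not 0 < level < 1:
        raise ContingencyError("level must lie in (0, 1)")
    (a_, b_, c_, d_), corrected = _corrected(a, b, c, d)
    if not corrected and min(a, b, c, d) == 0:
        raise ContingencyError("zero cell without correction")
    log_or = math.log((a_ * d_) / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = float(stats.norm.ppf((1 + level) / 2))
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def exact_p(a: int, b: int, c: int, d: int,
            convention: str = "min_likelihood") -> float:
    """Fisher's exact two-sided p-value.

    ``min_likelihood`` sums the probabilities of all tables with the same
    margins whose point probability does not exceed the observed one;
    ``doubling`` doubles the smaller one-sided tail (capped at 1).
    """
    _validate(a, b, c, d)
    if convention == "min_likelihood":
        return float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])
    if convention == "doubling":
        n, k, m = a + b + c + d, a + b, a + c
        rv = stats.hypergeom(n, k, m)
        lower = float(rv.cdf(a))
        upper = float(rv.sf(a - 1))
        return min(1.0, 2.0 * min(lower, upper))
    raise ContingencyError(f"unknown convention {convention!r}")


def woolf_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided normal-approximation p from the Woolf log-OR z statistic."""
    (a_, b_, c_, d_), _ = _corrected(*_validate(a, b, c, d))
    log_or = math.log((a_ * d_) / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return float(2 * stats.norm.sf(abs(log_or) / se))


@dataclass(frozen=True)
class ContingencyResult:
    a: int
    b: int
    c: int
    d: int
    oddsratio: float
    ci_low: float
    ci_high: float
    p: float
    p_woolf: float
    level: float = 0.95
    corrected: bool = False
    or_method: str = "cross_product"
    ci_method: str = "woolf"
    p_method: str = "fisher_min_likelihood"


def contingency_result(a: int, b: int, c: int, d: int,
                       level: float = 0.95) -> ContingencyResult:
    """Full 2×2 summary: OR, Woolf CI, Fisher exact p, Woolf z p."""
    _validate(a, b, c, d)
    _, corrected = _corrected(a, b, c, d)
    lo, hi = woolf_ci(a, b, c, d, level=level)
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        oddsratio=odds_ratio(a, b, c, d),
        ci_low=lo, ci_high=hi,
        p=exact_p(a, b, c, d),
        p_woolf=woolf_p(a, b, c, d),
        level=level, corrected=corrected)


def recover_table(row_margins: Tuple[int, int], target_or: float,
                  target_ci: Tuple[float, float],
                  tol: float = 1e-9) -> List[Tuple[int, int, int, int]]:
    """All integer 2×2 tables with given row margins matching printed stats.

    Scans every (a, b, c, d) with a+b and c+d equal to the margins and all
    cells positive (a zero cell cannot yield a clean printed Woolf CI),
    keeping tables whose OR and CI bounds, rounded to 3 decimals, match
    the targets within ``tol``. An empty list means the printed numbers
    admit no such table.
    """
    r1, r2 = row_margins
    if r1 <= 0 or r2 <= 0:
        raise ContingencyError("margins must be positive")
    if tol <= 0:
        raise ContingencyError("tol must be positive")
    lo_t, hi_t = target_ci
    hits = []
    for a in range(1, r1):
        b = r1 - a
        for c in range(1, r2):
            d = r2 - c
            orr = (a * d) / (b * c)
            if abs(round(orr, 3) - target_or) > tol:
                continue
            lo, hi = woolf_ci(a, b, c, d)
            if (abs(round(lo, 3) - lo_t) <= tol
                    and abs(round(hi, 3) - hi_t) <= tol):
                hits.append((a, b, c, d))
    return hits
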