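"""Disproportionality statistics: contingency tables, ROR, Woolf CI, z-test.

A spontaneous-reporting database has no exposure denominator, so signal
detection compares reporting rates *within* the database.  For one drug and
one (composite) event the deduplicated reports partition into a 2x2 table::

                       event   other events
        drug             a          b
        all other drugs  c          d

The reporting odds ratio ROR = (a/b)/(c/d) measures how disproportionately
the event is reported with the drug relative to the rest of the database.
Inference is on the log scale (Woolf): se = sqrt(1/a + 1/b + 1/c + 1/d),
95% CI = exp(ln ROR +/- z_{0.975} * se), and the two-sided p-value comes
from z = ln ROR / se.  A ROR is a reporting signal, not a risk estimate.

Drugs whose event cell falls below a minimum-count threshold (default 5
drug-event pairs) are excluded: tiny counts make the ROR unstable and prone
to spurious signals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy.stats import norm

from .model import SafetyReport
from .vocab import EventTermSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 5
EXCLUDED_BELOW_MIN_COUNT = "below-min-count"


class DegenerateTableError(ValueError):
    """Raised when a zero cell makes the ROR undefined and correction is off."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d) of the drug x event 2x2 table, in reports."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swap_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)

    def cells(self, correction: bool = False) -> tuple[float, float, float, float]:
        """Cell values, Haldane-Anscombe +0.5 corrected if requested.

        Without correction a zero cell raises :class:`DegenerateTableError`.
        """
        if correction:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        if min(self.a, self.b, self.c, self.d) == 0:
            raise DegenerateTableError(f"zero cell in {self}; enable correction")
        return (float(self.a), float(self.b), float(self.c), float(self.d))


def ror(table: ContingencyTable, correction: bool = False) -> float:
    """Reporting odds ratio (a*d)/(b*c)."""
    a, b, c, d = table.cells(correction)
    return (a * d) / (b * c)


def log_ror_se(table: ContingencyTable, correction: bool = False) -> float:
    """Woolf standard error of ln ROR: sqrt(1/a + 1/b + 1/c + 1/d)."""
    a, b, c, d = table.cells(correction)
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def woolf_ci(table: ContingencyTable, alpha: float = 0.05,
             correction: bool = False) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the ROR at level 1 - alpha."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    point = ror(table, correction)
    z = norm.ppf(1 - alpha / 2)
    half = z * log_ror_se(table, correction)
    return (point * math.exp(-half), point * math.exp(half))


def z_p_value(table: ContingencyTable, correction: bool = False) -> float:
    """Two-sided p-value of the Woolf z-test of ROR = 1."""
    z = math.log(ror(table, correction)) / log_ror_se(table, correction)
    return float(2.0 * norm.cdf(-abs(z)))


@dataclass(frozen=True)
class SignalResult:
    """One drug's screen outcome: counts, statistics, inclusion flag."""

    drug: str
    table: ContingencyTable
    ror: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    excluded: bool = False
    reason: str | None = None


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals, the convention of
    published ROR tables (banker's rounding would differ on exact halves)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def build_contingency(reports: list[SafetyReport], drug: str,
                      term_set: EventTermSet,
                      comparator: str = "exclusive") -> ContingencyTable:
    """Count the 2x2 table for one drug over deduplicated reports.

    A report counts toward the drug row if the drug appears in any role, and
    toward the event column if at least one of its PTs is in the composite
    set; each report lands in exactly one cell.  With the default
    ``"exclusive"`` comparator the drug's own reports are removed from the
    comparator row (c = total event reports - a, d = total other - b);
    ``"inclusive"`` keeps whole-database totals in the comparator.
    """
    composite = term_set.composite_terms
    a = b = n_event = 0
    for report in reports:
        has_event = any(pt.lower() in composite for pt in report.events)
        n_event += has_event
        if report.has_drug(drug):
            if has_event:
                a += 1
            else:
                b += 1
    n_other = len(reports) - n_event
    if comparator == "exclusive":
        return ContingencyTable(a, b, n_event - a, n_other - b)
    if comparator == "inclusive":
        return ContingencyTable(a, b, n_event, n_other)
    raise ValueError(f"unknown comparator {comparator!r}")


def apply_min_count_filter(results: list[SignalResult],
                           k: int = DEFAULT_MIN_COUNT) -> list[SignalResult]:
    """Flag results with fewer than ``k`` drug-event pairs as excluded.

    Excluded results carry no statistics (their ROR would be unstable);
    retained results pass through unchanged.
    """
    if k < 1:
        raise ValueError(f"minimum count k must be >= 1, got {k}")
    out: list[SignalResult] = []
    for res in results:
        if res.table.a < k:
            out.append(SignalResult(drug=res.drug, table=res.table,
                                    excluded=True, reason=EXCLUDED_BELOW_MIN_COUNT))
        else:
            out.append(replace(res, excluded=False, reason=None))
    return out


def _finish(drug: str, table: ContingencyTable, k: int, alpha: float,
            correction: bool) -> SignalResult:
    if table.a < k:
        return SignalResult(drug=drug, table=table, excluded=True,
                            reason=EXCLUDED_BELOW_MIN_COUNT)
    try:
        point = ror(table, correction)
        low, high = woolf_ci(table, alpha, correction)
        p = z_p_value(table, correction)
    except DegenerateTableError:
        return SignalResult(drug=drug, table=table, excluded=True,
                            reason="degenerate-table")
    return SignalResult(drug=drug, table=table, ror=point,
                        ci_low=low, ci_high=high, p_value=p)


def screen(reports: list[SafetyReport], drug_list: list[str],
           term_set: EventTermSet, k: int = DEFAULT_MIN_COUNT,
           alpha: float = 0.05, comparator: str = "exclusive",
           correction: bool = False) -> list[SignalResult]:
    """Run the full multi-drug screen against the whole-database comparator.

    Returns one :class:`SignalResult` per drug, in ``drug_list`` order.
    """
    if not reports:
        raise ValueError("screen requires a non-empty report list")
    if k < 1:
        raise ValueError(f"minimum count k must be >= 1, got {k}")
    composite = term_set.composite_terms
    n_event = sum(any(pt.lower() in composite for pt in r.events) for r in reports)
    n_other = len(reports) - n_event
    # Single pass over reports for all drugs' (a, b) cells.
    wanted = set(drug_list)
    ab: dict[str, list[int]] = {d: [0, 0] for d in drug_list}
    for report in reports:
        has_event = any(pt.lower() in composite for pt in report.events)
        for ingredient in report.ingredients & wanted:
            ab[ingredient][0 if has_event else 1] += 1
    results = []
    for drug in drug_list:
        a, b = ab[drug]
        if comparator == "exclusive":
            table = ContingencyTable(a, b, n_event - a, n_other - b)
        elif comparator == "inclusive":
            table = ContingencyTable(a, b, n_event, n_other)
        else:
            raise ValueError(f"unknown comparator {comparator!r}")
        results.append(_finish(drug, table, k, alpha, correction))
    return results


def screen_from_counts(counts: dict[str, tuple[int, int]], total_event: int,
                       total_other: int, k: int = DEFAULT_MIN_COUNT,
                       alpha: float = 0.05, comparator: str = "exclusive",
                       correction: bool = False) -> list[SignalResult]:
    """Screen from pre-tabulated per-drug (a, b) counts plus database totals.

    This is the from-counts input mode: published drug-level report counts
    and the all-drugs totals are enough to reproduce every statistic without
    the underlying report archive.
    """
    results = []
    for drug, (a, b) in counts.items():
        if comparator == "exclusive":
            table = ContingencyTable(a, b, total_event - a, total_other - b)
        elif comparator == "inclusive":
            table = ContingencyTable(a, b, total_event, total_other)
        else:
            raise ValueError(f"unknown comparator {comparator!r}")
        results.append(_finish(drug, table, k, alpha, correction))
    return results


def results_frame(results: list[SignalResult]) -> pd.DataFrame:
    """Tabulate screen results (full precision; round for display only)."""
    return pd.DataFrame(
        {
            "drug": r.drug, "a": r.table.a, "b": r.table.b,
            "c": r.table.c, "d": r.table.d, "ror": r.ror,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
            "excluded": r.excluded, "reason": r.reason or "",
        }
        for r in results
    )
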