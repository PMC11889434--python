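"""Stratified screens, demographic summaries, yearly trends, subtype mixes.

These operations describe the composite-event case series (who is reported,
when, with which histology) and check robustness of the screen by re-running
it inside demographic strata with the comparator totals recomputed within
each stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model import AGE_BANDS, SEX_LEVELS, UNSPECIFIED, SafetyReport
from .signal import SignalResult, screen
from .vocab import EventTermSet, classify_event

logger = logging.getLogger(__name__)

#: Histology categories of the per-drug subtype breakdown; "other" pools
#: generic, recurrent, follicular, anaplastic and otherwise unspecified
#: pathology.
BREAKDOWN_CATEGORIES = ("medullary", "papillary", "metastatic", "other")
_BREAKDOWN_MAP = {"medullary": "medullary", "papillary": "papillary",
                  "metastatic": "metastatic"}

#: Report-classification categories of the demographic summary, which keeps
#: the two generic PTs ("Thyroid cancer", "Thyroid neoplasm") as their own
#: classes and pools anaplastic/recurrent/metastatic under "other".
SUMMARY_CLASSES = ("thyroid cancer", "thyroid neoplasm", "papillary thyroid cancer",
                   "medullary thyroid cancer", "follicular thyroid cancer", "other")


@dataclass(frozen=True)
class StratumSpec:
    """One stratification request: an axis and a level on it."""

    axis: str  # "sex" | "age_band" | "year"
    level: str | int

    def matches(self, report: SafetyReport) -> bool:
        if self.axis == "sex":
            return report.sex == self.level
        if self.axis == "age_band":
            return report.age_band == self.level
        if self.axis == "year":
            if self.level == UNSPECIFIED:
                return report.year is None
            return report.year == self.level
        raise ValueError(f"unknown stratum axis {self.axis!r}")


def event_reports(reports: list[SafetyReport], term_set: EventTermSet) -> list[SafetyReport]:
    """Restrict to reports carrying at least one composite-event PT."""
    composite = term_set.composite_terms
    return [r for r in reports if any(pt.lower() in composite for pt in r.events)]


def _classify_summary(pt: str, term_set: EventTermSet) -> str | None:
    is_member, _ = classify_event(pt, term_set)
    if not is_member:
        return None
    key = pt.strip().lower()
    return key if key in SUMMARY_CLASSES else "other"


def demographics_summary(reports: list[SafetyReport],
                         term_set: EventTermSet) -> pd.DataFrame:
    """Percentage table over an event-report case series.

    Sections: sex, age band, report classification (distinct composite PTs
    per report, percentages over all classified mentions) and reporting
    country.  Sex, age and country percentages are over reports and each
    section sums to 100.

    Returns a tidy frame with columns ``section, level, percent``.
    """
    if not reports:
        raise ValueError("demographics_summary requires a non-empty case series")
    n = len(reports)
    rows: list[tuple[str, str, float]] = []
    for level in SEX_LEVELS:
        rows.append(("sex", level, 100.0 * sum(r.sex == level for r in reports) / n))
    for band in AGE_BANDS:
        rows.append(("age_band", band, 100.0 * sum(r.age_band == band for r in reports) / n))
    mentions: dict[str, int] = {c: 0 for c in SUMMARY_CLASSES}
    total_mentions = 0
    for r in reports:
        cats = {_classify_summary(pt, term_set) for pt in r.events}
        for cat in cats - {None}:
            mentions[cat] += 1
            total_mentions += 1
    for cat in SUMMARY_CLASSES:
        pct = 100.0 * mentions[cat] / total_mentions if total_mentions else 0.0
        rows.append(("classification", cat, pct))
    countries = sorted({r.country or UNSPECIFIED for r in reports})
    for country in countries:
        share = sum((r.country or UNSPECIFIED) == country for r in reports)
        rows.append(("country", country, 100.0 * share / n))
    return pd.DataFrame(rows, columns=["section", "level", "percent"])


def stratified_screen(reports: list[SafetyReport], spec: StratumSpec,
                      drug_list: list[str], term_set: EventTermSet,
                      **screen_kwargs) -> list[SignalResult]:
    """Run the screen inside one stratum, totals recomputed within it.

    An empty stratum yields an empty result list with a warning rather than
    an error, so sweeps over all levels of an axis are safe.
    """
    subset = [r for r in reports if spec.matches(r)]
    if not subset:
        logger.warning("stratum %s=%s is empty", spec.axis, spec.level)
        return []
    return screen(subset, drug_list, term_set, **screen_kwargs)


@dataclass(frozen=True)
class YearlyTrend:
    """Composite-event report counts per calendar year for a drug class."""

    series: pd.Series  # index: consecutive years; values: counts
    unspecified: int   # event reports in the class with no usable year

    @property
    def total(self) -> int:
        return int(self.series.sum()) + self.unspecified


def yearly_trend(reports: list[SafetyReport], drug_class: frozenset[str] | set[str],
                 term_set: EventTermSet) -> YearlyTrend:
    """Count composite-event reports naming >=1 class member, per year.

    Years inside the observed range with no reports are filled with zero;
    reports without a year are tallied separately.
    """
    cases = event_reports(reports, term_set)
    years: list[int] = []
    unspecified = 0
    members = frozenset(drug_class)
    for r in cases:
        if not (r.ingredients & members):
            continue
        if r.year is None:
            unspecified += 1
        else:
            years.append(r.year)
    if not years:
        return YearlyTrend(pd.Series(dtype=int), unspecified)
    counts = pd.Series(years).value_counts().sort_index()
    full_index = range(min(years), max(years) + 1)
    return YearlyTrend(counts.reindex(full_index, fill_value=0).astype(int), unspecified)


def subtype_breakdown(reports: list[SafetyReport], drug: str,
                      term_set: EventTermSet) -> dict[str, float]:
    """Histological subtype proportions among one drug's event reports.

    A report naming composite PTs of several distinct subtypes contributes
    one mention to each; proportions are over subtype mentions, so they sum
    to 1.  Raises on a drug with no composite-event reports.
    """
    cases = [r for r in event_reports(reports, term_set) if r.has_drug(drug)]
    if not cases:
        raise ValueError(f"no composite-event reports name {drug!r}")
    mentions = {c: 0 for c in BREAKDOWN_CATEGORIES}
    total = 0
    for r in cases:
        subtypes = {term_set.subtype_map[pt.lower()] for pt in r.events
                    if pt.lower() in term_set.subtype_map}
        for st in {_BREAKDOWN_MAP.get(s, "other") for s in subtypes}:
            mentions[st] += 1
            total += 1
    return {c: mentions[c] / total for c in BREAKDOWN_CATEGORIES}
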