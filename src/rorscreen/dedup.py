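"""Case-level deduplication.

Spontaneous-report databases carry multiple versions of the same case as
follow-up information arrives.  Counting every version would inflate every
contingency cell, so the screen runs on one report per case: the latest
version, per the FDA's published guidance for FAERS (keep the row with the
highest version identifier for each case number).
"""

from __future__ import annotations

import logging

from .model import SafetyReport

logger = logging.getLogger(__name__)


def deduplicate(reports: list[SafetyReport], enabled: bool = True) -> list[SafetyReport]:
    """Collapse case versions to one report per ``case_id``.

    Keeps the report with the greatest ``version_key`` for each case; on a
    tied ``(case_id, version_key)`` pair the first occurrence wins and a
    warning is logged.  Output is sorted by ``case_id`` so downstream runs
    are deterministic.  Idempotent.  With ``enabled=False`` the input is
    returned sorted but uncollapsed.
    """
    if not enabled:
        return sorted(reports, key=lambda r: (r.case_id, r.version_key))
    best: dict[str, SafetyReport] = {}
    ties = 0
    for report in reports:
        current = best.get(report.case_id)
        if current is None or report.version_key > current.version_key:
            best[report.case_id] = report
        elif report.version_key == current.version_key and report is not current:
            ties += 1
    if ties:
        logger.warning("%d duplicate (case_id, version_key) pairs — kept first seen", ties)
    removed = len(reports) - len(best)
    if removed:
        logger.info("deduplication removed %d superseded case versions", removed)
    return [best[cid] for cid in sorted(best)]
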