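"""Reading FAERS-style quarterly ASCII files and the internal flat format.

FAERS publishes each quarter as "$"-delimited ASCII tables; the three used
here are DEMO (one row per case version: demographics, date, country), DRUG
(one row per drug entry) and REAC (one row per reported reaction PT).
Legacy files are not clean UTF-8, so input is decoded as Latin-1 with
replacement.

The internal flat format is three CSVs plus a JSON manifest — small, diffable
and bit-exact under round-trip — so the pipeline is testable without the
multi-gigabyte quarterly archive.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .model import UNSPECIFIED, ROLE_CODES, SafetyReport, age_band
from .vocab import DrugDictionary, normalize_drug

logger = logging.getLogger(__name__)

INTERNAL_FILES = ("reports.csv", "report_drugs.csv", "report_events.csv")


@dataclass(frozen=True)
class Dialect:
    """Column and delimiter conventions of a FAERS-style ASCII quarter.

    ``year_source`` selects which date column supplies the report year for
    trend analyses: "event" prefers the adverse-event date, "receipt" the
    FDA receipt date.  Candidate column names are tried in order, so both
    modern (primaryid) and legacy (isr) layouts parse.
    """

    delimiter: str = "$"
    encoding: str = "latin-1"
    year_source: str = "event"  # "event" | "receipt"
    id_cols: tuple[str, ...] = ("primaryid", "isr")
    case_cols: tuple[str, ...] = ("caseid", "case")
    sex_cols: tuple[str, ...] = ("sex", "gndr_cod")
    event_date_cols: tuple[str, ...] = ("event_dt",)
    receipt_date_cols: tuple[str, ...] = ("fda_dt", "init_fda_dt", "rept_dt")
    country_cols: tuple[str, ...] = ("reporter_country", "occr_country")

    def date_cols(self) -> tuple[str, ...]:
        if self.year_source == "event":
            return self.event_date_cols + self.receipt_date_cols
        return self.receipt_date_cols + self.event_date_cols


@dataclass
class RawQuarter:
    """Parsed records of one quarter, before normalization and assembly."""

    demo_records: list[dict]
    drug_records: list[dict]
    reaction_records: list[dict]
    skipped_lines: int = 0

    def counts(self) -> tuple[int, int, int]:
        return (
            len(self.demo_records),
            len(self.drug_records),
            len(self.reaction_records),
        )


def _pick(header: list[str], candidates: tuple[str, ...], what: str, path) -> str:
    for name in candidates:
        if name in header:
            return name
    raise ValueError(f"{path}: no {what} column among {candidates} in header {header}")


def _read_table(path: str | Path, dialect: Dialect, columns: dict[str, tuple[str, ...]],
                required: tuple[str, ...]) -> tuple[list[dict], int]:
    """Parse one "$"-delimited table into dicts keyed by logical field name.

    Lines whose field count disagrees with the header, or whose required
    fields fail to parse, are counted and logged — never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding=dialect.encoding, errors="replace") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ValueError(f"{path}: empty or unparseable header")
        header = [h.strip().lower() for h in header_line.rstrip("\n\r").split(dialect.delimiter)]
        col_idx: dict[str, int] = {}
        for logical, candidates in columns.items():
            try:
                col_idx[logical] = header.index(_pick(header, candidates, logical, path))
            except ValueError:
                if logical in required:
                    raise
        records: list[dict] = []
        skipped = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n\r").split(dialect.delimiter)
            if len(fields) != len(header):
                skipped += 1
                logger.warning("%s:%d: expected %d fields, got %d — skipped",
                               path, lineno, len(header), len(fields))
                continue
            rec = {logical: fields[i].strip() for logical, i in col_idx.items()}
            if any(not rec.get(r) for r in required):
                skipped += 1
                logger.warning("%s:%d: missing required field — skipped", path, lineno)
                continue
            records.append(rec)
    return records, skipped


def read_quarter(demo_path: str | Path, drug_path: str | Path,
                 reac_path: str | Path, dialect: Dialect | None = None) -> RawQuarter:
    """Parse one quarter's DEMO/DRUG/REAC files into a :class:`RawQuarter`."""
    dialect = dialect or Dialect()
    demo, s1 = _read_table(
        demo_path, dialect,
        columns={
            "id": dialect.id_cols, "case": dialect.case_cols,
            "sex": dialect.sex_cols, "age": ("age",), "age_cod": ("age_cod",),
            "date": dialect.date_cols(), "country": dialect.country_cols,
        },
        required=("id", "case"),
    )
    drug, s2 = _read_table(
        drug_path, dialect,
        columns={"id": dialect.id_cols, "drug_seq": ("drug_seq",),
                 "drugname": ("drugname",), "role_cod": ("role_cod",)},
        required=("id", "drugname"),
    )
    reac, s3 = _read_table(
        reac_path, dialect,
        columns={"id": dialect.id_cols, "pt": ("pt",)},
        required=("id", "pt"),
    )
    quarter = RawQuarter(demo, drug, reac, skipped_lines=s1 + s2 + s3)
    logger.info("parsed quarter: %d demo, %d drug, %d reaction records (%d skipped)",
                *quarter.counts(), quarter.skipped_lines)
    return quarter


def _parse_year(date_field: str | None) -> int | None:
    """FAERS dates are YYYYMMDD, YYYYMM or YYYY; the leading 4 digits are the year."""
    if not date_field:
        return None
    head = date_field.strip()[:4]
    if len(head) == 4 and head.isdigit():
        year = int(head)
        if 1900 <= year <= 2100:
            return year
    return None


def _parse_sex(code: str | None) -> str:
    return {"F": "female", "M": "male"}.get((code or "").strip().upper(), UNSPECIFIED)


def assemble_reports(quarters: list[RawQuarter],
                     drug_dict: DrugDictionary) -> list[SafetyReport]:
    """Build one pre-deduplication :class:`SafetyReport` per case version.

    Drug names are normalized through ``drug_dict`` (unmapped names fall into
    the other-drugs bucket so comparator denominators stay complete); all
    role codes are retained — the role never filters a drug entry.  Case
    versions with no drug or no reaction record are dropped with a count
    logged, since a report contributes to no contingency cell without both.
    """
    if not quarters:
        logger.warning("assemble_reports called with no quarters")
        return []
    drugs_by_id: dict[str, set[tuple[str, str]]] = {}
    events_by_id: dict[str, set[str]] = {}
    for q in quarters:
        for rec in q.drug_records:
            role = (rec.get("role_cod") or "").strip().upper()
            if role not in ROLE_CODES:
                role = ""
            drugs_by_id.setdefault(rec["id"], set()).add(
                (normalize_drug(rec["drugname"], drug_dict), role)
            )
        for rec in q.reaction_records:
            events_by_id.setdefault(rec["id"], set()).add(rec["pt"])

    reports: list[SafetyReport] = []
    incomplete = 0
    seen_ids: set[str] = set()
    for q in quarters:
        for rec in q.demo_records:
            vid = rec["id"]
            if vid in seen_ids:
                continue
            seen_ids.add(vid)
            drugs = drugs_by_id.get(vid)
            events = events_by_id.get(vid)
            if not drugs or not events:
                incomplete += 1
                continue
            country = (rec.get("country") or "").strip()
            reports.append(SafetyReport(
                case_id=rec["case"],
                version_key=int(vid) if vid.isdigit() else abs(hash(vid)) % 10**9,
                sex=_parse_sex(rec.get("sex")),
                age_band=age_band(rec.get("age"), rec.get("age_cod")),
                year=_parse_year(rec.get("date")),
                country=country or None,
                drugs=frozenset(drugs),
                events=frozenset(events),
            ))
    orphans = (set(drugs_by_id) | set(events_by_id)) - seen_ids
    if orphans:
        logger.warning("%d drug/reaction case ids have no demographic record", len(orphans))
    if incomplete:
        logger.info("dropped %d case versions lacking drug or reaction records", incomplete)
    return reports


def write_internal(reports: list[SafetyReport], out_dir: str | Path) -> None:
    """Write reports to the internal flat format (three CSVs + manifest).

    Rows are sorted on (case_id, version_key) and set-valued fields are
    written in sorted order, so the round trip is bit-exact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = sorted(reports, key=lambda r: (r.case_id, r.version_key))
    with open(out / "reports.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "version_key", "sex", "age_band", "year", "country"])
        for r in ordered:
            w.writerow([r.case_id, r.version_key, r.sex, r.age_band,
                        "" if r.year is None else r.year, r.country or ""])
    with open(out / "report_drugs.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "version_key", "ingredient", "role"])
        for r in ordered:
            for ingredient, role in sorted(r.drugs):
                w.writerow([r.case_id, r.version_key, ingredient, role])
    with open(out / "report_events.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "version_key", "preferred_term"])
        for r in ordered:
            for pt in sorted(r.events):
                w.writerow([r.case_id, r.version_key, pt])
    manifest = {"format": "rorscreen-internal", "version": 1,
                "n_reports": len(ordered)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def read_internal(in_dir: str | Path) -> list[SafetyReport]:
    """Read the internal flat format back into reports."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text(encoding="utf-8"))
    if manifest.get("format") != "rorscreen-internal":
        raise ValueError(f"{src}: not an internal-format directory")
    drugs: dict[tuple[str, int], set[tuple[str, str]]] = {}
    events: dict[tuple[str, int], set[str]] = {}
    with open(src / "report_drugs.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["case_id"], int(row["version_key"]))
            drugs.setdefault(key, set()).add((row["ingredient"], row["role"]))
    with open(src / "report_events.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["case_id"], int(row["version_key"]))
            events.setdefault(key, set()).add(row["preferred_term"])
    reports: list[SafetyReport] = []
    with open(src / "reports.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["case_id"], int(row["version_key"]))
            reports.append(SafetyReport(
                case_id=row["case_id"],
                version_key=int(row["version_key"]),
                sex=row["sex"],
                age_band=row["age_band"],
                year=int(row["year"]) if row["year"] else None,
                country=row["country"] or None,
                drugs=frozenset(drugs.get(key, set())),
                events=frozenset(events.get(key, set())),
            ))
    if len(reports) != manifest["n_reports"]:
        raise ValueError(f"{src}: manifest reports {manifest['n_reports']} rows, "
                         f"found {len(reports)}")
    return reports
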