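"""Vocabularies for drug-name normalization and adverse-event term classification.

Spontaneous-report databases record drugs as free text (brand names, salts,
doses, formulations) and adverse events as MedDRA preferred terms (PTs).
This module maps verbatim drug strings to canonical ingredients and PTs to a
composite thyroid-cancer event with histological subtype labels.

Default vocabularies ship with the package and can be replaced by editable
CSV files with the same columns.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

#: Token returned for drug names absent from the dictionary.  Unmapped drugs
#: are retained so the all-other-drugs comparator keeps a complete denominator.
OTHER_DRUG = "__other__"

#: Canonical histological subtype labels attached to composite-event PTs.
SUBTYPES = (
    "generic",
    "recurrent",
    "papillary",
    "follicular",
    "medullary",
    "anaplastic",
    "metastatic",
)

#: Ingredients screened in the bundled thyroid-cancer analysis: anti-diabetic
#: weight-loss drugs, weight-neutral anti-diabetics, and other weight-loss
#: medications used as comparators.
STUDY_DRUGS = (
    "semaglutide",
    "dulaglutide",
    "liraglutide",
    "tirzepatide",
    "empagliflozin",
    "dapagliflozin",
    "canagliflozin",
    "metformin",
    "sitagliptin",
    "linagliptin",
    "alogliptin",
    "vildagliptin",
    "saxagliptin",
    "pioglitazone",
    "orlistat",
    "bupropion",
    "topiramate",
    "phentermine",
    "naltrexone",
    "insulin glargine",
    "rosuvastatin",
    "glyburide",
)

#: Incretin-based weight-loss drugs tracked as a class for yearly trends.
GLP1_CLASS = frozenset(
    {"semaglutide", "dulaglutide", "liraglutide", "tirzepatide"}
)

# Tokens stripped from verbatim drug strings before lookup: salts, dose
# units and formulation words carry no ingredient information.
_NOISE_TOKENS = frozenset(
    {
        "hcl", "hydrochloride", "sodium", "calcium", "potassium", "maleate",
        "tartrate", "succinate", "mesylate", "besylate", "fumarate",
        "mg", "mcg", "ug", "g", "ml", "iu",
        "tablet", "tablets", "tab", "tabs", "capsule", "capsules", "cap",
        "caps", "injection", "inj", "oral", "solution", "susp", "suspension",
        "pen", "prefilled", "xr", "er", "sr", "cr", "odt",
    }
)

_HAS_DIGIT = re.compile(r"\d")
_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_key(verbatim: str) -> str:
    """Collapse a verbatim drug string to a lookup key.

    Lower-cases, replaces punctuation with spaces, and drops dose/salt/
    formulation tokens and any token containing a digit, so that
    ``"Metformin HCl 500mg"`` and ``"METFORMIN"`` share the key
    ``"metformin"``.
    """
    tokens = _NON_ALNUM.sub(" ", verbatim.lower()).split()
    kept = [t for t in tokens if t not in _NOISE_TOKENS and not _HAS_DIGIT.search(t)]
    return " ".join(kept)


@dataclass(frozen=True)
class DrugDictionary:
    """Synonym dictionary mapping normalized keys to canonical ingredients."""

    entries: dict[str, str]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon_by_key: dict[str, str] = {}
        for key, canonical in self.entries.items():
            if key in canon_by_key and canon_by_key[key] != canonical:
                raise ValueError(f"key {key!r} maps to two ingredients")
            canon_by_key[key] = canonical

    @property
    def canonical_ingredients(self) -> frozenset[str]:
        return frozenset(self.entries.values())

    def members_of_class(self, drug_class: str) -> frozenset[str]:
        return frozenset(
            d for d, c in self.classes.items() if c == drug_class
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        """Load from a CSV with columns ``key, canonical[, drug_class]``."""
        entries: dict[str, str] = {}
        classes: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                key = normalize_key(row["key"])
                entries[key] = row["canonical"]
                if row.get("drug_class"):
                    classes[row["canonical"]] = row["drug_class"]
        return cls(entries=entries, classes=classes)


@dataclass(frozen=True)
class EventTermSet:
    """Composite-event PT set with one subtype label per member term."""

    subtype_map: dict[str, str]  # lower-cased PT -> subtype

    def __post_init__(self) -> None:
        for pt, st in self.subtype_map.items():
            if st not in SUBTYPES:
                raise ValueError(f"unknown subtype {st!r} for PT {pt!r}")

    @property
    def composite_terms(self) -> frozenset[str]:
        return frozenset(self.subtype_map)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTermSet":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            subtype_map={r["preferred_term"].strip().lower(): r["subtype"] for r in rows}
        )


def normalize_drug(verbatim: str, dictionary: DrugDictionary) -> str:
    """Map a verbatim drug string to its canonical ingredient.

    Deterministic; unmapped names fall into the :data:`OTHER_DRUG` bucket
    rather than being dropped, keeping report denominators complete.
    """
    return dictionary.entries.get(normalize_key(verbatim), OTHER_DRUG)


def classify_event(pt: str, terms: EventTermSet) -> tuple[bool, str | None]:
    """Return ``(is_composite, subtype)`` for a preferred term.

    Matching is exact at the PT level, case-insensitive.  Non-member terms
    return ``(False, None)``.
    """
    subtype = terms.subtype_map.get(pt.strip().lower())
    return (subtype is not None, subtype)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("rorscreen").joinpath("data", name)))


def default_drug_dictionary() -> DrugDictionary:
    """Packaged dictionary covering every screened ingredient with brand keys."""
    return DrugDictionary.from_csv(_data_path("drug_dictionary.csv"))


def default_event_terms() -> EventTermSet:
    """Packaged thyroid-cancer composite-event term set."""
    return EventTermSet.from_csv(_data_path("event_terms.csv"))
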