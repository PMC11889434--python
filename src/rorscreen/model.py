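"""Core report model shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Table-style age bands (years).  Ages above 85 have no band and map to
#: "unspecified", as do missing or unparseable ages.
AGE_BANDS = ("0-11", "12-17", "18-64", "65-85", "unspecified")

SEX_LEVELS = ("female", "male", "unspecified")

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.  Roles are carried but never used to filter drug entries.
ROLE_CODES = ("PS", "SS", "C", "I")

UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class SafetyReport:
    """One case version of a spontaneous adverse-event report.

    ``drugs`` holds ``(canonical_ingredient, role_code)`` pairs; ``events``
    holds MedDRA preferred-term strings verbatim (classification against the
    composite event set happens downstream).  ``year`` is ``None`` when the
    report carries no usable date.
    """

    case_id: str
    version_key: int
    sex: str = UNSPECIFIED
    age_band: str = UNSPECIFIED
    year: int | None = None
    country: str | None = None
    drugs: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    events: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"invalid age band {self.age_band!r}")

    @property
    def ingredients(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.drugs)

    def has_drug(self, ingredient: str) -> bool:
        return any(d == ingredient for d, _ in self.drugs)


# Conversion factors from FAERS age unit codes to years.
_AGE_UNIT_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


def age_band(age_value: float | str | None, age_unit: str | None = "YR") -> str:
    """Deterministically band an age value + FAERS unit code.

    Bands: 0-11, 12-17, 18-64, 65-85; anything missing, negative, or above
    85 is "unspecified" (no band is defined past 85).
    """
    if age_value is None or age_value == "":
        return UNSPECIFIED
    try:
        value = float(age_value)
    except (TypeError, ValueError):
        return UNSPECIFIED
    factor = _AGE_UNIT_YEARS.get((age_unit or "YR").strip().upper())
    if factor is None:
        return UNSPECIFIED
    years = value * factor
    if years < 0:
        return UNSPECIFIED
    if years < 12:
        return "0-11"
    if years < 18:
        return "12-17"
    if years < 65:
        return "18-64"
    if years <= 85:
        return "65-85"
    return UNSPECIFIED
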