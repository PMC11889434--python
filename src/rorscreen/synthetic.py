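"""Synthetic spontaneous-report databases with known ground truth.

Real FAERS quarters are multi-gigabyte downloads with no usable truth about
which drug-event associations are real.  This generator emulates the
structure of such a database — demographic mixtures, per-drug report
volumes, a rare composite event, histology mixtures, duplicate case
versions, co-medication — under a fully specified model, so every pipeline
stage can be exercised against known parameters.

Event model: a report's odds of carrying the composite event are the
baseline odds ``p0 / (1 - p0)`` scaled by the *maximum* reporting-odds
multiplier among the drugs it names (multiplier 1 if none).  Taking the max
rather than the product keeps a single-drug report's population ROR equal to
its multiplier and bounds contamination from co-medication: when exactly one
drug has multiplier m and all others 1, the population ROR for that drug is
m exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .model import AGE_BANDS, ROLE_CODES, SEX_LEVELS, UNSPECIFIED, SafetyReport
from .signal import ContingencyTable
from .vocab import OTHER_DRUG, default_drug_dictionary, _data_path

#: Composite-event PTs with a reporting mixture resembling a thyroid-cancer
#: case series: mostly generic terms, papillary the most common named
#: histology, medullary and follicular rare.
DEFAULT_SUBTYPE_PTS = {
    "Thyroid cancer": 0.77,
    "Thyroid neoplasm": 0.11,
    "Papillary thyroid cancer": 0.091,
    "Medullary thyroid cancer": 0.015,
    "Follicular thyroid cancer": 0.008,
    "Anaplastic thyroid cancer": 0.003,
    "Thyroid cancer metastatic": 0.002,
    "Thyroid cancer recurrent": 0.001,
}

#: Background (non-event) reaction PTs for reports without the composite event.
NOISE_PTS = ("Nausea", "Headache", "Diarrhoea", "Vomiting", "Fatigue",
             "Dizziness", "Rash", "Pruritus")

# Demographic mixtures of the emulated case population.
DEFAULT_SEX_MIX = {"female": 0.63, "male": 0.236, "unspecified": 0.134}
DEFAULT_AGE_MIX = {"0-11": 0.004, "12-17": 0.006, "18-64": 0.428,
                   "65-85": 0.111, "unspecified": 0.451}
DEFAULT_COUNTRY_MIX = {"US": 0.4485, "CA": 0.034, "JP": 0.011, "DE": 0.0081,
                       "FR": 0.0076, "IT": 0.007, "OTHER": 0.4838}


@dataclass(frozen=True)
class DrugSpec:
    """One catalogue drug: marginal report probability and odds multiplier."""

    name: str
    marginal: float      # P(report names this drug)
    multiplier: float    # reporting-odds multiplier; population ROR target

    def __post_init__(self) -> None:
        if not 0 < self.marginal < 1:
            raise ValueError(f"{self.name}: marginal must be in (0,1)")
        if self.multiplier <= 0:
            raise ValueError(f"{self.name}: multiplier must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of one synthetic report database."""

    seed: int
    n_reports: int
    drugs: tuple[DrugSpec, ...]
    p0: float = 14370 / 25939386  # baseline composite-event probability
    year_range: tuple[int, int] = (2004, 2024)
    year_weights: tuple[float, ...] | None = None  # None -> increasing ramp
    sex_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_MIX))
    age_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_MIX))
    country_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_MIX))
    subtype_pts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PTS))
    duplication_rate: float = 0.05   # P(case gets >=1 extra version)
    background_rate: float = 0.6     # P(report names an unmapped background drug)

    def _year_weights(self) -> np.ndarray:
        lo, hi = self.year_range
        if self.year_weights is not None:
            w = np.asarray(self.year_weights, dtype=float)
            if len(w) != hi - lo + 1:
                raise ValueError("year_weights length must match year_range")
        else:
            # Gentle growth with a late surge, echoing modern reporting volumes.
            w = np.linspace(1.0, 3.0, hi - lo + 1)
            w[-2:] *= 3.0
        return w / w.sum()

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0,1)")
        if not 0 <= self.duplication_rate < 1:
            raise ValueError("duplication_rate must be in [0,1)")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0,1]")
        for mix, levels in ((self.sex_mix, SEX_LEVELS), (self.age_mix, AGE_BANDS)):
            if set(mix) - set(levels):
                raise ValueError(f"unknown mixture levels {set(mix) - set(levels)}")
        for mix in (self.sex_mix, self.age_mix, self.country_mix, self.subtype_pts):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture sums to {total}, expected 1")
        names = [d.name for d in self.drugs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate drug names in catalogue")
        self._year_weights()

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["drugs"] = [asdict(d) for d in self.drugs]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        payload["drugs"] = tuple(DrugSpec(**d) for d in payload["drugs"])
        for key in ("year_range",):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        if payload.get("year_weights") is not None:
            payload["year_weights"] = tuple(payload["year_weights"])
        cfg = cls(**payload)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    seed: int
    n_cases: int                  # distinct cases, before duplicate versions
    p0: float
    multipliers: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")


def _sample_core(config: SyntheticConfig, rng: np.random.Generator):
    """Vectorized core draws: drug membership matrix and event flags."""
    n = config.n_reports
    marginals = np.array([d.marginal for d in config.drugs])
    multipliers = np.array([d.multiplier for d in config.drugs])
    has_drug = rng.random((n, len(config.drugs))) < marginals
    report_mult = np.where(has_drug, multipliers, 1.0).max(axis=1)
    base_odds = config.p0 / (1.0 - config.p0)
    odds = base_odds * report_mult
    p_event = odds / (1.0 + odds)
    has_event = rng.random(n) < p_event
    return has_drug, has_event


def simulate_tables(config: SyntheticConfig,
                    rng: np.random.Generator | None = None,
                    comparator: str = "exclusive") -> dict[str, ContingencyTable]:
    """Draw one database and tabulate each catalogue drug's 2x2 counts.

    Skips report materialization entirely (no demographics, duplicates or
    background drugs — none of which touch the contingency counts), so large
    replicate sweeps for coverage and type-I studies are cheap.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    has_drug, has_event = _sample_core(config, rng)
    n_event = int(has_event.sum())
    n_other = config.n_reports - n_event
    tables = {}
    for j, spec in enumerate(config.drugs):
        a = int((has_drug[:, j] & has_event).sum())
        b = int(has_drug[:, j].sum()) - a
        if comparator == "exclusive":
            tables[spec.name] = ContingencyTable(a, b, n_event - a, n_other - b)
        else:
            tables[spec.name] = ContingencyTable(a, b, n_event, n_other)
    return tables


def generate(config: SyntheticConfig) -> tuple[list[SafetyReport], GroundTruth]:
    """Generate a full synthetic report list plus its ground truth.

    Reproducible: the seed fully determines the output.  Duplicate case
    versions are injected after the case-level draw and are exact copies at
    a higher version number, so deduplication can be verified against the
    recorded distinct-case count.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    has_drug, has_event = _sample_core(config, rng)

    sex_levels, sex_p = zip(*config.sex_mix.items())
    sexes = rng.choice(sex_levels, size=n, p=sex_p)
    age_levels, age_p = zip(*config.age_mix.items())
    ages = rng.choice(age_levels, size=n, p=age_p)
    country_levels, country_p = zip(*config.country_mix.items())
    countries = rng.choice(country_levels, size=n, p=country_p)
    lo, hi = config.year_range
    years = rng.choice(np.arange(lo, hi + 1), size=n, p=config._year_weights())
    has_background = rng.random(n) < config.background_rate
    pts, pt_p = zip(*config.subtype_pts.items())
    event_pts = rng.choice(pts, size=n, p=pt_p)
    noise_pts = rng.choice(NOISE_PTS, size=n)
    # Role codes skew toward suspect roles, as in real report streams.
    roles = rng.choice(ROLE_CODES, size=(n, len(config.drugs) + 1),
                       p=(0.45, 0.15, 0.3, 0.1))
    extra_versions = np.where(rng.random(n) < config.duplication_rate,
                              rng.integers(1, 3, size=n), 0)

    reports: list[SafetyReport] = []
    for i in range(n):
        drugs = {(config.drugs[j].name, str(roles[i, j]))
                 for j in np.flatnonzero(has_drug[i])}
        if has_background[i] or not drugs:
            drugs.add((OTHER_DRUG, str(roles[i, -1])))
        events = frozenset({str(event_pts[i] if has_event[i] else noise_pts[i])})
        base = SafetyReport(
            case_id=f"C{i:08d}",
            version_key=1,
            sex=str(sexes[i]),
            age_band=str(ages[i]),
            year=int(years[i]),
            country=None if countries[i] == UNSPECIFIED else str(countries[i]),
            drugs=frozenset(drugs),
            events=events,
        )
        reports.append(base)
        for v in range(int(extra_versions[i])):
            reports.append(SafetyReport(
                case_id=base.case_id, version_key=v + 2, sex=base.sex,
                age_band=base.age_band, year=base.year, country=base.country,
                drugs=base.drugs, events=base.events,
            ))
    truth = GroundTruth(seed=config.seed, n_cases=n, p0=config.p0,
                        multipliers={d.name: d.multiplier for d in config.drugs})
    return reports, truth


def reference_screen_config(seed: int = 0, n_reports: int = 50_000,
                            marginal_inflation: float = 3.0,
                            p0_inflation: float = 60.0) -> SyntheticConfig:
    """A catalogue whose expected contingency tables mirror, at bench scale,
    the bundled thyroid-cancer screen counts.

    Per-drug marginals are the observed report shares and multipliers the
    observed RORs (Haldane-corrected where a drug had zero event reports).
    Both the marginals and the baseline event probability are inflated so
    that expected event cells are measurable at ``n_reports`` instead of the
    tens of millions of reports behind the original counts.  The marginal
    inflation is kept small: large values make catalogue drugs co-occur so
    often that the max-multiplier event model leaks strong signals into weak
    drugs' cells.  Relative magnitudes across drugs — which drug signals,
    which falls below the minimum-count threshold — are preserved.
    """
    import csv as _csv

    with open(_data_path("thyroid_screen_counts.csv"), newline="", encoding="utf-8") as fh:
        rows = {r["drug"]: (int(r["reports_with_event"]), int(r["reports_other_events"]))
                for r in _csv.DictReader(fh)}
    tot_e, tot_o = rows.pop("all_drugs")
    n_db = tot_e + tot_o
    drugs = []
    for name, (a, b) in rows.items():
        table = ContingencyTable(a, b, tot_e - a, tot_o - b)
        from .signal import ror as _ror
        mult = _ror(table, correction=(min(a, b) == 0))
        drugs.append(DrugSpec(name=name,
                              marginal=min(0.5, marginal_inflation * (a + b) / n_db),
                              multiplier=mult))
    cfg = SyntheticConfig(seed=seed, n_reports=n_reports, drugs=tuple(drugs),
                          p0=min(0.5, p0_inflation * tot_e / n_db))
    cfg.validate()
    return cfg


def write_faers_ascii(reports: list[SafetyReport], out_dir: str | Path,
                      seed: int = 0) -> tuple[Path, Path, Path]:
    """Write reports as "$"-delimited DEMO/DRUG/REAC quarter files.

    Canonical ingredients are rendered as verbatim-style strings by sampling
    brand/generic synonyms and case variants from the packaged dictionary,
    so re-ingesting the files exercises name normalization end-to-end.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    inverse: dict[str, list[str]] = {}
    for key, canonical in default_drug_dictionary().entries.items():
        inverse.setdefault(canonical, []).append(key)
    band_age = {"0-11": 6, "12-17": 15, "18-64": 40, "65-85": 72}

    demo_p, drug_p, reac_p = (out / "DEMO.txt", out / "DRUG.txt", out / "REAC.txt")
    with open(demo_p, "w", encoding="latin-1") as fd, \
         open(drug_p, "w", encoding="latin-1") as fg, \
         open(reac_p, "w", encoding="latin-1") as fr:
        fd.write("primaryid$caseid$sex$age$age_cod$event_dt$reporter_country\n")
        fg.write("primaryid$drug_seq$drugname$role_cod\n")
        fr.write("primaryid$pt\n")
        for r in sorted(reports, key=lambda r: (r.case_id, r.version_key)):
            pid = f"{r.case_id.lstrip('C')}{r.version_key:02d}"
            sex = {"female": "F", "male": "M"}.get(r.sex, "")
            age = band_age.get(r.age_band, "")
            date = f"{r.year}0615" if r.year is not None else ""
            fd.write(f"{pid}${r.case_id}${sex}${age}$YR${date}${r.country or ''}\n")
            for seq, (ingredient, role) in enumerate(sorted(r.drugs), start=1):
                if ingredient == OTHER_DRUG:
                    verbatim = f"BACKGROUNDCOMPOUND{rng.integers(1, 30):02d}"
                else:
                    verbatim = str(rng.choice(inverse[ingredient])).upper()
                fg.write(f"{pid}${seq}${verbatim}${role}\n")
            for pt in sorted(r.events):
                fr.write(f"{pid}${pt}\n")
    return demo_p, drug_p, reac_p
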