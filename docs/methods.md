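# Methods

## The screen

For one drug and a composite event (a fixed set of MedDRA preferred terms),
deduplicated reports are tabulated into a 2×2 contingency table: a = reports
naming the drug with the event, b = naming the drug without it, c and d the
comparator cells. The reporting odds ratio ROR = (a·d)/(b·c) compares the
reporting odds of the event with the drug against the rest of the database.
Inference is asymptotic on the log scale (Woolf): se(ln ROR) =
√(1/a + 1/b + 1/c + 1/d), CI = exp(ln ROR ± z₁₋α/₂·se), and the two-sided
p-value comes from z = ln ROR / se, which is exactly consistent with the CI
(p < α ⟺ 1 outside the 1−α interval). α defaults to 0.05
(z₀.₉₇₅ = 1.959964, computed from the normal quantile, never hard-coded).

Conventions, each chosen where practice varies:

- **Comparator.** Default is *exclusive*: c = (total event reports) − a,
  d = (total non-event reports) − b, i.e. the drug's own reports are removed
  from the comparator — the standard ROR definition. An *inclusive* variant
  (whole-database totals in the comparator row) is a switch; at FAERS scale
  the two differ far below printed precision.
- **Counting unit.** Unique deduplicated reports. A report listing a drug
  twice, or listing it in several roles, counts once; a report with several
  composite PTs counts once in the event column. Role codes (PS/SS/C/I) are
  carried but never filter a drug entry, so concomitant exposure is counted.
- **Minimum-count threshold.** Drugs with a < 5 drug–event pairs are
  excluded and carry no statistics; k is configurable but 5 is the
  conventional floor below which RORs are too unstable to report. The
  boundary is literal: a = 5 is retained.
- **Zero cells.** With any zero cell the ROR is undefined; the engine raises
  a degenerate-table error unless the Haldane–Anscombe +0.5 correction is
  requested. The correction is off by default because the minimum-count
  threshold already removes every zero a-cell, and comparator cells cannot
  be zero in any realistically sized database.
- **Rounding.** Internal values are full precision; display rounding is
  half-up at 2 decimals, matching how ROR tables are conventionally printed
  (banker's rounding would differ on exact halves).

A from-counts mode accepts per-drug (a, b) plus all-drugs totals and skips
ingestion entirely: published count tables are sufficient inputs to the
whole statistical layer.

## Vocabularies

Drug strings are normalized by lower-casing, stripping punctuation, and
dropping salt/dose/formulation tokens and any token containing a digit, then
looked up in a synonym dictionary (brand and generic keys for every screened
ingredient). Unmapped names map to a single other-drugs bucket and are
*retained*: they contribute to the comparator cells, so denominators stay
complete. Matching of event terms is exact at the PT level and
case-insensitive; verbatim reaction text is out of scope.

Each composite PT carries one subtype label (generic, recurrent, papillary,
follicular, medullary, anaplastic, metastatic). Two category schemes
consume these labels: the demographic summary keeps the two generic PTs as
their own classes and pools anaplastic/recurrent/metastatic as "other",
while the per-drug histology breakdown uses {medullary, papillary,
metastatic, other} with "other" pooling generic, recurrent, follicular and
anaplastic — the two groupings used in published case-series tables. A
report naming composite PTs of several distinct subtypes contributes one
mention to each, with the denominator equal to total subtype mentions, so
proportions always sum to 1.

## Deduplication

Spontaneous-report cases accrete versions as follow-ups arrive. The screen
keeps, per case identifier, the version with the greatest version key —
FDA's published guidance for FAERS — with a switch to disable collapsing.
Tied (case, version) pairs keep the first occurrence and log a warning.
Probabilistic record linkage across manufacturers is out of scope.

## Ingestion

FAERS-style quarters are "$"-delimited ASCII with a header line; files are
decoded as Latin-1 with replacement because legacy quarters are not clean
UTF-8. Column names are resolved against candidate lists so both modern
(primaryid) and legacy (isr) layouts parse. Lines with the wrong field
count, or missing required fields, are counted and logged, never silently
dropped; a missing file or unparseable header is fatal. The report year
comes from the event date when present, falling back to the receipt date
(which of the two leads is a dialect option, since either choice is
defensible for trend counting). Case versions lacking any drug or any
reaction record are dropped with a logged count — they cannot contribute to
any contingency cell. Ages are banded into 0–11, 12–17, 18–64 and 65–85
years after unit conversion (YR/DEC/MON/WK/DY/HR); missing, negative or
>85-year ages are "unspecified" since no band above 85 is defined.

The internal flat format is three CSVs (reports, report_drugs,
report_events) plus a JSON manifest, with rows and set-valued fields written
in sorted order so the round trip is bit-exact.

## Synthetic databases

The generator emulates the structure of a spontaneous-report database under
a fully specified model so every stage can be tested against known truth:

- Demographics per report are drawn from sex/age-band/country/year
  mixtures. Defaults reflect a thyroid-cancer case series: 63% female,
  most classified ages 18–64, ~45% of ages unspecified, US the single
  largest reporting country, and report volume ramping up over 2004–2024
  with a late surge.
- Each catalogue drug enters a report independently with its marginal
  probability; a background (unmapped) drug is added with probability 0.6,
  and reports that would otherwise name no drug get one, so every report
  names at least one drug. Roles are sampled with suspect roles most
  likely.
- The event is drawn with odds p₀/(1−p₀) scaled by the **maximum**
  reporting-odds multiplier among the report's drugs (1 if none). The max
  — rather than a product — keeps the population ROR of a drug with
  multiplier m exactly m whenever all other multipliers are 1, which is
  what the parameter-recovery and type-I simulations verify. The default
  p₀ ≈ 5.5·10⁻⁴ is the event share observed in the bundled reference
  counts. Event reports draw one subtype PT from a histology mixture
  (generic terms dominating, papillary the most common named subtype);
  non-event reports draw a common background PT.
- With probability 0.05 a case gains one or two exact duplicate versions at
  higher version numbers (a modest rate reflecting that duplication is
  common but a minority phenomenon); injection never changes the distinct
  case count, which is recorded in the ground truth alongside the true
  multipliers.

`reference_screen_config()` builds a catalogue whose marginals are the
observed per-drug report shares of the bundled counts and whose multipliers
are the observed RORs (Haldane-corrected for zero-event drugs). To make
expected event cells measurable at bench scale (n ≈ 50,000 instead of 26
million), the baseline event probability is inflated ×60 and the marginals
only ×3: inflating marginals aggressively makes catalogue drugs co-occur so
often that, under the max-multiplier model, strong signals leak into weak
drugs' event cells and distort the retention pattern. With these factors
the expected pattern of the reference screen survives scaling: the GLP-1
analogues are retained with the largest RORs and the orlistat analogue
falls below the k = 5 threshold.

The generator does **not** emulate: realistic co-prescription structure
(drug entries are independent), free-text drug-name noise beyond
brand/generic/case variants, reporting-bias dynamics (stimulated reporting,
underreporting), within-case demographic revisions across versions, or
multi-event reports. Passing tests therefore demonstrate correctness of
the pipeline's counting and inference under a clean generative model, not
robustness to real-world reporting artifacts.

## Validation problem sizes

The test suite checks: exact reproduction of the bundled reference
statistics through the from-counts path; equality of the single-pass
tabulation with a brute-force double loop on 100 random databases of 50 to
1,000 reports; CI calibration with an embedded multiplier of 4.0 (drug
marginal 0.01, p₀ = 0.001, n = 200,000; 500 replicates; ≥93% of Woolf 95%
CIs cover 4.0) and empirical type-I error with all multipliers 1 (10 drugs,
marginal 0.02, p₀ = 0.02, n = 100,000, 150 replicates; CI excludes 1 at
5% ± 2%) — the type-I configuration uses larger expected cells than the
coverage one so the asymptotic test is evaluated in its intended regime;
threshold behaviour on the sparse tail (a = 0, 1, 2, 4 excluded at k = 5;
a = 7 retained); and the invariant suite (inversion symmetry, p/CI
consistency, stratum-sum conservation, dedup idempotence, seed
determinism), with randomized versions under hypothesis.

## Known limitations

- Disproportionality is relative reporting, not incidence; no causal claim
  is supported, and no multiple-testing correction is applied across the
  drug list (none is conventional for this screen; the flagged signals are
  hypotheses for follow-up).
- Stratified screens recompute totals within the stratum but no formal
  across-stratum heterogeneity test is provided.
- PRR, IC/BCPNN and EBGM-style shrinkage metrics are out of scope.
- The dictionary is a compact curated synonym list, not a licensed MedDRA
  or RxNorm resolution; coverage beyond the screened ingredients is
  deliberately thin.
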