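# rorscreen

Disproportionality screening for spontaneous adverse-event report databases.

Spontaneous-reporting systems such as the FDA Adverse Event Reporting System
(FAERS) collect voluntary case reports of suspected adverse drug reactions.
They have no exposure denominator, so absolute risks are not computable — but
one can ask whether an event is reported *disproportionately often* with a
given drug relative to the rest of the database. `rorscreen` implements this
screen end-to-end for a composite event defined by a set of MedDRA preferred
terms (the packaged defaults target thyroid cancer and its histological
subtypes, screened against weight-loss and anti-diabetic medications): FAERS
quarterly ASCII ingestion, drug-name normalization, case deduplication, the
statistical screen, demographic/stratified summaries, yearly trends, subtype
breakdowns, and a synthetic report generator with known ground truth.

It is intended for pharmacoepidemiologists and methods researchers who want
a reproducible, testable reference pipeline rather than a spreadsheet.

## The statistic

For each drug the deduplicated reports partition into a 2×2 table

|                 | composite event | other events |
|-----------------|-----------------|--------------|
| drug            | a               | b            |
| all other drugs | c               | d            |

with the drug's own reports removed from the comparator row. The reporting
odds ratio and its Woolf (log-normal) interval are

ROR = (a·d)/(b·c),  se = √(1/a + 1/b + 1/c + 1/d),
95% CI = exp(ln ROR ± z₀.₉₇₅·se),

with a two-sided p-value from z = ln ROR / se. A drug contributes in any
role (suspect, concomitant, interacting); drugs with fewer than five
drug–event pairs (a < 5) are excluded, since tiny counts make the ROR
unstable. A ROR is a reporting signal, not a risk estimate.

## Worked example

The package ships drug-level report counts for the composite thyroid-cancer
event from a 2004–2024Q1 FAERS snapshot. The from-counts mode reproduces
the full screen from those counts alone:

```sh
rorscreen screen --from-counts src/rorscreen/data/thyroid_screen_counts.csv \
                 --out-dir out/
```

which writes `out/results.csv` (rounded half-up to 2 decimals below):

```text
            drug   a      b   ror  ci_low  ci_high       p_value  excluded
     semaglutide 124  29401  7.67    6.42     9.15 1.833347e-112     False
     dulaglutide 131  65684  3.62    3.05     4.30  1.368822e-48     False
     liraglutide 316  36562 15.92   14.23    17.81  0.000000e+00     False
     tirzepatide  37  31928  2.09    1.52     2.89  7.262710e-06     False
   empagliflozin  11  30778  0.64    0.36     1.16  1.453796e-01     False
   dapagliflozin   7  12714  0.99    0.47     2.08  9.857985e-01     False
       metformin  17  53172  0.58    0.36     0.93  2.316953e-02     False
     phentermine   0   1427   NaN     NaN      NaN           NaN      True
      naltrexone   2  24375   NaN     NaN      NaN           NaN      True
        orlistat   4  23841   NaN     NaN      NaN           NaN      True
      topiramate  14  34652  0.73    0.43     1.23  2.365023e-01     False
       bupropion   0  17692   NaN     NaN      NaN           NaN      True
    rosuvastatin  12  13890  1.56    0.88     2.75  1.242662e-01     False
       glyburide   1   4617   NaN     NaN      NaN           NaN      True
insulin glargine  63 104510  1.09    0.85     1.39  5.046319e-01     False
```

Reading it: the GLP-1 receptor agonists show strong positive
disproportionality (e.g. liraglutide ROR ≈ 15.9, CI well above 1), the dual
GIP/GLP-1 agonist tirzepatide a modest one (2.09, CI 1.52–2.89), metformin a
weak inverse association (0.58, CI 0.36–0.93, p ≈ 0.02), while topiramate,
dapagliflozin, rosuvastatin and insulin glargine are compatible with no
disproportionality. Drugs with fewer than five event reports carry no
statistics and are flagged excluded.

The same engine runs from raw report files. A fully synthetic database with
known ground truth exercises every stage:

```sh
rorscreen simulate --seed 4 --n 50000 --out-dir sim/
rorscreen screen --demo sim/ascii/DEMO.txt --drug sim/ascii/DRUG.txt \
                 --reac sim/ascii/REAC.txt --out-dir sim_out/
rorscreen trend    --input-dir sim/internal --out-dir trend_out/
rorscreen subtypes --input-dir sim/internal --drug-name liraglutide --out-dir sub_out/
```

From Python, the same pipeline is `rorscreen.generate`,
`rorscreen.deduplicate`, `rorscreen.screen`, `rorscreen.stratified_screen`,
`rorscreen.yearly_trend` and `rorscreen.subtype_breakdown`.

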