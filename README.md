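# dispro

Disproportionality analysis for spontaneous adverse-event reporting
data, built around the workflow used to study lower-limb complications
(amputations, Fournier's gangrene and related necrotizing conditions)
reported for SGLT2-inhibitor antidiabetics in FAERS, the FDA Adverse
Event Reporting System.

It is a library for pharmacovigilance analysts and methods researchers
who need the whole chain as tested, composable pieces:

* **I/O** for the FAERS quarterly ASCII dialect (dollar-delimited DEMO /
  DRUG / REAC / OUTC tables) and a single-file ICSR interchange CSV;
* **vocabularies** — exact (non-fuzzy) free-text drug-name normalization
  to USAN-style generics via a bundled synonym dictionary (brands and
  fixed-dose combinations included), the closed 12-term event list,
  country→region and outcome-code→category maps;
* **case processing** — consolidation of report versions into cases
  (union of drug–event relationships across versions, demographics from
  the latest version) and inclusion filtering (date window, primary-
  suspect role, event list);
* **disproportionality** — 2×2 contingency construction and the
  reporting odds ratio with a log-scale Wald CI;
* **descriptive summaries** — per-drug demographic/outcome/region/year/
  event tables and year trends with exact half-up percentage rounding;
* **a synthetic report generator** whose drug–event association
  strengths are designed directly on the odds-ratio scale, so every
  stage can be validated end to end against known ground truth.

## The statistic

For a drug–event pair, cases are cross-classified as

|                | event | no event |
|----------------|-------|----------|
| drug (suspect) | a     | b        |
| all other drugs| c     | d        |

and the reporting odds ratio is

    ROR = (a·d) / (b·c),   95% CI = exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) ).

If any cell is zero, 0.5 is added to all four cells
(Haldane–Anscombe) and the correction is recorded. A pair is flagged as
a signal when ROR > 2.00 **and** the lower CI bound > 1.00 (strict
inequalities). The analysis unit is the consolidated case; a
report-version unit is available as a configuration switch.

## Worked example

Recover a designed odds ratio through the full pipeline
(`examples/designed_odds_ratio_recovery.py`):

```
$ python examples/designed_odds_ratio_recovery.py
2x2 table: a=178 b=1863 c=192 d=17767
designed odds ratio: 10.0
estimated ROR: 8.84  (95% CI 7.17 - 10.90)
```

The generator multiplied the baseline odds of the event by θ = 10 for
exposed cases; after consolidation, filtering and 2×2 construction the
estimated ROR is 8.84 with a 95% CI that covers the design value — on
repeated seeds the CI covers θ in ≈95% of runs (that calibration is an
automated test).

Screen a study-shaped synthetic universe
(`examples/screen_synthetic_reports.py`):

```
$ python examples/screen_synthetic_reports.py
report versions: 646  cases: 500
included: 159  background: 320  out of window: 21

signalled drug-event pairs (a = exposed cases with the event; CI is the 95% Wald interval):
         drug               event  a   ror  ci_low  ci_high
canagliflozin          Amputation 47 36.74   14.18    95.14
canagliflozin      Toe amputation 47  9.81    5.43    17.75
canagliflozin       Diabetic foot 19  5.02    2.32    10.86
canagliflozin       Osteomyelitis 23 14.09    5.23    37.94
empagliflozin Fournier's gangrene 32  9.88    5.45    17.91
ertugliflozin        Gas gangrene  1 23.30    1.95   278.47
ertugliflozin       Diabetic foot  2 32.00    2.82   363.71
```

The 500-case fixture was designed with strong canagliflozin
associations for amputation-type events and an empagliflozin
association for Fournier's gangrene; the screen recovers them. The two
ertugliflozin rows show why sparse drugs need care: with one or two
exposed cases the Haldane-corrected ROR is huge but its interval is
nearly unbounded.

`examples/descriptive_table.py` prints the per-drug descriptive block
(sex, outcome severity, region, year, events) with counts and
percentages.

The same pipeline is scriptable from the shell:

```bash
dispro generate --seed 7 --out data/          # synthetic universe, both dialects
dispro run --config run.yaml --out results/   # ingest → consolidate → screen → summarize
dispro summarize --in data/icsr.csv --out tables/
```

`dispro run` writes `results.csv`, `forest.csv` (plot-ready), the
descriptive `summary.csv`, `year_trend.csv`, `exclusions.csv`, a config
echo and a stage-count log.

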