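# Methods

## Data model and scope

The package analyses spontaneous adverse-event reports in the shape
used by FAERS: an individual case safety report (ICSR) identified by a
case id, submitted as one or more versions (follow-ups), each version
carrying demographics (age, sex, reporter country, receipt date), drug
mentions with a role code (primary suspect PS, secondary suspect SS,
concomitant C, interacting I), reaction preferred terms (PTs), and
outcome codes (DE, LT, HO, DS, CA, RI, OT). PTs are treated as flat
labels; no MedDRA hierarchy is used. The THER/INDI/RPSR tables and E2B
XML are out of scope.

Receipt dates may be partial (`yyyymm00`, `yyyy0000`); they are
truncated to the first valid day and the precision is kept on the row,
which is sufficient for year-level trends. Ages are normalised to years
(MON/12, DY/365.25). Invalid dates are never silently coerced: strict
parsing raises, lenient parsing flags the date missing.

## Case consolidation

The analysis unit is the consolidated case. Demographics and the
receipt date come from the version with the highest `case_version`,
ties broken by latest receipt date, then lexicographically greatest
`primary_id` — a fixed chain so output is deterministic under any input
order. Drug–event relationships are accumulated by union: a case
carries a (generic drug, event term) pair if the drug (in a configured
suspect role, default PS) and the event co-occur in at least one
version. A follow-up that drops an event therefore never removes a
pair, and consolidation is idempotent and monotone under new versions.

Where a report-level convention is preferred (reporting systems and
publications are not consistent about the counting unit), `unit:
version` treats each version as its own case; the default is the
stricter case unit.

When a case carries several outcome codes across versions it is
assigned one category by severity precedence Death > Life-threatening >
Disability > Hospitalization > Other medical events. Published
per-drug outcome percentages sum to ≈100%, implying one category per
case, but no precedence rule is published; most-severe-wins is this
package's choice and is configurable only by recategorising upstream.

## Drug-name normalization

Matching is exact after lower-casing, whitespace collapsing and
apostrophe unification. The bundled dictionary covers the eight
SGLT2-inhibitor generics (canagliflozin, dapagliflozin, empagliflozin,
ertugliflozin, ipragliflozin, tofogliflozin, luseogliflozin,
remogliflozin), their major brands, and fixed-dose combinations; a
combination resolves to all of its constituents, and exposure to any
constituent counts as exposure to that generic. There is deliberately
no fuzzy matching: edit-distance rescue of typos would change counts
silently and unauditably. Unmatched mentions simply do not define
exposure — their reports still populate the background.

## Inclusion filtering

Included cases have (i) receipt date on or after the window start
(default 2013-03-29, the class's first US approval), (ii) at least one
drug of interest in a suspect role, and (iii) at least one event from
the closed 12-term list (Fournier's gangrene, cellulitis gangrenous,
diabetic gangrene, gas gangrene, dry gangrene, amputation, leg/foot/
limb/toe amputation, diabetic foot, osteomyelitis). All other in-window
cases — including cases with no drug rows at all — form the background
that populates cells c and d. Cases before the window, or with no
usable date, are excluded from both sides. Each case is logged under
exactly one disposition reason so the exclusion log reconciles with the
input count.

## Disproportionality

For each pair, `a` counts cases whose pair set contains (drug, event),
`a + b` counts all cases with the drug in a suspect role, `c` the event
among the remaining cases, `d` the rest; the four cells always sum to
the case universe. ROR = ad/(bc) with the Wald interval
`exp(ln ROR ± z₁₋α/₂·√(1/a+1/b+1/c+1/d))`, α = 0.05 by default
(z from the normal quantile, 1.959964, not a rounded 1.96). The CI
method is the standard spontaneous-reporting convention. If any cell is
zero, 0.5 is added to all four cells (Haldane–Anscombe) and
`correction_applied` is recorded; all-positive tables are never
touched. A drug with no exposed case cannot form a table; in batch
screening such pairs are reported with a `no_exposure` status instead
of raising.

The signal rule is ROR > 2.00 and lower CI bound > 1.00, both strict,
evaluated per pair with no multiplicity adjustment (a Bonferroni hook
exists for users who want one; it divides α by the grid size).

## Descriptive summaries

Percentages are computed with exact decimal arithmetic and rounded
half-up to one decimal. Sex, outcome, region and year blocks partition
the drug's cases (missing values go to an explicit Unknown label) and
so sum to 100 ± rounding; the event block counts cases per term and may
exceed the case count because multiple listed events co-occur. Age is
mean (SD) over cases with known age, displayed integer-rounded. The
year trend reports counts per calendar year with percent of the drug's
total, optionally restricted to one reporter country.

The bundled reference table of published descriptive counts is used by
the validation suite to confirm the rounding convention: every printed
percentage is recomputed from its printed count. That exercise showed
the published region block uses the block's own column sum (which
exceeds the case totals) as denominator, and identified nine cells that
do not reconcile with their own counts under any standard rounding
(documented with reasons in `dispro/reference.py`); those cells are
excluded from the exact-match check.

## Synthetic data generator

The generator emulates the study conditions rather than any particular
quarter of real data: multi-version cases (configurable follow-up rate;
a follow-up may drop an event, exercising union semantics), one
primary-suspect drug per case by default (keeps ground-truth 2×2
attribution unambiguous), free-text names drawn from each drug's
synonym pool with a configurable typo rate producing dictionary misses,
filler PTs outside the event list, outcome codes, sex/age/country/date
distributions, and background suspect drugs for unexposed cases.

Associations are designed on the odds-ratio scale: an exposed case's
event probability is `p* = θ·odds₀ / (1 + θ·odds₀)` with
`odds₀ = p₀/(1−p₀)`. Because the multiplication is on odds, the
case-level cross-product ratio equals θ exactly at any baseline rate —
the designed parameter is precisely the estimand of the ROR. The
ground-truth object records θ and the realized exposure/event
indicators, from which the true 2×2 of any pair can be reconstructed.

Defaults: receipt dates uniform over 2013-04-01..2024-12-31, sex
M/F/UNK = 0.62/0.35/0.03, age ~ Normal(58, 10) clipped to 18–95,
reporter countries dominated by the US (0.70), outcome codes weighted
toward hospitalization — all chosen to resemble the demographic profile
of the studied reports (predominantly older US males). The ~500-case
study-shaped fixture uses four drugs with strongly unequal exposure
(canagliflozin ≫ empagliflozin > dapagliflozin ≫ ertugliflozin), strong
designed associations for the events the class is known for, a 30%
follow-up rate, 5% typo rate, and a date window starting 2012-06-01 so
out-of-window exclusion always has work.

What the generator does **not** emulate: stimulated reporting and
notoriety waves, duplicate cases under different case ids (probabilistic
record linkage is out of scope), missing-not-at-random demographics,
country-specific reporting cultures, or correlated event co-occurrence
beyond what shared exposure induces. Passing calibration tests
therefore demonstrates correctness of the machinery under the designed
model, not robustness to every real-world reporting bias.

## Calibration checks

Two frequentist checks run the generator's universes through the whole
pipeline (generate → consolidate → filter → 2×2 → ROR):

* **Null coverage** — θ = 1, n = 5000 cases per replicate, 200
  replicates, exposure 0.15 and baseline 0.08 (sizes chosen for
  all-positive expected cells, a ≈ 60, where the Wald interval is
  calibrated): the 95% CI should cover 1 in 92.5–97.5% of replicates.
* **Parameter recovery** — θ = 10, exposure 0.1, baseline 0.01,
  n = 20,000, 50 replicates: the median estimated ROR should fall
  within the binomial sampling bounds [8.5, 11.8].

Both simulation designs set the typo rate and follow-up rate to zero so
the designed θ is exactly the estimand — name noise would misclassify
exposed cases into the background and attenuate the ROR toward the
null, which is a property of dirty data, not of the estimator.

## Numerical choices and degenerate inputs

* Exact `Fraction`/`Decimal` arithmetic is used in tests and rounding,
  floating point in the estimator; agreement is verified to 1e-12
  relative error over random tables.
* Empty inputs: an empty case list filters to empty outputs with a
  warning; a drug subset with zero cases yields an empty summary with
  no percentages; header-only files parse to an empty report set.
* The dollar-delimited dialect has no escaping; a literal `$` in
  content is a write error rather than a corrupt file.
* Determinism: generator output is a pure function of its config
  (single seeded RNG), writers sort rows canonically, and the screen
  iterates the drug and event lists in their given order, so repeated
  runs are byte-identical.

## Known limitations

ROR is a reporting-disproportionality measure, not a risk estimate: it
has no denominator of drug exposure and inherits every bias of
spontaneous reporting. The pipeline deliberately implements only the
documented cleaning steps (deduplication by case id, exact name
normalization, role and window filters); upstream extraction tools
apply further undocumented cleaning, so absolute counts from real
extracts will differ between toolchains even on identical quarters.
Interchange-CSV round trips are exact for reports with at least one
drug and one reaction; ages pass through the interchange format in
years only.
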