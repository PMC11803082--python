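# Methods

This note records the models, rules and numerical choices behind
`abxdemog`, and what its synthetic-data validation does and does not
establish about real prescription extracts.

## Data model and ingest

The unit of data is a disaggregated cell: items dispensed in one
calendar month for one drug, age band, sex and region. Age follows the
closed 23-band scheme "0–1", "2–5", then 5-year bands to "105+".
The published labels "101–105" and "105+" share the endpoint 105; band
membership resolves to the lower band there, so the open band holds ages
106+ in practice. Counts below 5 arrive redacted ("*", true value 1–4).

Exclusions mirror standard practice for this kind of extract, applied in
order: unknown age band or sex; indeterminate sex; then drugs whose mean
items per complete calendar year (2016–2023 by default; the first and
last source years are partial) fall below 10, with redacted cells
counted at the configured imputation value. Demographic exclusions run
before the rare-drug rule, so a drug's annual mean is computed over the
population actually analysed. Rejected rows (malformed counts, bad
periods) are returned with reasons, never silently dropped —
FOI-style extracts deserve an audit trail.

Redaction imputation substitutes a fixed value v ∈ {1,2,3,4} inside a
scope (everyone / males only / children only, the last meaning bands
wholly under 20, i.e. "0–1"–"16–20"); out-of-scope redactions take the
study default of 1. Totals are therefore non-decreasing in v, and the
true total always lies in [total(1), total(4)] — both properties are
tested on suppressed synthetic data.

## Rates

rate = items / population × 100,000. The ONS-style mid-year estimate of
a calendar year serves every month of that year. When a stratification
has no time dimension but the records span several years, the
denominator is person-years (sum of the yearly populations); this is the
only choice under which collapsing sub-strata commutes with rate
computation, which the tests assert. Sex contrasts use the natural log
of the female:male rate ratio; a single zero rate yields ±∞ with the
majority set by the nonzero side, and both-zero cells are flagged and
excluded from majority summaries.

## Seasonality rule

For each drug, the monthly profile is the mean of national item totals
per calendar month over the pre-COVID window (data start to February
2020; the COVID window is March 2020 – June 2022 inclusive). The
overall mean is the mean of the 12 month-means — insensitive to years
contributing unequal month counts; a switch selects the raw all-months
mean instead. A drug is seasonal when ≥ 2 months sit at or ≥ 1.2 × the
overall mean (the threshold is inclusive; boundary cases are otherwise
ambiguous). The rule is scale-invariant and monotone in the threshold,
both tested. On synthetic drugs with amplitude 0.5 on two winter months
versus amplitude 0, at ≥ 10,000 mean monthly items, classification is
exact (sensitivity = specificity = 1.0 over 100 drugs); weaker
amplitudes or sparser drugs are *not* guaranteed and were not a design
target.

## UCM weighting

Weights are per-capita rates relative to females 66–70 (the closest
5-year subset of the classic STAR-PU 65–74 female baseline), computed
from national data of a single reference year (2023 by default) —
pooling regions for stability, as STAR-PU practice does; a per-region
weighting mode is deliberately absent. Family weightings restrict the
numerator to one BNF family. Choices:

- clamp bounds [0.01, 100] apply to overall and family weights alike
  (they are inert for well-populated cells);
- child bands (lower bound < 16, i.e. "0–1"–"16–20") with zero items
  take 0.01; a zero-item adult cell is an error unless clamping is
  explicitly enabled, since it usually signals a data problem;
- the baseline weight is set to exactly 1.0 after the division, so
  float rounding never perturbs it;
- region ranking is descending by metric with ties broken by ascending
  region code (deterministic output); colour groups are 10/10/10/12 at
  42 regions, proportional cuts otherwise.

The metric (items per weighted person) is invariant to jointly scaling a
region's population and items, so equal-rate-structure regions of
different sizes compare as equal — the property that motivates weighting
in the first place.

## AWaRe targets

The packaged reference table carries WHO AWaRe categories for the
antibiotics commonly seen in these extracts, plus an override file
mapping source-name variants (salt suffixes, UK names such as
"Penicillin V") to reference names; matching is case- and
whitespace-insensitive, exact name first, then override, else
Unclassified. Unclassified drugs stay in the share denominator — the
targets are fractions of total consumption, and dropping unmatched
drugs would inflate the Access share (a configurable choice, default as
stated). Shares are item-weighted; target flags test Access ≥ 60/70/80%.

## Influenza-season analysis

RTI prescribing is proxied by the penicillins and cephalosporins/other
β-lactams families, excluding amoxicillin (volume and breadth of
indications). A season is 1 October – 30 March; at monthly resolution
March is included whole (the one-day boundary only bites with daily
data). Season rates divide a group's season items by its population in
the year containing October. Analysis groups sum canonical bands; the
"5–10" vaccination group maps to band "6–10", an unavoidable edge
mismatch noted here once. relative_rate divides by the 15–50 group
(exactly 1 there by construction); prop_change compares a group's rate
to its own previous season, undefined for the first. Seasons whose
October-year population is missing from the denominator table are
dropped rather than erroring, since a data window usually truncates
mid-season. No causal estimator is fitted; the output is descriptive.

## Headline summaries

Drugs are ranked by total items over complete years. mean_annual =
total / n_years rounded **half-to-even** — this reproduces the reference
table's printed values exactly (e.g. 9,181,476 / 8 = 1,147,684.5 prints
as 1,147,684), where half-away-from-zero does not. The top month
maximises items summed over the *whole* dataset (ties to the earliest
month). Female-majority supports two rules: printed-percentage ≥ 50
(matches how a rounded 50% is reported as majority) and raw share
strictly > ½; the headline counts default to the former. Top age bands
per sex are the three highest 2023 rates, descending.

## Sensitivity scan

For each (imputation value, scope) — always including the baseline
(1, all) — the scan recomputes per-drug, per-band sex majorities on
per-capita rates and reports the fraction of drugs female-majority in
≥ 50/75/90% of their bands. Bands where both sexes have zero items are
excluded from a drug's band denominator (an undefined comparison should
not count against female majority). The three fractions are nested by
construction, and the band-level majorities agree exactly with the rates
module at the baseline.

## Synthetic generator

The generator is the test instrument: it reproduces the statistical
structure the analysis assumes, not the real data's marginals. Each
stratum's monthly count is Poisson (optionally negative-binomial with
size 5, since real dispersion is unknown and tests must hold under
both) with mean

base_rate/10⁵ × age_profile(band) × sex_factor × seasonal × region ×
covid × shifts × population,

where sex factors 2r/(1+r) (F) and 2/(1+r) (M) give female:male rate
ratio r while keeping the pooled rate at base_rate; the seasonal
multiplier is 1 + amplitude in peak months; the COVID dip (default 0.7)
applies inside March 2020 – June 2022; and optional rate shifts multiply
chosen bands from a period onward (used to inject vaccination-like
drops). Populations are deterministic England-shaped per-sex band
counts with a female excess at 76+, split across regions by size
multiplier. Suppression replaces counts below 5 with the redaction
marker; zero-count strata are simply absent, never redacted.

Defaults emulate the study conditions: 20 drugs named and shaped like
the most-prescribed English antibiotics (winter-seasonal respiratory
penicillins/macrolides, strongly female urinary drugs with ratios up to
4.5, a male-skewed quinolone, AWaRe categories matching the packaged WHO
map, ~81% Access by expected volume), 42 equal-size regions with a ±15%
prescribing spread, and 24 months (2022–2023) so the full pipeline runs
in well under a minute. The generator does **not** emulate: practice-
level structure, drug shortages or outbreak spikes, time-varying
completeness of demographic recording, or correlation between drugs —
so passing tests show the *methods* recover known structure, not that
real English prescribing has that structure.

Recovery checks in the suite and acceptance script use deliberately
sized problems: 100 drugs × 36 pre-COVID months for the classifier;
one drug at 9,000 items/100k/month for ≥ 10⁵ expected items per
age-sex cell in the UCM check (2% relative tolerance); twin regions at
500 items/100k/month for the +20% ranking check; three 6-month
low-rate fixtures for the imputation bracket; and a −10% shift on one
band over five seasons for the flu check (±2 percentage points).

## Known limitations

- Items are the only consumption unit; no DDDs, grams or duration.
- The rule-based seasonality classifier has no significance test; it is
  a reporting convention, not an inference.
- UCM weights inherit STAR-PU's flaws (no comorbidity adjustment;
  grouping all antibiotics masks family-level variation — the
  UCM-family mode exists precisely to expose that).
- The vaccination analysis is ecological and descriptive; the package
  deliberately offers no causal estimator for it.
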