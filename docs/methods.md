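# Methods

## Scope and data model

`pvsignal` implements frequentist signal detection for spontaneous
adverse-event reporting systems (SRS) of the FAERS family.  An SRS has no
denominator of drug users: reports arrive voluntarily, cases recur across
quarterly releases as follow-up versions, dates can be partial, and a report
may carry several drugs, several MedDRA preferred terms (PTs) and several
outcome codes.  The package therefore works on *reports*, not patients, and
all statistics below are reporting statistics, not incidence estimates.

The six quarterly tables (DEMO, DRUG, REAC, OUTC, THER, INDI) are read from
`$`-delimited ASCII with case-insensitive headers.  Malformed data lines
(wrong field count) are counted and dropped; a missing mandatory column
(PRIMARYID everywhere, CASEID in DEMO) is a hard error.

### Deduplication

One record per CASEID is kept: the maximal (FDA_DT, PRIMARYID) pair, i.e.
the most recent FDA receipt date, ties broken by the higher PRIMARYID.
This is the standard FDA-recommended rule for collapsing follow-up
versions.  Sort keys are numeric when every value in the column parses as a
number, otherwise lexicographic.  The operation is idempotent, and the
output size equals the number of distinct CASEIDs.

### Cohort construction

A report belongs to the target cohort when at least one DRUG record has the
requested role code (default PS, primary suspect) and its DRUGNAME or
PROD_AI contains any configured synonym (case-insensitive substring by
default, since FAERS verbatim drug names carry dose and formulation
suffixes; exact matching is available).  Everything else is background, so
target and background partition the deduplicated database — the background
is the whole remaining database, the conventional comparator for
disproportionality.

A reporter-occupation filter is available but **off by default**: empirical
SRS data always contain consumer reports, and restricting to healthcare
professionals is a sensitivity analysis rather than a default.  Date-range
and indication information are carried on each case for the same reason.

### Ages and dates

AGE_COD units are converted to years (DEC ×10, YR ×1, MON /12, WK /52.18,
DY /365.25, HR /8766); a present age without a unit is assumed to be years
(logged), negative ages become missing.  Dates are digit strings: 8 digits
is day precision, 6 is month, 4 is year.  Partial dates are *retained* for
year-level descriptives but *excluded* from time-to-onset, which needs day
precision — imputing within-month onset times would fabricate resolution.

### MedDRA

MedDRA is licensed and is never bundled.  SOC-level analysis takes a
user-supplied 2-column TSV (`pt<TAB>soc`, primary SOC only).  Lookups are
case-insensitive after whitespace normalization; unmapped PTs accumulate in
an audit list and are excluded from SOC aggregation while remaining in the
PT-level analysis, which does not need the dictionary.

## Disproportionality statistics

For a term *t* the four-fold table over the deduplicated database is

|              | event *t* | other events |
|--------------|-----------|--------------|
| target drug  | a         | b            |
| other drugs  | c         | d            |

* **ROR** = ad/bc, 95% CI = exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))
  (Woolf interval).
* **PRR** = [a/(a+b)] / [c/(c+d)],
  95% CI = exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).
* **χ²**: Pearson statistic with 1 df, expected counts from the fixed
  margins (E(a) = (a+b)(a+c)/N, …), computed on raw counts.  Yates
  continuity correction is exposed as a flag and off by default.

Both CIs are symmetric on the log scale, so the geometric mean of the
bounds reproduces the point estimate — a useful internal-consistency check
for any published table of RORs with CIs.

**Signal rule.**  With at least `min_a` = 3 reports: ROR branch fires when
the CI lower bound is strictly above 1; PRR branch when PRR ≥ 2 *and*
χ² ≥ 4 (both inclusive, the ROR bound strict — exactly as conventionally
printed).  A term is a signal when either branch fires.  Undefined
statistics never fire.

**Zero cells.**  Default policy is Haldane–Anscombe: when any cell is 0,
add 0.5 to all four cells for estimation and CI (flagged on the result);
`skip` instead marks the statistic undefined.  χ² always uses raw counts.

**Counting unit.**  `report` (default): a is the number of target reports
mentioning the term, b the rest of the cohort — Σa over terms can exceed
the cohort size but each term's table is a partition of reports.  `event`:
b and d count remaining (report, term) mentions instead.  SRS publications
are often ambiguous about this; the unit is recorded in every result and in
the run manifest.  The percentage column always divides the report count by
the total number of event mentions in the target cohort, which is how
"share of all AEs" is conventionally quoted.

**SOC aggregation** maps each report's PT set to a SOC set, so a report
contributes each SOC at most once and a never exceeds the cohort size.

**Ranking** restricts to flagged signals: by frequency (descending a, ties
by descending ROR, then term) or by strength (descending ROR, ties by
descending a, then term).  **Label comparison** flags each term as
listed/unlisted against a user-supplied label PT list (case-insensitive)
and counts unlisted terms within any top-k slice.

## Time-to-onset

TTO = event date − earliest day-precision therapy start among THER records
linked (via the drug sequence number) to a matching suspect drug, in days.
Exclusions are counted by reason: partial/missing event date, no linked
day-precision start, non-positive latency.

The latency sample is summarized by median, quartiles (linear interpolation
between order statistics — the convention is recorded in output metadata),
min and max, and fitted with a two-parameter Weibull by maximum likelihood
(scale α in days, shape β), via the scipy optimizer with location fixed at
zero.  **No censoring model** is used: spontaneous reports carry no
risk-set denominator, so only observed events enter — the fit describes the
reported latencies, not a hazard in a defined population.  95% CIs come
from the observed Fisher information on (ln α, ln β) (central-difference
Hessian of the negative log-likelihood, normal approximation on the log
scale).  Fits with fewer than 20 observations are refused (indeterminate).

**Failure classification** from β and its CI: CI containing 1 → *random*
(constant hazard); β < 1 with the CI entirely below 1 → *early* failure
(decreasing hazard: events concentrate shortly after treatment start);
β > 1 with the CI above 1 → *wear-out*; anything else indeterminate.

**Onset bins** are right-closed intervals over days 30/60/90/180/360 by
default ([1,30], [31,60], …, (360,∞)), configurable; percentages are over
the TTO sample size and sum to 100 up to rounding.

## Descriptives

Sex, age bins ([0,18), [18,60), [60,85], (85,∞) — the boundary value 85.0
falls in the 60–85 bin), reporter occupation (MD/OT/PH/CN, everything else
pooled as "other groups"), top-k countries (rest pooled), outcomes, and
reports per year.  A report's multiple outcome codes are collapsed to the
most severe before tabulation.  Only "death first" is canonical; the full
default order DE > LT > DS > RI > HO > CA > OT is a documented,
configurable convention, and missing values always form an explicit NA row
so every block sums to the cohort size.  Percentages are printed at one
decimal.

## Synthetic generator

The generator emulates the *structure* of FAERS quarters, not real term
frequencies: planted drug–event associations with known effect sizes,
background PTs, duplicate CASEIDs re-emitted under a later PRIMARYID (20%
with an identical FDA_DT to exercise the tie-break), partial (YYYYMM) and
missing event dates, demographic/outcome mixes, and Weibull onset
latencies.

Planted associations are parameterized as a **true reporting odds ratio**:
target reports carry the event with probability p₁ = odds₁/(1+odds₁),
odds₁ = ROR_true · p₀/(1−p₀), background with p₀.  The population odds
ratio of the report-level table then equals ROR_true exactly, which makes
CI-coverage tests exact in expectation (a risk-ratio parameterization would
not be).  Infeasible configurations (p₁ ≥ 1) are rejected by name.

Defaults describe the emulated study conditions — an elderly,
Japan-dominated antiplatelet cohort: 20,000 reports, 5% target-drug
fraction, sex mix M 55.9% / F 31.1% / missing 13%, ages concentrated at
60–85, occupation and outcome mixes matching typical SRS tabulations,
onset Weibull(α = 162.3 days, β = 0.61) (an early-failure profile), 5%
duplicate rate, 10% partial + 5% missing event dates.  The strongest
planted signal (true ROR 8 at p₀ = 0.005) yields expected a ≈ 39 ≥ 30,
the regime where the Woolf CI's nominal coverage holds.  One planted term
has true ROR = 1 as a negative control.

Onset days are discretized by **ceiling** to ≥ 1 day (report dates have day
resolution, and observed latencies start at one day).  At this α/β about
4.5% of the continuous mass lies below one day, so ceiling lumps a visible
atom at day 1 and biases a refitted shape upward by ≈ +0.02–0.04 at
n ≈ 1000.  Distribution tests therefore either de-discretize with a
uniform jitter or use the continuous latencies stored in the ground truth.

What the generator does **not** model: real MedDRA term frequencies, drug
co-prescription structure, reporting waves, stimulated reporting, or
country-specific coding habits.  Passing tests demonstrate that the
statistics, plumbing and thresholds are correct and well-calibrated under
a known data-generating process — not that any particular real-world
signal is causal or that real FAERS counts will be reproduced.

## Pipeline determinism and numerics

A run is deterministic given config + inputs: the single seed feeds only
the generator (all analysis stages are closed-form or deterministic MLE),
outputs carry no timestamps, and the manifest hashes the analysis-relevant
config (the output directory is excluded).  Per-stage record counts and
TTO exclusion reasons in the manifest make the report-flow chart
reconstructible.  TSV outputs render numbers at two decimals (one for
descriptive percentages); a JSON companion file preserves full precision.

Problem sizes used in the test suite and acceptance script (3,000–20,000
synthetic reports, 100–200 replicates for coverage, n = 1090 for the
Weibull operating point) were chosen as the smallest sizes at which the
asymptotic approximations under test are expected to hold.

## Known limitations

* Disproportionality quantifies reporting imbalance, not risk; no
  multiplicity correction is applied (none is conventional for exploratory
  SRS screens), so expect false positives among weak signals.
* The Weibull fit ignores truncation by the reporting horizon and
  left-censoring of long latencies; β is descriptive of reported latencies.
* Substring drug matching can over-match (e.g. a synonym contained in an
  unrelated verbatim name); use exact mode with a curated synonym list for
  production screens.
* The event-mention counting unit double-counts reports across terms in
  b/d; it is provided for comparability with publications that use
  mention denominators, with the unit recorded in the output.
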