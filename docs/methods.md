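# Methods

## Scope and data model

`qcrisk` operates on three observational inputs for one treatment machine:
a QC measurement log (dated deviations of each monitored parameter, in the
parameter's tolerance unit), a service log (failure onset / discovery /
repair dates, with a flag for whether the QC test itself caught the
failure), and a dose-metric table (per patient, per QC item, per candidate
test interval: the magnitude of the dose perturbation a tolerance-level
error would cause, as ΔPTV-coverage in percentage points and Δmax-cord dose
in cGy). Dose metrics are produced externally by a treatment planning
system; the package performs no dose calculation.

All dates are calendar dates and every duration is a whole-day date
difference. The estimators are therefore independent of any site's duty
calendar; a site that wants "operating days" semantics simply supplies logs
indexed on consecutive operating days, which is what the bundled simulator
does. The observation period defaults to the QC-log span (first to last
measurement, inclusive) and is never derived from a month-counting formula.

## Ranking scales

Severity, occurrence, and detection quantities are mapped to integer ranks
1–10 by tables of nine inclusive upper bounds (rank 10 is anything above
the ninth bound; an exact boundary takes the lower rank). The built-in
scales follow the TG-100 convention:

| rank | ΔPTV (%) ≤ | Δcord (cGy) ≤ | O (%) ≤ | D (%) ≤ |
|------|-----------|---------------|---------|---------|
| 1    | 1         | 45            | 0.01    | 0.01    |
| 2    | 2         | 90            | 0.02    | 0.2     |
| 3    | 3         | 135           | 0.05    | 0.5     |
| 4    | 4         | 180           | 0.1     | 1       |
| 5    | 5         | 225           | 0.2     | 2       |
| 6    | 10        | 450           | 0.5     | 5       |
| 7    | 15        | 675           | 1       | 10      |
| 8    | 20        | 900           | 2       | 15      |
| 9    | 50        | 2250          | 5       | 20      |

An item whose record contains no failure at all receives occurrence rank 2,
never 1: a finite clean record cannot support the ≤0.01% failure-time claim
of rank 1. The tables are package constants but can be overridden for other
guideline scales.

## Estimators

**Occurrence.** A failing QC measurement holds the "failed" state from its
date until the next passing measurement of that item or the covering
repair, whichever is earlier; each calendar day counts once, and the
quantity is the failed-day count over the observation period, in percent.
The state-holding rule is a design choice (the time-ratio definition of O
does not itself say how long a failing record "lasts"); it is validated
against a brute-force day-by-day walk in the test suite.

**Detection.** Each failure the QC test missed contributes half the days
between the missing QC test and the discovery — the expected undetected
duration if the true onset is uniform over that gap. Failures caught by the
QC test itself contribute zero. The denominator is the same observation
period used for occurrence, which keeps O and D commensurable for the
E = O/D metric. D can be computed once per item (default) or per interval;
the result type carries an optional interval tag for the latter.

**Severity.** Per patient, the ΔPTV and Δcord quantities are ranked
separately and combined by the configurable `aggregation`: the default
`max_of_criteria` takes the worse of the two (conservative; the two-column
scale does not dictate a combination rule), with `ptv_only` / `cord_only`
for sensitivity analysis. Cohort pooling is `mean_of_ranks` by default —
the mean of per-patient combined ranks, which is why severity indices are
generally fractional (e.g. 2.950) — with `rank_of_means` (rank the
cohort-mean quantities) available because the narrative description of the
method reads either way.

**Integer profiles.** The fractional severity index is rounded to an
integer rank by the configurable `rounding`: `nearest` (default, half away
from zero), `floor`, or `ceiling`. A rounded rank outside 1–10 is clamped
with a logged warning.

## Risk matrix and recommendation

The 10×10 severity × occurrence matrix uses three ordered levels
(low/green < medium/yellow < high/red) with these band rules, applied in
precedence order:

1. S = 1 → low;
2. O = 1 → medium if S ∈ {9, 10} (catastrophic-if-it-happens exception),
   else low;
3. S ∈ 2–5: O+S ∈ [9, 10] → medium, O+S ∈ [11, 15] → high, else low;
4. S ∈ 6–10: O+S ∈ [9, 11] → medium, O+S ∈ [12, 20] → high, else low.

The clauses are stated independently in the source material; this
precedence (S = 1 before the O = 1 exception, both before the band sums) is
the only ordering consistent with all of them simultaneously. Enumerating
all 100 cells gives 32 low, 19 medium, 49 high; the matrix is monotone
non-decreasing in both S and O.

For one item, the failure modes across the interval grid share a single O
rank and are scanned from the shortest interval upward:

- the first **medium** interval is recommended (`first_medium`);
- if all intervals are low, the longest is recommended
  (`longest_all_low`);
- if a **high** interval appears before any medium one, the longest
  interval before it is recommended (`last_before_high`);
- high risk already at the shortest tested interval is an error: the item
  needs escalation beyond the grid (e.g. more than daily testing).

The two fallbacks extend the published first-medium rule to sequences it
does not cover, preserving its logic of "largest interval with acceptable
risk". Non-monotone level sequences (possible with noisy severity means)
are processed by scan order alone, with a warning.

### Rounding caveat

With `nearest` rounding the recommendation pipeline reproduces five of the
six reference recommendations computed from the published per-interval
severity means (weekly, bimonthly, bimonthly, monthly, triweekly for items
1, 2, 3, 4, 6). Item 5 (radiation isocenter size, mean 6.556 at D14) rounds
to S = 7, making O+S = 9 medium at D14 where the published choice is D21;
`floor` rounding fixes item 5 but breaks item 1 (2.950 → 2 is low at D7).
No single rounding convention reproduces all six, so the discrepancy is
documented rather than patched, and `rounding` is exposed as an analysis
option.

## Schedule evaluation

E = O_rank / D_rank. Verdicts between a new and an old schedule are decided
exactly by cross-multiplying the integer ranks; reported E values are
rounded half-away-from-zero to two decimals (2/6 → 0.33, 2/7 → 0.29). E is
computed from ranks, not raw quantities, matching how the metric is tabled;
the raw quantities remain available on the estimator results for
sensitivity analysis.

## Synthetic data generator

The simulator emulates the data-generating reality behind the records so
estimators can be validated against exhaustive ground truth:

- **Failure arrivals** are memoryless: each item fails on a healthy day
  with probability `rate / 240`, where the rate is quoted per operating
  year of 240 days (20 working days × 12 months). Day *i* of the
  simulation maps to `start_date + i`, i.e. a consecutive run of operating
  days, so date differences equal operating-day counts and the estimator
  denominators are unambiguous.
- **Failure lifecycle:** once failed, the true deviation exceeds tolerance
  until repair. A QC test (every `qc_interval_days`) flags a true
  exceedance with probability `detection_sensitivity`; a missed failure is
  recorded as a clean-looking measurement and is discovered by service
  staff `service_delay_days` after onset (or by a later QC test, whichever
  comes first). Repair completes `repair_delay_days` after discovery.
  Scripted failures (fixed onset/found/repaired days) override the
  stochastic process for deterministic scenarios.
- **Ground truth** is kept by day-by-day bookkeeping of the latent state:
  the true out-of-tolerance fraction (failed days / period) and the true
  undetected fraction (failed-and-not-yet-found days / period).
- **Dose effects** follow an explicit stand-in model: expected deltas grow
  as `base × (interval / shortest)^exponent` with mean-one lognormal
  patient variability. The mechanism behind severity growing with the test
  interval is not part of the published method (only the observation that
  it does), so the assumed mechanism is a named, configurable parameter
  rather than an implicit constant.

Defaults define the reference scenario: a 360-operating-day (1.5-year)
period with daily QC; failure rate 2/3 per 240-day year for the gantry item
(one expected failure, hence one expected out-of-tolerance day, per 360
days — an out-of-tolerance time fraction of 0.278%) and zero for the five
items that never failed; drift noise of a quarter tolerance; 6-day service
delay; next-day repair; 10-patient dose cohorts with base effects 1.0 %PTV
/ 45 cGy, exponent 0.7, CV 0.3, which drive cohort-mean severity ranks
from ≈1.5 at daily testing to ≈8.5 at bimonthly.

What the generator does **not** emulate: real drift dynamics (degradation
is binary, not gradual), correlated failures across items, working-day
calendar gaps (weekends/holidays), measurement-device error on the QC
reading itself, and any dosimetric realism in the dose-effect model.
Passing tests on synthetic data therefore demonstrate estimator and
decision-rule correctness under the stated assumptions, not clinical
validity of a particular recommendation.

## Numerical and degenerate-input conventions

- Boundary deviations (|deviation| = tolerance) count as within tolerance.
- Rank-table boundaries are inclusive upper bounds; rank rounding is half
  away from zero (Decimal-based, not float banker's rounding).
- An empty QC log for an item yields occurrence rank 2 with quantity 0; an
  empty service log yields detection rank 1 with quantity 0; a missing
  (item, interval) dose cohort is an error naming the pair.
- Readers validate referential integrity (unknown item ids, off-grid
  intervals, reversed event dates) and name the offending row.
- Simulation determinism: one `numpy` Generator seeded from the scenario
  seed, consumed in a fixed item/day order; identical configs give
  byte-identical output files.

## Problem sizes

The bundled analyses and tests run at desk scale: 6 items × 6 intervals ×
10-patient cohorts, 360-day observation windows, and 200-seed Monte-Carlo
batches for parameter-recovery checks, which complete in seconds on one
CPU. Longer horizons or larger catalogs scale linearly in days × items.

## Known limitations

- The recommendation uses S and O only; D enters through the E metric, so
  a hard-to-detect but rare failure can still earn a long interval.
- Occurrence estimation is record-driven: failures that never produce an
  out-of-tolerance QC record (missed and silently repaired) are invisible
  to O, though they still lower D through the service log.
- The half-interval detection convention is an expectation argument, not an
  observed duration; per-failure truth can deviate by up to half the gap.
- With rank-valued O and D, E is a coarse metric: many schedule changes
  leave it unchanged even when raw quantities move.
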