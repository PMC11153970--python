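# Methods

## Problem and model

Electronic monitors (EMs) log the date-time of each opening of a medication
container; openings proxy intakes. The package computes the *implementation*
component of adherence — how well dosing matched the prescribed regimen
while the patient was on treatment — as a daily binary statistic and its
summary rates, after folding in the investigator-documented deviations that
otherwise bias raw EM data downward.

Per monitor-day the pipeline assembles:

* **expected openings** `e` from the regimen in force that day. Continuous
  regimens expect a constant count. Cyclic regimens (e.g. 21 days on / 7
  days off) expect the configured count during the first `On` days of each
  cycle and 0 during the next `Off` days; the cycle phase is anchored at the
  regimen row's start date, so a monitoring window that begins mid-cycle
  inherits the row's phase, and a regimen change starts a fresh period with
  a fresh anchor. Alternating two-monitor regimens (two dose strengths, one
  day over two) are represented as two On=1/Off=1 rows whose start dates
  differ by one day.
* **corrected openings** `c = max(0, recorded + delta)`, where `delta` is
  the signed sum of documented `AddedOpenings` rows that day: positive for
  pocket doses (intake without opening), negative for documented extra
  openings (curiosity checks, pill counts). Days without events count as 0
  recorded openings.
* **censoring**: any day inside a `NonMonitoredPeriod` is excluded from both
  numerator and denominator; censoring wins over adjustments dated the same
  day.

Daily implementation is `1` if `c >= e` (so `0 >= 0` on Off days is optimal
and overconsumption is never penalised), `0` otherwise, `NA` if censored.
Patient-day implementation is the product over the monitors whose window
covers the day; any censored monitor censors the patient-day. Rates are
optimal/monitored days. All date intervals are closed on both ends — the
single most consequential convention in the package, since an off-by-one
changes every denominator.

The pipeline deliberately performs **no inference**: deviations enter only
through auxiliary rows the investigator has validated (e.g. by pill count).
Doses prepared in advance for the next day are handled by the investigator
recording that day as a nonmonitored period; within-day timing is out of
scope, as are persistence (time-to-discontinuation) analyses and any
longitudinal modelling of the cleaned data.

## Validation taxonomy

Findings are partitioned by their effect on correctness. *Critical errors*
block all output: missing mandatory sheets/columns, unparseable or ambiguous
dates (e.g. `03/04/2021` is rejected, never guessed; ISO 8601 and native
date cells are accepted), `On` without `Off`, start after end, duplicate
EMInfo rows, auxiliary rows referencing undeclared monitors, monitoring-
window days covered by zero or multiple regimen periods, and an empty raw
folder. *Warnings* never block: declared monitors without raw data,
undeclared monitors in raw data (their events are excluded), ignored files,
duplicate identical event rows (kept — monitors legitimately log rapid
successive openings), out-of-window adjustments, clipped or out-of-window
censoring intervals, corrected counts clamped at zero, and zero monitored
days. Over-deletion clamps to zero with a warning rather than erroring: an
auxiliary-data mistake the investigator must see, but not one that should
abort the run. `--strict` promotes all warnings to errors. The raw filename
filter (`eventslist`) is case-sensitive.

Both logs are always written, deterministically ordered; the workbook writer
pins document properties and zip timestamps so identical runs are
byte-identical — useful for audit trails and exercised by the tests.

## Synthetic cohorts

The generator produces matched raw files + auxiliary workbook + per-day
truth. Defaults describe a small oral-anticancer monitoring cohort: 10
patients, 15 monitors (5 patients with two EMs — one alternating pair, four
mid-study monitor switches), one 21/7 cyclic monitor, one mid-study dose
change, monitor periods lognormal (median 187 days, sigma 0.6, clipped to
[60, 450]). Intake is Bernoulli per scheduled dose with p = 0.97; a taken
dose is a pocket dose with probability 0.07; extra openings occur on 1% of
monitored days; EM-nonuse intervals start on 1% of days and last 4–10 days.
Under these conditions the raw (uncleaned) median patient implementation
sits roughly 10–15 percentage points below the cleaned median of ≈97% —
the regime in which data cleaning visibly matters. Sequential (rather than
concurrent) monitors for the switch patients keep patient-level rates near
p; a concurrent pair would push them toward p².

Every injected deviation is written to *both* sides (raw events and
auxiliary rows), and deviations never fall on censored days, so full
cleaning recovers the truth table exactly — the basis of the recovery
tests. What the generator does **not** emulate: within-day timing structure
(times are uniform over 07:00–22:00), monitor clock drift, dose-strength
arithmetic, undocumented deviations, or discordant medication-history
sources; passing tests therefore certify the cleaning calculus, not the
field accuracy of any particular study's auxiliary data.

## Verification strategy and problem sizes

* An independent brute-force oracle (plain csv/openpyxl reading plus
  day-by-day loops, no shared code) must agree *exactly* with the pipeline —
  per-day values and all summaries — on 50 randomised miniature cohorts
  (≤5 patients, ≤60-day windows, mixed regimens and deviations).
* The generator truth table must be recovered exactly over 20 seeds.
* Parameter recovery: 200 patients × 100 days, once-daily continuous, no
  deviations, p ∈ {0.6, 0.8, 0.95}; the mean patient rate must fall within
  2 Monte-Carlo standard errors of p.
* Schedule algebra (21/7 expansion, periodicity, cycle mass), the daily and
  product-rule truth tables, validation gating, and the sign of the
  raw-vs-clean gap are tested directly; property tests (hypothesis) cover
  aggregation conservation, the monitored/censored partition, and
  adjustment-delta conservation under clamping.

These sizes keep the full suite under a minute on one CPU while leaving the
statistical checks well-powered.

## Numerical and degenerate-input choices

Rates are exact integer ratios internally (Python floats of `opt/mon`);
rendered summaries show percentages with one decimal. Zero monitored days
yield an empty rate plus a warning rather than NaN arithmetic. Zero-delta
adjustment rows are dropped with a warning. `ExpectedOpenings = 0` is a
legal continuous regimen (e.g. a documented treatment pause): every day is
trivially optimal, which is the printed rule taken at face value —
consumers comparing cyclic to continuous cohorts should note that Off days
mechanically raise cyclic rates.
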