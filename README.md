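# adhclean

Cleaning and enrichment of **electronic-monitor (EM) medication adherence
data**, with per-day *implementation* statistics at monitor and patient
level.

EMs (e.g. MEMS pill bottles) time-stamp every opening as a proxy for a
medication intake. Raw opening logs, analysed naively, systematically
*understate* adherence: patients take *pocket doses* (doses removed without
opening the monitor), clinicians trigger *extra openings* (curiosity checks,
pill counts), monitors sit unused during holidays or hospitalisations, and
regimens change mid-study. `adhclean` is for adherence researchers who need
those deviations — documented by the investigator in a structured companion
workbook — folded into the raw data reproducibly before any statistical
analysis.

## The statistic

For monitor $m$ on day $t$ inside its monitoring window, let $e_{mt}$ be the
number of expected openings implied by the prescribed regimen (constant for a
continuous regimen; for a cyclic regimen with On/Off phase lengths
$(a, b)$ anchored at the regimen period's start, $e_{mt} =$ expected openings
when $(t - t_0) \bmod (a+b) < a$, else $0$), and let
$c_{mt} = \max(0,\; r_{mt} + \delta_{mt})$ be the corrected opening count
(recorded openings plus the signed documented adjustment). Daily
implementation is

$$y_{mt} = \mathbf{1}\{c_{mt} \ge e_{mt}\} \in \{0, 1\},
\qquad y_{mt} = \text{NA on censored (nonmonitored) days.}$$

Note $0 \ge 0$: Off-cycle days are trivially optimal, and overconsumption is
not penalised. Per patient-day, implementation is the **product** over all
monitors whose window covers the day (one suboptimal monitor ⇒ 0; one
censored monitor ⇒ NA). Summary implementation rates are
optimal days / monitored days, per monitor and per patient; NA days are
excluded from numerator and denominator.

## Inputs and outputs

* **Raw EM files** — a folder of CSV/TSV/XLSX exports whose filenames contain
  `eventslist`; either one row per opening (`PatientCode, Monitor, Date`) or
  the daily-adherence layout with an extra `RecordedOpenings` column.
* **Auxiliary Data workbook** — mandatory sheets `EMInfo` (monitoring
  windows) and `Regimen` (expected openings, On/Off cycles, regimen changes);
  optional sheets `AddedOpenings` (signed per-day corrections),
  `NonMonitoredPeriods` (censoring), `PatientCovariables`, `EMCovariables`,
  `AdverseEvents`.
* **Output** — `implementation.xlsx` with four sheets (*by monitor*,
  *by patient*, *summary by monitor*, *summary by patient*; censored days are
  empty cells) plus `errors.log` / `warnings.log`. Critical errors (bad
  dates, regimen gaps/overlaps, orphan rows …) block output; warnings never
  do.

## Worked example

Simulate a ground-truthed 10-patient cohort (15 monitors: one 21-on/7-off
cyclic regimen, one alternating two-monitor pair, mid-study monitor
switches) and clean it:

```sh
$ adhclean simulate --out sim --seed 7
raw files: sim/raw
auxiliary workbook: sim/auxiliary.xlsx
truth tables: sim/truth_*.csv

$ adhclean clean sim/auxiliary.xlsx sim/raw
errors: 0  warnings: 0
logs: sim/errors.log, sim/warnings.log
implementation workbook: sim/implementation.xlsx
  P01: 206/206 optimal days (100.0%)
  P02: 133/140 optimal days (95.0%)
  P03: 122/125 optimal days (97.6%)
  P04: 99/103 optimal days (96.1%)
  P05: 371/380 optimal days (97.6%)
  ...
```

Each line is a patient's implementation summary: optimal days over monitored
days. `P02: 133/140 (95.0%)` means that on 95% of the 140 days on which
P02's monitors were in use, the corrected openings met or exceeded the
expected openings of every monitor in use that day. Add `--no-corrections`
to recompute the raw (before-cleaning) view for before/after comparisons,
`--csv` for CSV mirrors of every sheet, `--strict` to treat warnings as
blocking.

The same machinery is available as a library:

```python
from adhclean import run_pipeline
result = run_pipeline("sim/auxiliary.xlsx", "sim/raw")
result.patient_summary  # PatientCode, MonitoredDays, OptimalDays, rate, covariables
```

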