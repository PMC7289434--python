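# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `queueflow`, in the spirit of a model-description appendix.

## Data model and targets

A visit log has one row per patient visit with minute-resolution
timestamps (ISO 8601, local facility time): `scheduled_time`,
`arrival_time`, `begin_time`, `end_time`, plus exam metadata (code,
body-region category, contrast flag), resource id, optional age,
outpatient flag and an optional add-on insertion time. Invariants enforced
at construction: `arrival ≤ begin ≤ end`, unique visit ids, and a single
facility per log. All durations are integer minutes.

The prediction target is the **delay** `begin − scheduled` at scheduled
and hybrid facilities (signed; negative when a patient is seen before
their slot) and the **wait** `begin − arrival` at walk-in facilities
(nonnegative by construction). At walk-in facilities the scheduled time of
every record is forced to its arrival time at ingest — the standard proxy
when no real schedule exists. Records without an `end_time` are rejected:
cancelled or never-completed visits are outside the data model.

## The 84-feature catalog

Five groups: congestion (57), customer (2), resource (1), task (15), time
(9). Definitions the source material leaves open were fixed as follows:

* **Set membership.** "In line" = arrived, exam not begun (`arrival ≤ t <
  begin`); "in progress" = `begin ≤ t < end`; completed/begun "today" are
  day-scoped with `end ≤ t` / `begin ≤ t`. A visit beginning exactly at
  `t` is in progress, not in line. Trailing windows of width `w` are
  half-open `(t − w, t]`. The index visit is excluded from every set and
  count.
* **Leakage rule.** Event-derived features may use only events with
  timestamps ≤ t; a visit's delay/wait becomes known at its *begin* time.
  Schedule-derived features (scheduled-flow and future-flow counts,
  next-slot counts, AheadCount, IsFirst/IsLast, Before/AfterSlot) may use
  schedule entries with any timestamp, because bookings are known in
  advance. Add-on counts use the add-on's insertion timestamp.
* **"Delayed"** means delay strictly > 0 minutes; no grace threshold.
* **History features** (MostRecent1–5, AvgWaitLast{2,4,8}Customers,
  Median5, AvgWaitForDay, Min/MaxTime, DelayCount) are scoped to the
  current day and ordered by begin time; the K-customer statistics
  zero-pad to K when fewer predecessors exist (so `AvgWaitLast4Customers`
  with two predecessors is their summed target over 4), and Min/Max/Avg
  default to 0 on an empty day. Whether history should look back across
  days is a genuinely open choice; day-scoping matches how operational
  dashboards reset each morning.
* **Expected durations.** `SumTimeToCompleteNextSlot/Next60` and
  `SumTimeToCompleteInProgress` use the historical *median* service
  duration per exam code, estimated over a reference period (default: the
  first 90 calendar days of the log) that precedes and is disjoint from
  the featurized rows, with the facility-wide median as fallback for
  unseen codes. In-progress remaining time is `max(0, expected − elapsed)`.
* **ExpectedDelayNextExam** = `max(0, clearance − next scheduled time)`
  with `clearance = t + SumTimeToCompleteInProgress / n_servers` — a
  deliberately simple single-queue clearance estimate.
* **SumHowEarlyWaiting** sums `scheduled − arrival` without clamping, so
  late arrivals contribute negatively.
* **Slot-grid features** (BeforeSlot/AfterSlot, next-slot counts) measure
  against the facility's appointment grid (default 30 minutes), anchored
  at midnight; `StartTime` is the fractional hour of arrival and its
  powers 2–4 capture nonlinear clock trends.
* **LineCount0Strict** is read literally: in-line patients whose scheduled
  time is still in the future — identically 0 under the walk-in proxy.

Two walk-in applicability flags accompany every feature, because one flag
cannot express both sensible readings: `walkin_applicable` (strict — drops
every feature whose definition needs a real appointment schedule or a
signed delay) and `walkin_proxy_applicable` (permissive — under the
arrival-as-schedule proxy only the delay-defined counters DelayedInLine,
DelayCount and DelayCountLastHour lose their meaning). Transfer analyses
choose a policy explicitly; both flag columns are reviewable in the
exported catalog CSV.

## Workflow simulator

The simulator emulates four facility archetypes — MRI-like scheduled
(2 scanners, 30-min slots, ~29 visits/day, utilization ≈ 0.9),
ultrasound-like scheduled (4 rooms, ~68/day), CT-like hybrid (2 scanners,
15-min slots, scheduled plus ~1 walk-in/h) and X-ray-like pure walk-in
(2 rooms, ~12 arrivals/h ≈ 120/day) — spanning the 25–120 visits/day range
typical of outpatient imaging. Daily volumes and loads were calibrated so
that congestion, not the clock, drives delays, with delay/wait magnitudes
on the scale reported for comparable real facilities (tens of minutes for
MRI-like, single-digit minutes for X-ray-like). Operating days are
weekdays only.

Per operating day: scheduled patients are booked per slot as
`Binomial(n_servers, booking_prob)`; no-shows are dropped with probability
`noshow_prob`; add-ons are inserted during the day with schedule timestamp
equal to insertion time; walk-ins arrive as a Poisson process. Arrivals
are `scheduled + Normal(earliness_mean = −20, sd = 12)` minutes (patients
typically arrive 20 minutes early), clamped into the day. Service
durations are log-normal per exam code (configured mean in minutes and
log-sd dispersion), rounded to ≥ 1 minute.

Service discipline (1-minute clock): the next free server takes the
*arrived* waiting patient with the earliest scheduled time and never
starts before that scheduled time — `begin = max(arrival, scheduled,
server-free)`. Since walk-ins carry arrival as scheduled time, the one
rule yields schedule-order (non-FIFO w.r.t. arrival) service at scheduled
facilities and FIFO at walk-in facilities. A consequence worth noting:
simulated scheduled facilities never produce *negative* delays, although
the data model and target definition support them.

What the simulator does **not** emulate: staffing rosters, equipment
downtime, no-show recovery, patient-specific behaviour, inpatient
interruptions, seasonal case-mix drift. Passing tests on simulated data
therefore demonstrate that the protocols recover known congestion-driven
structure — not that any particular real facility behaves like the
archetypes.

One simulator-fidelity caveat discovered during development: when an
archetype's exam codes have widely differing mean durations (the MRI
archetype spans 34–50 minutes), the exam-type composition of the queue
becomes a legitimate proxy for workload, and task-group features earn
selection frequency they would not have at real facilities where
within-protocol duration variance dominates. The congestion-recovery
acceptance check therefore uses the ultrasound archetype, whose per-code
means are close and which books uniform 30-minute slots.

## Selection protocols

* **Splits.** Each replicate draws a training-window start uniformly over
  admissible days (overlapping replicates allowed), takes 6 consecutive
  months as training and the following 14 days as test. Both window
  lengths are configurable; shorter windows are used in smoke tests.
* **Stepwise.** Candidate models are scored by 10-fold CV-MSE of the OLS
  fit; folds are a seeded random partition, assigned per replicate. The
  scan is implemented with per-fold Gram matrices of the train-standardized
  design (numerically equivalent to refitting OLS per fold; standardization
  changes no prediction because the intercept is always included). Singular
  subsets fall back to the minimum-norm pseudoinverse solution; exact score
  ties go to the earlier catalog column. Exactly `n_max` (default 20)
  features are always added; cross-validated MSE is *not* forced to be
  monotone along the path (it typically decreases, but adding the best
  remaining candidate can raise it once signal is exhausted — only the
  full-train MSE is guaranteed non-increasing, and that is what the
  property test asserts).
* **Forest.** scikit-learn `RandomForestRegressor`; default tuning grid
  mtry ∈ {p/3, √p, p/2} × depth ∈ {8, 16, ∞} × trees ∈ {200, 500}, tuned
  once per facility and reused across replicates. Importance is computed
  on out-of-bag rows per tree (via `estimators_samples_`), permuting one
  column at a time with a seeded generator; negative scores are kept as an
  honest noise floor. Permutation importance is used instead of impurity
  importance, which is biased toward high-cardinality features.
* **Transfer.** The ratio is of mean-absolute errors (consistent with the
  MAE metric used for model comparison throughout); the 95% interval is
  the 2.5/97.5 percentile of per-split ratios. Identical sets give ratio
  exactly 1 for the deterministic linear model on fixed splits.

## Problem sizes used in the shipped checks

The acceptance-level tests run a 400-operating-day ultrasound-archetype
simulation (~23k featurized visits after a 90-day duration-reference
period), 20 stepwise replicates for the frequency analysis, a second
facility identical except for its exam mix for the cross-facility ratios,
200 random 1–2-day logs for brute-force oracle equivalence of all 84
features, and 20 planted-signal replicates (n = 600, one linear driver
among 9 noise columns) for first-pick recovery. These sizes were chosen so
the full suite completes in about a minute on a laptop core while keeping
every check statistically decisive.

## Known limitations

* The feature engine assumes a visit completes within 24 h of arrival
  (line/in-progress membership scans look back no further).
* `compute_features`/`featurize_log` called without explicit duration
  stats estimate them from the whole log — convenient for exploration but
  leaky for modelling; the pipeline always freezes stats on the reference
  period and featurizes only later visits.
* The clearance model behind ExpectedDelayNextExam ignores server
  heterogeneity and patient reordering.
* Transfer ratios compare feature *sets*; they say nothing about
  coefficient or split-point transfer.
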