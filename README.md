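# queueflow

Feature engineering and feature-selection protocols for predicting patient
**wait** and **delay** times in outpatient facilities, together with a
discrete-event workflow simulator that generates realistic facility visit
logs with known ground-truth dynamics.

## The problem

Operational teams in imaging departments (MRI, ultrasound, CT, X-ray) want
to predict, at the moment a patient arrives, how long that patient will
wait. For a scheduled facility the target is the *delay*
`begin − scheduled` (negative when the exam starts early); for a walk-in
facility it is the *wait* `begin − arrival` (nonnegative by construction),
with arrival time standing in for the nonexistent scheduled time wherever
a schedule is assumed.

Which predictors matter? `queueflow` implements a catalog of **84
operational features**, all computable from an ordinary facility
information system's visit log, divided into five groups: *congestion* (57
features: line counts and their one-hour history, flow counts, in-progress
totals, delay/wait history), *customer* (2), *resource* (1), *task* (15:
exam-type composition of the queue) and *time* (9: calendar and clock).
Every feature is evaluated **as of the index patient's arrival time** with
strict anti-leakage semantics: events (arrivals, exam begins/ends) may be
used only up to the prediction time, while schedule entries — known in
advance — may lie in the future.

Two selection protocols identify the most predictive feature *sets*:

* **Repeated forward-stepwise linear regression** — per replicate, a random
  consecutive 6-month training window plus the following 2 weeks as test;
  at each step the candidate minimizing 10-fold cross-validated MSE of the
  augmented OLS model is added, for exactly 20 steps. The *testing
  percentage error* of the size-N model is
  `100 × testMSE(N) / testMSE(intercept-only)` (the intercept-only model
  predicts the training-mean target and scores exactly 100%). Selection
  frequency across replicates ranks the features.
* **Random-forest cumulative importance** — hyperparameters tuned by
  10-fold CV; each feature scored by out-of-bag permutation importance
  (mean per-tree increase in OOB MSE when the feature's column is
  permuted), summed across replicate forests.

A third module quantifies **transferability**: the ratio
`MAE(transferred set) / MAE(locally optimal set)` on held-out windows
(1.06 = 6% worse), with walk-in applicability filtering and cross-model
(LR set in forest, forest set in LR) evaluation. The reduced feature sets
published for four real imaging facilities ship as CSV fixtures for
set-algebra analyses.

The consistent empirical picture — reproduced here on simulated
facilities — is that **congestion features dominate** every facility type
and transfer across facilities and models nearly without loss.

## Worked example

`examples/03_stepwise_selection.py` simulates a congested four-room
ultrasound-like scheduled facility for 300 operating days, computes the
84-feature matrix, and runs 5 stepwise replicates:

```
feature matrix: 15916 visits

most frequently selected features:
  LineCount0                     100%  (congestion)
  SumDelayInProgress             100%  (congestion)
  InProgressSize                 100%  (congestion)
  NoneInLine                     100%  (congestion)
  VascularCount                  100%  (task)
  NumScheduledNextSlot            80%  (congestion)
  IsFirst                         60%  (congestion)
  ExpectedDelayNextExam           60%  (task)
  IsLast                          60%  (congestion)
  FlowCount30                     40%  (congestion)

mean testing percentage error by model size:
  100.0   83.9   76.0   72.9   72.3   72.0   72.2   72.1   71.5   67.7   66.6
```

Reading: the queue seen at arrival (`LineCount0`), the backlog already in
the scanners (`SumDelayInProgress`, `InProgressSize`) and related
congestion state are selected in essentially every replicate; adding the
first feature alone cuts test MSE to 84% of the intercept-only error, and
ten features reach a ~67% plateau. The other example scripts cover the
simulator (`01`), single-visit feature vectors (`02`), forest importance
(`04`) and set algebra/transfer (`05`); each prints the numbers it
computes and a line on how to read them.

A thin CLI mirrors the pipeline stages:

```bash
queueflow simulate --archetype xray_walkin --days 30 --seed 1 --out log.csv
queueflow featurize --log log.csv --facility-type walkin --out matrix.csv
queueflow select-lr --matrix matrix.csv --replicates 100 --seed 1 --out-prefix lr
queueflow run --config run.yaml --seed 1   # full simulate→select→transfer bundle
```

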