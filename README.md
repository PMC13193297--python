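# exposim

A headless, deterministic simulator of an exposure-therapy training session
with a virtual patient, together with the bounded-outcome trial analysis
pipeline used to evaluate such training.  No graphics, hardware, or network:
everything runs as plain Python over text formats (CSV, JSONL, JSON).

## What it does

**Simulation side**

- `exposim.hierarchy` — ordered 10-task exposure hierarchies (a packaged
  contamination ladder is the default fixture) and the ±2-position move
  constraint at decision points.
- `exposim.engine` — the virtual-patient state machine: 9 decision points on
  a 45-second cadence, verbalization cues every 15 seconds tagged with the
  patient's distress band, SUDS (0–10) habituating 1 point per 2 minutes of
  continuous exposure, and an append-only event log (JSONL) that replays
  exactly.  Time is simulated; nothing waits on a wall clock.
- `exposim.policies` — scripted therapist policies (gradual titration,
  avoidant, fixed, random) and cohort generation (3 repetitions per trainee
  with full resets in between).
- `exposim.feedback` — the post-session feedback screen: SUDS trajectory,
  rule-based classification of every decision, text chart and step plot.

**Analysis side**

- `exposim.measures` — instrument scoring (usability 0–100 conversion,
  summed scales, percent-correct knowledge, subscale means) and the bounded
  measure registry.
- `exposim.synth` — synthetic 2-arm (20/21) × 4-timepoint trial datasets on
  three bounded measures, generated by a logit-normal-binomial model with
  within-participant correlation.
- `exposim.analysis` — scores rescaled to binomial successes/trials,
  saturated marginal binomial-logit fits via estimating equations with
  classical sandwich covariance, 16 contrasts in three families
  (8 within-condition changes, 4 cross-sectional arm comparisons,
  4 arm differences in change), step-down Holm adjustment at familywise
  α = .05, Cohen *d* effect sizes, and single-hypothesis two-group
  comparisons for end-of-study measures.

## CLI

One entry point, `exposim`, with subcommands:

```sh
# interactive session in the terminal
exposim play --out session.jsonl

# scripted session (byte-identical for a fixed seed)
exposim simulate --policy titration --theta 4 --seed 1 --out session.jsonl

# cohort: 5 trainees x 3 repetitions -> JSONL logs + manifest.csv
exposim simulate --policy random --trainees 5 --seed 2 --out cohort_dir/

# post-session feedback (text chart, JSON report, trajectory plot)
exposim feedback --log session.jsonl --json-out fb.json --plot-out fb.png

# score item-level responses (columns item1..itemN) into the long format
exposim score --measure tbes --responses items.csv --out scored.csv

# synthetic trial -> long CSV (+ .provenance.json sidecar)
exposim synth-trial --seed 3 --out trial.csv

# longitudinal analysis -> report.contrasts.csv + report.json
exposim analyze-trial --data trial.csv --out-prefix report
```

## File formats

- **Hierarchy**: UTF-8 CSV with header `position,task_id,label`, one task
  per line, positions consecutive from 1 (least difficult).
- **Session log**: JSONL, schema version 1.  First line is a header object
  (`schema_version`, `session_id`, `complete`, `config`, `hierarchy`);
  each following line is one event (`t`, `kind`, payload).  The reader
  rejects unknown schema versions.
- **Trial data**: long CSV with header
  `participant_id,arm,timepoint,measure,score` plus a JSON provenance
  sidecar carrying the generator config and seed.
- **Analysis report**: CSV (one row per contrast: estimate, SE, statistic,
  raw and Holm-adjusted p, unadjusted 95% CI, Cohen *d*) and JSON (adds
  per-cell means with back-transformed CIs).

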