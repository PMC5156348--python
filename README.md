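# nestcare

Quantifying biparental care from nest-box ethogram logs: from two-parent
behavioural event logs to effort metrics, intraclass repeatability,
sampling-window evaluation, and diurnal / division-of-labour models — plus
a continuous-time behavioural simulator for generating synthetic study
corpora.

## What it does

Given per-nest event logs of two parents' coded behaviour (`care` bouts,
`inside`-the-box bouts, and feeding point events over 07:00–19:00
recordings), the package computes:

- **Effort metrics** by exact interval algebra: individual care and nest
  attendance (care ∪ inside) per parent, joint (intersection) and total
  (union) variants, and the male share of feeding bouts. Footage gaps are
  handled by observable-time denominators; windows with less than 95 % of
  their nominal footage are flagged missing.
- **Sampling windows**: full-day recordings tiled into 12 × 1h or 4 × 3h
  windows, per-window effort matrices and overall daily effort.
- **Repeatability**: one-way-ANOVA intraclass repeatability (Harper's
  variance-component method, with the balanced `(F − 1)/(F + n − 1)`
  shortcut and `n0` correction for unbalanced designs), significance
  gating, and 1h-vs-3h paired-t comparisons.
- **Window-vs-daily prediction**: per-window OLS R² against daily effort
  with nonparametric case-bootstrap CIs (percentile by default, BCa
  optional; B = 10⁴, fully seeded).
- **Mixed models**: AIC-selected orthogonal-polynomial diurnal trends with
  nest random intercepts, and sex × stage division-of-labour models with
  parent-nested-in-nest random terms, both tested by likelihood-ratio
  tests on ML fits.
- **Simulation**: a two-parent semi-Markov process (off / inside / care,
  piecewise-constant hazards on a 1-minute grid, diurnal and stage
  log-hazard shifts, per-parent random intercepts, partner coupling,
  Poisson feeding) that emits corpora with the study's full recording
  layout (570 scheduled hours, or 840 in the all-full-day variant).

## CLI

```sh
# simulate a study corpus
nestcare simulate --preset paperlike --seed 7 --output-dir out/

# individual stages
nestcare summarize     --input out/corpus.csv --output-dir out/
nestcare repeatability --input out/corpus.csv --output-dir out/
nestcare predict       --input out/corpus.csv -B 10000 --seed 1 --output-dir out/
nestcare diurnal       --input out/corpus.csv --output-dir out/
nestcare division      --input out/corpus.csv --output-dir out/

# or the whole chain at once
nestcare report --input out/corpus.csv -B 10000 --seed 1 --output-dir out/report/
```

Every command writes CSV tables plus a `manifest.json` recording the
command, seed, inputs and outputs. The event-log format is a long CSV
(`nest_id, stage, stage_day, parent, record_type{span|state|feed}, state,
start_s, end_s`, seconds since local midnight, half-open intervals) with
an optional gap sidecar CSV; a per-second wide TSV importer is also
provided (`nestcare.io.read_wide_tsv`).

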