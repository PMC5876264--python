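# hamscore

Additive MRI severity scoring for acute hamstring muscle injury, with the
downstream analysis pipeline: cohort description, prognostic evaluation of
the total score against return-to-sport (RTS) time, and a calibrated
synthetic-cohort generator for end-to-end testing when per-subject data is
unavailable.

## What it does

- **`hamscore.rubric`** — the scoring grid as data. Seven components (age,
  number of muscles involved, injury location, insertional involvement,
  transverse cross-sectional %, retraction, craniocaudal sagittal extent)
  are each mapped to 0–3 points via declarative bins; the total is the sum.
  `score_injury` scores one validated record; `enumerate_score_range`
  brute-forces the achievable (min, max) total for MRI-negative and
  MRI-positive records (1–3 and 4–19 under the default grid).
  Alternative rubrics load from JSON (`--rubric` on the CLI).
- **`hamscore.summary`** — category counts with half-up one-decimal
  percentages (denominator = the supplied counts' own total) and continuous
  summaries (mean with 95% t-CI, median, IQR, sample SD, min, max).
- **`hamscore.evaluation`** — Lilliefors-corrected Kolmogorov–Smirnov
  normality checks, Pearson + Spearman correlation with variance explained
  (100·r²), and a dichotomized comparison at a score threshold (default 10):
  per-group n/mean/median/SD, mean difference with Welch 95% CI, and
  Cohen's d (pooled SD). Degenerate cases yield explicit absences, never
  silent infinities.
- **`hamscore.synthetic`** — cohorts sampled from configurable categorical
  marginals and a linear-in-score Gaussian RTS model whose intercept/slope/
  noise are moment-matched to target RTS mean, SD and score–RTS correlation
  (`calibrate_rts_model`); floored at 1 day and rounded to whole days.
  Fully reproducible from a single seed with per-variable sub-streams.
- **`hamscore.io` / `hamscore.pipeline` / `hamscore.cli`** — CSV readers
  with row-level validation and exclusion accounting, and the umbrella
  pipeline writing scored records, summary/evaluation reports (JSON + Markdown)
  and plot-ready data tables.

## CLI

```sh
hamscore simulate --n 110 --seed 42 --out records.csv
hamscore score     --input records.csv --out scored.csv
hamscore summarize --input records.csv --out summary.json
hamscore evaluate  --input records.csv --threshold 10 --report eval.json
hamscore pipeline  --input records.csv --outdir out/
```

All commands accept `--rubric path.json` to swap in a variant scoring grid
(the shipped default is `src/hamscore/data/default_rubric.json`). Exit
codes: 0 success, 2 validation/schema failure, 3 computation failure.
Record CSVs are UTF-8 with a mandatory header; columns are listed in
`hamscore.io.COLUMNS`, missing values are empty cells.

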