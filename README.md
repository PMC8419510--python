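# who-select

Wildebeest Herd Optimization (WHO) as a reusable feature-selection toolkit:

- **`who_select.who_core`** — the WHO metaheuristic as a general continuous
  minimizer over box-bounded domains (milling probes, leader-weighted local
  updates, herd instinct toward fitter peers, starvation avoidance, herd
  pressure toward the global best, and a social-memory re-seed of the worst
  candidate), with strict elitism and seeded determinism.
- **`who_select.wrapper_selection`** — wrapper feature-subset selection:
  continuous positions on `[0,1]^d` are thresholded into binary masks and
  scored by `error_weight * CV-misclassification + (1-error_weight) *
  subset-size-ratio` with a deterministic stratified-CV k-NN (or linear-SVM)
  evaluator. Includes budget-matched random-search and hill-climbing
  baselines and a repeated-independent-runs harness.
- **`who_select.prefilters`** — statistical pre-filters: tree-ensemble Gini
  importance (explicit node/tree representation plus a bootstrapped CART
  grower) and chi-square dependency scores from bin-by-class contingency
  tables.
- **`who_select.metrics`** — diagnostic metrics (accuracy, sensitivity,
  specificity, an SPC/SNS harmonic-mean F-score, Dice, PPV, NPV; zero
  denominators yield an explicit `None`) and repeated-run fitness statistics
  (best / worst / mean / sample SD).
- **`who_select.synthetic_data`** — labeled feature matrices with planted
  informative, correlated-redundant, and pure-noise features, plus
  continuous benchmark objectives (sphere, rastrigin, 1-D quadratic).
- **`who_select.cli`** — the `who-select` command.

## CLI

```sh
# synthetic dataset (CSV with a `label` column + ground-truth sidecar JSON)
who-select simulate --n 300 --informative 5 --redundant 10 --noise 35 \
    --effect 1.5 --seed 1 --out features.csv

# raw continuous optimization on a named benchmark
who-select optimize --objective sphere --dim 10 --iters 200 --seed 1

# statistical pre-filter (gini or chi2)
who-select prefilter --data features.csv --method gini --keep 25 \
    --seed 1 --out prefilter.json

# wrapper selection: repeated independent runs, JSON report
who-select run --data features.csv --label-col label --iters 15 --pop 30 \
    --runs 35 --seed 1 --out report.json

# budget-matched baseline searchers
who-select baseline --data features.csv --method random --budget 2700 \
    --seed 1 --out baseline.json

# re-evaluate a report's mask: fitness round-trip + full metric suite
who-select evaluate --data features.csv --report report.json
```

All commands are deterministic given `--seed`; reports are sorted-key JSON,
so identical invocations produce byte-identical files. Add `-v` before the
subcommand for INFO logging (config echo, per-iteration best fitness,
wall time).

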