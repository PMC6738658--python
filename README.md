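# riskgaze

Gaze-conditioned evidence-accumulation models of risky choice between simple
two-outcome lotteries, built as a tested, end-to-end pipeline:

- **design** — the 5×5 amount × probability lottery grid, dominance
  classification, trade-off enumeration, catch trials, risk classification.
- **gaze** — fixation preprocessing: AOI assignment, sub-50 ms dropping,
  same-AOI merging, trial exclusion rules, transition taxonomy
  (within-alternative / within-attribute / diagonal) and gaze summaries.
- **values** — static valuation: EV, EU (`u(x) = x^α`), CPT with inverse-S
  probability weighting, the exponential Luce choice rule, gaze-modulated
  regression values (`value · gaze^τ`), and the MaxiMax / Least-Likely /
  Priority heuristics.
- **accumulators** — the core dynamics: five gaze-driven leaky-accumulator
  variants (normalized and categorical within-attribute difference
  accumulators, one-layer and two-layer within-alternative accumulators, and
  a hybrid with mutual inhibition), with mid-range default substitution for
  unscanned attributes and a vectorized batch evaluator for fitting.
- **decision** — integration-to-boundary: fixed and collapsing boundaries,
  stochastic termination, Monte-Carlo likelihood of (choice, decision time)
  conditioned on fixations, Vincentized group RT quantiles.
- **inference** — two-step maximum likelihood (choices, then boundary
  parameters with common random numbers), AIC, prediction accuracy,
  stratified cross-validation, model comparison tables, and a
  parameter-recovery harness.
- **behavior** — descriptive analyses: EV psychometrics, risk preference by
  probability domain, gaze-advantage residuals, recency curves, transitivity
  violations, accuracy by ΔEV quantile, and normativity comparisons.
- **synthetic** — full synthetic experiments (participants, Markov gaze
  sequences with realistic count/duration/transition structure, choices and
  RTs from the accumulator models), with ground truth stored separately from
  anything the fitting code reads.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact design
counts, a brute-force dynamics oracle over 1 000 random cases, model
reductions, S5-style parameter recovery, model-selection sanity,
individual-difference and normativity directions, and a decision-time
round trip). The full suite takes several minutes on one CPU.

## CLI

Every stage is driven by a YAML config (see `riskgaze.io.CONFIG_SCHEMA`):

```sh
riskgaze simulate   --config run.yaml   # synthetic experiment + ground truth
riskgaze preprocess --config run.yaml   # cleaning + exclusion report
riskgaze fit        --config run.yaml --step step1   # choice MLE
riskgaze fit        --config run.yaml --step step2   # boundary fitting
riskgaze compare    --config run.yaml   # pooled model table
riskgaze recover    --config run.yaml --model two_layer  # recovery report
riskgaze analyze    --config run.yaml   # behavioral summaries + figures
```

A minimal config:

```yaml
paths: {output_dir: out}
design: {seed: 0}
simulate: {n_participants: 5, seed: 3, mode: step1}
fitting: {models: [EV, CPT, two_layer], n_starts: 6, seed: 1}
```

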