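# beamcea

Within-trial cost-utility analysis toolkit for a two-arm randomized trial
with a fixed three-visit schedule (HRQoL at weeks 0/12/24, EQ-5D utilities
at months 0/3/6) and a windowed cost ledger. The package provides:

- **`trial_data`** — participant-level data model, CSV schema, validation,
  lossless round-trip I/O (missing values are empty cells, never zeros).
- **`synthetic_trial`** — seeded generator of synthetic trials: correlated
  baseline/follow-up Gaussian scores with an additive arm effect, truncated
  Gaussian utilities, Gamma (or lognormal) costs, and differential dropout
  (MCAR or MAR) that never touches baseline data.
- **`outcomes`** — intention-to-treat and per-protocol analysis: LOCF
  single imputation, ANCOVA (OLS of follow-up on arm + baseline + age),
  proper multiple imputation by linear-regression predictive draws, and
  pooling with the within + (1 + 1/m) x between variance rule and
  small-sample degrees of freedom.
- **`health_econ`** — QALYs as trapezoid area under the utility curve,
  last-value-carried-forward completion of missing cost items (scaled by
  window length), exact integer-pence cost aggregation with configurable
  intervention-cost attribution and a user-supplied inflation index, and
  table/affine 5L-to-3L utility mapping.
- **`cea_bayes`** — Bayesian bivariate cost-effectiveness model with Gamma
  marginals for cost and 1 - QALY, baseline-cost/baseline-utility
  adjustment, and a cost-to-effect conditional-mean link; fitted by an
  adaptive Metropolis-within-Gibbs sampler (proposal scales frozen after
  burn-in) with split-chain convergence diagnostics. Outputs incremental
  cost/QALY draws, ICER with dominance labelling, CEAC, net monetary
  benefit, and cost-effectiveness-plane summaries with a 95% Gaussian
  ellipse.
- **`design_power`** — per-group sample size for a change-score t test
  (change SD = sd * sqrt(2(1 - rho)), exact noncentral-t power equation,
  an ANCOVA-style alternative mode), dropout inflation, and a vectorized
  power simulation harness.
- **`cli_report`** — one-command pipeline (simulate -> outcomes -> econ ->
  CEA -> design check) producing deterministic CSV tables, CEAC/plane
  plots, adherence summaries and a JSON manifest.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests (hypothesis) for
the arithmetic invariants, and `tests/test_acceptance.py` with the
stochastic acceptance criteria (parameter recovery, null calibration,
oracle agreement). Full run takes a few minutes on one CPU.

## CLI

```bash
# synthetic trial
beamcea simulate --seed 7 --out trial.csv

# outcome analysis (populations: itt-locf, itt-mi, per-protocol)
beamcea analyze-outcomes --in trial.csv --outcome mcs --population itt-locf --out outcomes.csv

# per-participant QALY / cost table
beamcea econ --in trial.csv --intervention-cost 15 --out econ.csv

# Bayesian cost-effectiveness model
beamcea cea --in econ.csv --seed 1 --out-summary cea.csv --plot-ceac ceac.png --plot-plane plane.png

# design calculation (+ optional simulation check)
beamcea design --sd 10 --rho 0.7 --delta 3 --simulate 5000

# full pipeline from one YAML config
beamcea run --config examples/pipeline.yaml --out out/
```

A pipeline YAML has optional sections `simulation`, `outcomes`, `econ`,
`cea` and `design`; any omitted section uses defaults. See
`tests/test_cli_report.py::FAST_CONFIG` for a minimal example.

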