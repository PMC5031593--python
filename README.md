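# metabopls

Chemometric inference linking specialized-metabolite abundances to a
bounded percentage response (e.g. the fraction of stressed cells showing
damage), built for small, session-structured untargeted-metabolomics
feature tables.

The pipeline implements:

- **Tabular I/O** — CSV/TSV feature tables with reserved metadata columns
  (`sample_id`, `session_id`, `treatment`, `damage_pct`), strict validation,
  bit-exact round-trips, and a JSON analysis report.
- **Preprocessing** — autoscaling (unit-variance), count-based proportions,
  relative-to-control damage normalization, paired effect tests, metabolite
  grouping (summed features), and ≥ k-fold accumulation screens with a
  detection floor.
- **PCA QC** — SVD-based PCA with Hotelling T² and SIMCA-style DModX
  outlier screening at a configurable level (default 99%).
- **PLS1 (NIPALS)** — univariate-response partial least squares with
  regression coefficients `b = W(PᵀW)⁻¹q`, percent-scale predictions,
  R²/RMSEC fit statistics, and VIP scores (`Σ VIP² = p`).
- **Validation** — N-fold *full* cross-validation (every observation held
  out exactly once) with training-fold-only scaling, Q²/PRESS/RMSECV,
  forward component selection, VIP-threshold variable selection tuned by
  sevenfold CV Q² (with a parsimony margin and greedy add/drop refinement),
  and response-permutation testing.
- **Monte Carlo stability** — Bernoulli(0.70) observation subsampling
  around the full selection procedure, per-metabolite selection
  frequencies, strong/weak/unrelated relevance bands with coefficient
  direction, and pooled out-of-subsample RMSEP.
- **Synthetic data** — a log-normal generator with session-dominant
  metabolome variance, treatment-targeted feeding boosts, a planted
  protective metabolite set driving the response, and full ground truth for
  recovery tests; plus a small hand-specified worked fixture.

## CLI

```sh
# generate a synthetic table (+ ground truth)
metabopls simulate --seed 1 --out table.csv --truth-out truth.json

# variable selection + final PLS fit
metabopls fit --table table.csv --out fit.json

# Q2 across fold counts + permutation test
metabopls validate --table table.csv --components 2 --out validation.json

# Monte Carlo stability spectrum (CSV: metabolite, frequency, class, direction)
metabopls stability --table table.csv --out spectrum.csv

# the full three-subset analysis (controls-only / fed-only / all samples)
metabopls run-all --table table.csv --config config.yaml --out report.json
```

Run configuration is a YAML file mirroring `RunConfig` (fold counts,
permutation/subsample counts, VIP margin, frequency cutoffs, seed). All
randomness is driven by the seed; identical config + seed reproduces
reports byte-identically.

## Python API

```python
from metabopls import (
    SyntheticSpec, generate_dataset, vip_threshold_select, mc_stability, RunConfig,
)

table, truth = generate_dataset(SyntheticSpec(seed=0))
sel = vip_threshold_select(table.abundances, table.damage_pct, N=7, seed=0)
stab = mc_stability(table.abundances, table.damage_pct, RunConfig(seed=0))
```

## Tests

```sh
python -m pytest tests/            # full suite incl. acceptance (~10 min)
python -m pytest tests/ --ignore=tests/test_acceptance.py   # quick (~2 min)
```

`tests/test_acceptance.py` holds the acceptance criteria: the worked
count-proportion example, the VIP normalization identity, OLS/LOO oracle
equivalences, null and permutation calibration, planted-support recovery
with stability classification, error-ordering/robustness audits, and
outlier-test calibration.

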