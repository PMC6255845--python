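# protdyn

Kinetic-model classification of paired mRNA–protein time courses.

## What it is for

Paired transcriptome/proteome time series (e.g. RPKM + LFQ over fly
embryogenesis, 14 points in 0–20 h) usually show weak mRNA–protein
correlation.  Before invoking complex post-transcriptional regulation,
`protdyn` asks the kinetic question: can the measured protein trajectory be
explained by simple synthesis-plus-turnover dynamics driven by the measured
mRNA?  Each gene is fit with four nested ODE variants

    stationary:           dy/dt = 0
    degradation:          dy/dt = -λy
    production:           dy/dt = αu(t) - λy
    delayed production:   dy/dt = αH(t-τ)u(t) - λy

with the mRNA input u(t) interpolated piecewise-linearly (all variants solve
in closed form).  Fits are weighted least squares (χ² with σ = 0.169·mean by
default, the linear error model of 4-replicate LFQ data), multistarted from
latin-hypercube samples inside log-scale parameter boxes.  A variant is
*feasible* when it passes both a parametric-bootstrap χ² test and a
Durbin–Watson test on the time-ordered residuals (BH-corrected across
genes); among feasible variants a stepwise likelihood-ratio test picks the
simplest adequate model, with a re-assignment rule that prefers production —
the biologically unregulated scenario — when its translation rate is bounded
away from zero (profile-likelihood CI).  Genes fit by no variant are
**rejected**: candidates for post-transcriptional regulation.  The package
also provides profile-likelihood CIs, half-life and steady-state
annotations, time-shifted Spearman correlation, joint trajectory-pair
clustering, hypergeometric overlap arithmetic, and a ground-truth synthetic
data generator emulating embryogenesis expression dynamics.

Audience: systems-biology / omics analysts with gene × time matrices of
paired mRNA and protein abundances on a shared grid.

## Worked example

```python
from protdyn import (SimulationConfig, ClassifyConfig, CLASSES,
                     simulate_dataset, classify_dataset, benchmark_report)

ds = simulate_dataset(SimulationConfig(n_per_class={c: 10 for c in CLASSES}, seed=1))
table = classify_dataset(ds.mrna, ds.protein,
                         ClassifyConfig(bootstrap_B=200, seed=1, annotate=False))
rep = benchmark_report(ds.truth, table)
print(rep["confusion"]);  print(rep["model_class_accuracy"])
```

which prints (50 genes: 10 per class, 16.9% replicate noise, B=200):

```
predicted           degradation  delayed_production  production  rejected  stationary
true
degradation                  10                   0           0         0           0
delayed_production            0                  10           0         0           0
production                    2                   0           6         0           2
regulated_decoy               0                   2           0         8           0
stationary                    0                   0           0         0          10
0.9
```

Read: 36/40 genes generated by the four kinetic variants recover their
generating class (the four misses are weakly-translated production genes
falling to the mathematically simpler classes); 8/10 decoy genes — whose
translation rate steps by ≥5-fold mid-development, dynamics outside every
constant-parameter variant — are correctly rejected.  The classification
table itself carries, per gene, the
selected class and parameters (y0, λ, α, τ), χ², per-variant BH-adjusted
p-values, the half-life with profile-likelihood CI and a short/long call
against the cohort median, and steady-state flags.

The same pipeline runs from the shell:

```sh
protdyn simulate --seed 1 --n-per-class 10 --out data/
protdyn classify --mrna data/mrna.tsv --protein data/protein.tsv \
                 --bootstrap-B 200 --seed 1 --out results/
protdyn classify --mrna data/mrna.tsv --protein data/protein.tsv \
                 --min-time 3 --out results_postmzt/   # post-MZT window only
protdyn correlate --mrna data/mrna.tsv --protein data/protein.tsv --out corr/
```

The numbered scripts under `analysis/` run the same steps as a narrative
(simulate → classify → benchmark → correlate/cluster) writing their tables
under `results/`.

## Repository layout

- `src/protdyn/` — the library: `models` (closed-form ODE solutions),
  `fitting` (error model, multistart WLS), `gof` (bootstrap χ²/DW, BH),
  `selection` (LRT walk, re-assignment), `uncertainty` (profile CIs,
  half-life/steady-state), `pipeline` (end-to-end classification),
  `correlation` (shifted Spearman, clustering, hypergeometric),
  `simulate` (ground-truth generator), `io`, `cli`.
- `analysis/` — numbered drivers over the library.
- `docs/methods.md` — model, assumptions, parameter defaults, numerical
  choices and limitations.
- `scripts/acceptance.py` — recomputes the package's main result from
  scratch: simulates a fresh ground-truth benchmark, classifies it with the
  full pipeline and prints the recovery summary, writing its JSON to
  `--out`.  Run as

  ```sh
  python scripts/acceptance.py --seed 1 --out results/acceptance.json
  ```
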