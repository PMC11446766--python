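# ibaskit

Self-evolving classifier tuning for clinical risk prediction: an
**Improved Beetle Antennae Search (IBAS)** metaheuristic that evolves
classifier hyperparameters against a cross-validated fitness, plus the
clinical risk-factor statistics and evaluation pipeline it lives in,
exercised end-to-end on a synthetic diabetic-retinopathy-style
case-control cohort (150 subjects with retinopathy, 150 without, 19
routine clinical indicators).

It is written for biostatisticians and ML practitioners who want a
reproducible, headless version of this kind of "one-step" clinical
modelling workflow — from raw cohort CSV to risk report — and for anyone
who needs a well-tested BAS/IBAS implementation with the classical
23-function benchmark suite.

## The method

**BAS.** A beetle at `x` probes the objective at two antenna tips along
a random unit direction `b` and steps away from the worse tip:

```
x ← x − δ · b · sign(f(x + d·b) − f(x − d·b)),   d ← 0.95·d + 0.01,  δ ← 0.95·δ
```

**IBAS** improves this with (i) *piecewise chaotic-map initialization* —
the starting population is an orbit of a piecewise-linear chaotic map on
[0,1), spreading it near-uniformly over the search space; (ii)
*adaptive t-distribution mutation* — multiplicative Student-t
perturbations `x·(1+t)` whose degrees of freedom equal the iteration
index, heavy-tailed (global) early and near-Gaussian (local) late; and
(iii) *random-walk refinement* — the global best is polished by
neighbor sampling in a ball whose radius halves after N consecutive
failures. All operators are greedy and bound-clipped; runs are
bit-reproducible from a seed.

For hyperparameter evolution, IBAS searches the unit cube; a decoder
maps positions to mixed-type assignments (e.g. XGBoost learning rate ∈
[0.01, 1], max depth ∈ {1..20}, boosting rounds ∈ {1..100}), and the
fitness of an assignment is its mean stratified 5-fold ROC-AUC.

The clinical side implements the standard case-control analysis: a
pooled-variance t / Pearson χ² univariate screen, multivariate logistic
regression reporting β, SE, Wald = (β/SE)² on χ²(1), OR = exp(β) with
95% CIs, and per-subject risk probabilities through the inverse logit.

## Worked example

```python
import numpy as np
from ibaskit import benchmarks, cohort, hpo, optimizer, pipeline, stats

# 1. IBAS vs BAS on the 2-D sphere
sphere = benchmarks.list_functions(high_dim=2)[0]
space = optimizer.SearchSpace(sphere.lower, sphere.upper)
cfg = optimizer.OptimizerConfig(population_size=30, iterations=200, seed=1)
for variant in ("BAS", "IBAS"):
    res = optimizer.optimize(None, space, cfg, variant,
                             objective_batch=lambda X: benchmarks.batch_evaluate(sphere, X))
    print(variant, res.best.fitness)

# 2. Synthetic cohort + published-table statistics
table = cohort.generate(cohort.default_profile(), seed=11)
print(stats.two_sample_t(stats.TwoGroupSummary(64.18, 8.43, 150,
                                               60.87, 9.04, 150)).statistic)
print(stats.chi_square_2x2(97, 53, 64, 86).statistic)

# 3. One-step pipeline: split, clean, evolve, evaluate
pcfg = pipeline.PipelineConfig(model_kind="LR", population_size=6,
                               iteration_count=10, seed=1,
                               feature_selection=False)
report = pipeline.one_step(table, pcfg)
print(round(report.test_panel.ROC_AUC, 3))
```

prints

```
BAS 5.6061921252743693e-08
IBAS 4.7047714861520555e-39
3.279677437764387
14.598507529380223
0.999
```

The BAS/IBAS lines show the improved variant driving the 2-D sphere
some thirty orders of magnitude deeper than plain BAS at an identical
budget (on harder or higher-dimensional functions BAS stalls far from
the optimum; see the benchmark campaign).  `3.2797` and `14.5985` are
the age t-statistic and gender χ² recomputed from the published group
summaries, matching the printed `3.280` and `14.599`; `0.999` is the
held-out ROC-AUC of the evolved logistic model on the synthetic cohort
(the synthetic groups are well separated by HbA1c and the urinary
albumin/creatinine ratio, so near-perfect AUC is expected).

There is also a CLI — `ibaskit simulate | benchmark | optimize |
analyze | one-step | report` — covering the same steps from a shell;
`ibaskit one-step --data cohort.csv --out-dir run/` writes the JSON run
report, metric/convergence CSVs and the per-subject risk table.

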