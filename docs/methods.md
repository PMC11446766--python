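# Methods

`ibaskit` implements a "self-evolving" classifier-tuning workflow for
case-control clinical data — an Improved Beetle Antennae Search (IBAS)
metaheuristic that evolves classifier hyperparameters against a
cross-validated fitness — together with the surrounding clinical
statistics (univariate screening, multivariate logistic risk modelling)
and evaluation machinery, exercised end-to-end on a synthetic
diabetic-retinopathy-style cohort. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
test bed does and does not establish.

## The optimizer

**Baseline BAS.** Beetle Antennae Search is a directional search: from
position `x`, draw a random unit direction `b`, probe the objective at
the two antenna tips `x ± d·b`, and step `x ← x − δ·b·sign(f(x+d·b) −
f(x−d·b))`. We use the standard published formulation with geometric
schedules `d ← 0.95·d + 0.01` and `δ ← 0.95·δ` per iteration, greedy
acceptance (a move that worsens the objective is discarded), and clipping
to the box bounds. BAS is originally single-agent; to match a
population-of-30 protocol both variants here run a population of
independent beetles sharing only the global-best tracker.

**IBAS** adds three components:

1. *Piecewise chaotic initialization.* The initial population is an
   orbit of the piecewise-linear chaotic map on [0,1) (breakpoint
   parameter `P = 0.4`): `x/P` on [0,P), `(x−P)/(0.5−P)` on [P,0.5),
   `(1−P−x)/(0.5−P)` on [0.5,1−P), `(1−x)/P` on [1−P,1). Orbits of this
   map are dense and near-uniform, so the population spans the whole
   search space. States on the invariant set {0, P, 0.5, 1−P} would
   freeze the orbit and are nudged by 1e-12.
2. *Adaptive t-distribution mutation.* With probability `p_m = 0.5` per
   beetle per iteration, propose `x′ = x·(1 + t)` with i.i.d. Student-t
   coordinates whose degrees of freedom equal the iteration index:
   df = 1 gives Cauchy-like global jumps early, large df gives
   near-Gaussian local moves late. Multiplicative form (rather than
   additive) is assumed, as is common for t-mutations; greedy
   acceptance. A consequence worth knowing: the zero vector is a fixed
   point of the multiplicative perturbation.
3. *Random-walk refinement.* Each iteration the global best is polished
   by sampling neighbors uniformly in a ball of the current step radius
   (initial radius 10% of the mean bound width). After `N = 10`
   consecutive non-improving samples the radius halves; the walk stops
   below a threshold of 1e-6 of the mean bound width or after a hard cap
   of 1000 objective calls. Neighbors are drawn and evaluated in rounds
   of `N` (first improving draw wins, draw order preserved), which is
   equivalent to the one-at-a-time description of the halving rule and
   an order of magnitude faster in vectorized form.

Other conventions: positions are always clipped (never reflected); ties
keep the incumbent; minimization is canonical (wrap a maximization
objective with negation); all randomness flows from one seeded
generator, so identical configs and seeds give bit-identical traces.
Whether the random walk should run every iteration or only at
termination is ambiguous in the method's description; it runs on the
per-iteration best here, which is the stronger variant.

## Benchmark suite

The validation suite is the canonical 23-function collection (Sphere;
Schwefel 2.22/1.2/2.21; Rosenbrock; Step; noisy Quartic; Schwefel 2.26;
Rastrigin; Ackley; Griewank; two Penalized functions; Shekel's Foxholes;
Kowalik; Six-Hump Camel; Branin; Goldstein–Price; Hartmann 3/6; Shekel
5/7/10) with its standard bounds and the usual split into 7 unimodal and
16 multimodal functions. F1–F13 are dimension-scalable (30-D by default;
the campaign in the tests runs them at 10-D to keep a 23×2×30-run
campaign tractable on one CPU — a problem-size choice, the comparison is
qualitative either way). Non-analytic optima (Schwefel 2.26, Foxholes,
Kowalik, the Hartmanns, the Shekels) were refined numerically to ~1e-12
and frozen into the registry so the registry invariant — evaluating at
the stored minimizer reproduces the stored minimum within 1e-9 — is
testable. The noisy quartic adds uniform(0,1) noise from a
caller-supplied generator; evaluation without a generator is an error,
not silently deterministic. Out-of-bounds evaluation is an error rather
than a clip, so bound handling is owned by the optimizer alone.

Campaign protocol: population 30, 200 iterations, repeats with seeds
`base..base+r−1`, identical budgets for both variants, mean convergence
curves and final-best summaries exported as CSV. The test suite asserts
the qualitative claim — IBAS's mean final best no worse than BAS's on a
majority (≥12) of the 23 functions, and sub-1e-3 accuracy on the 2-D
sphere in ≥27/30 seeds. The observed margins are much larger (IBAS wins
22 of 23 at these budgets), but only the majority claim is asserted.

## Hyperparameter evolution

Search spaces (transcribed from the published tuning table): logistic
regression — inverse regularization strength C in [0.01, 100] grid step
10, penalty ∈ {L1, L2}; SVM (RBF) — C and gamma in [0.01, 100] step 10;
XGBoost — learning rate in [0.01, 1] step 0.1, max depth in [1, 20] step
0.5, boosting rounds in [1, 100] step 10. Grids include both endpoints
(the final point clipped to the upper bound); integer parameters round
each grid value half-up and drop duplicates, so the printed step 0.5 for
max depth yields the integers 1..20.

Fitness is the mean stratified k-fold (default k=5) metric — ROC-AUC by
default, accuracy or F1 optionally — with z-score normalization fitted
per training fold. The published protocol normalized the whole dataset
before modelling; that leaks validation statistics, so train-only
fitting is the default here and a global scope exists as an explicit
compatibility switch in the pipeline.

`evolve` runs IBAS over the unit hypercube with a decoder (continuous:
affine; integer: affine + round half-up; categorical: thresholded) and
objective `−cv_fitness(decode(·))`. Distinct assignments are cached, so
the classifier trains once per configuration. The random walk uses a
lighter budget here (initial step 0.25, threshold 0.02, ≤30 objective
calls per invocation) than in the benchmark setting: each objective call
costs k classifier fits, and hyperparameter surfaces do not reward 1e-6
resolution. Early stopping declares a plateau when the best fitness
improves by less than 1e-4 over 20 consecutive iterations ("no
significant improvement" made concrete). When early stopping triggers,
the convergence trace has as many entries as iterations actually run.

Joint feature selection — described for the one-step workflow but with
no stated mechanism — is provided as a clearly labelled interpretation:
one extra unit-cube dimension per feature, thresholded at 0.5, selects
the feature subset evaluated alongside the hyperparameters.

## Synthetic cohort

No patient data are distributed, so a generator emulates the published
two-group structure: 150 subjects per group, 19 indicators (15
continuous, 4 binary), with each group's printed mean ± SD or count
proportion transcribed verbatim. Continuous variables are Gaussians
truncated to clinically plausible ranges (e.g. non-negative biomarker
concentrations); binaries are Bernoulli. Gaussians matched to mean/SD
are the minimal model consistent with mean ± SD reporting; nothing
beyond the two-group first and second moments is emulated. Notes:

* Truncation biases moments. For most variables the truncated mass is
  negligible, but HDL-C (1.31 ± 0.81 mmol/L, floored at 0.1) loses ~7%
  of its left tail, shifting the realized mean by ≈ +0.11. Moment tests
  therefore compare against the analytic truncated-normal mean (the
  generator's actual target), not the printed mean.
* Predictors are independent by default. An optional preset adds
  clinically motivated correlations (SBP–DBP 0.6, FPG–HbA1c 0.6, TC–LDL
  0.7) for robustness testing only; those values are engineering
  choices. Under a supplied correlation the continuous block is
  multivariate normal with values clipped (not resampled) at the range
  edges.
* Binary coding is 1 = male / yes; non-pharmacological treatment is
  coded 1 = receives it, so its fitted log-odds coefficient should be
  negative (protective), mirroring the published direction.
* The source table prints glucose units as "μmol/L" (plausibly a typo
  for mmol/L); units are carried verbatim as metadata with this caveat.
* Power at n=150/group follows the printed effect sizes: HbA1c (d≈1.2)
  and UACR (d≈2.9) are flagged essentially always; drinking history and
  BMI are near-null and flagged at ≈ the nominal α rate. At much larger
  n even the near-null differences become significant, so the screening
  property is asserted at the published group size.

Passing tests on this cohort show the pipeline's machinery is sound
under the stated moments; they do not establish clinical performance —
real cohorts have correlated, skewed, non-Gaussian indicators and
missingness that is not completely at random (the injector here is
MCAR by construction).

## Clinical statistics

Univariate screening: pooled-variance two-sample t (not Welch) for
continuous variables and Pearson chi-square without continuity
correction for 2×2 tables — the conventions under which every
recomputable printed statistic is matched within 0.001. Constant columns
yield a flagged zero-statistic result instead of an error. Multivariate
analysis enters all univariately significant predictors on their
original scale with no stepwise elimination; the source's published
model shows a smaller subset whose selection rule is unstated, so the
full model is reported. The MLE is fit by statsmodels' Newton/IRLS; SEs
come from the inverse observed information; Wald = (β/SE)² against
χ²(1); OR = exp(β). Perfect separation and rank deficiency raise errors
naming the offending columns. Two CI conventions exist because the
published intervals match `OR ± 1.96·SE(β)` rather than the standard
`exp(β ± 1.96·SE)`; the standard form is the default and neither is
asserted correct.

## Evaluation

PRE/SEN/SPE/ACC/F1 come from the confusion matrix at "score ≥ threshold
⇒ positive" (default threshold 0.5; the positive class is retinopathy).
Ratios with zero denominators are reported as undefined (`None`), never
coerced to 0. ROC-AUC is the Mann–Whitney pair-probability with ties
counted half; PR-AUC is average precision. Both delegate to scikit-learn
and are cross-checked in the tests against exhaustive pair counting and
hand-stepped AP sums. Stratified k-fold assignment is deterministic
given a seed and errors when any class is smaller than k.

## One-step pipeline

`one_step` performs: stratified 80/20 split → cleaning fitted on
training rows only (median/mode imputation; winsorization at median ±
3·IQR/1.349, a robust 3σ rule; z-score normalization; optional seeded
minority oversampling of training rows) → IBAS hyperparameter evolution
(optional joint feature mask) on the training portion → final refit →
one evaluation of the held-out test set → per-subject risk probabilities
banded high/low at a configurable threshold (exactly 0.5 ⇒ high). The
report is reproducible byte-for-byte from config + seed; a leakage test
poisons test rows with sentinels and asserts every training-fitted
artifact is unchanged. The specific imputation/outlier/balancing rules
are not prescribed by the source workflow; simple deterministic choices
are fixed and logged per run.

## Problem sizes in the checked runs

The test suite and `scripts/acceptance.py` choose sizes that keep a
full run practical on one CPU while preserving each claim's meaning:
benchmark campaign at 10-D for the scalable functions (30 repeats in the
tests, 12 in the acceptance script); grid-vs-evolve comparison on the
logistic-regression space (the XGBoost grid as printed is 11×20×11 =
2420 cells × 5 folds, which buys no additional insight for the
comparison); evolution budgets of population 10 × 30 iterations for
hyperparameter runs; parameter recovery at n=400 × 200 replicates. The
planted-optimum check uses an XOR-style interaction: depth-1 boosting
(additive in features) cannot represent it, depth ≥ 2 can, so recovering
a depth ≥ 2 assignment with near-oracle fitness demonstrates the evolver
escapes a structurally suboptimal region.

## Known limitations

* The exact BAS/IBAS update equations and the 23-function list are not
  printed in the source; the standard formulations were adopted and are
  documented above. Published convergence-curve values are therefore
  not reproduced — only the qualitative BAS-vs-IBAS ordering.
* Published classifier performance tables derive from a private cohort
  and are out of reach; the pipeline's metrics here describe the
  synthetic cohort only.
* No nested cross-validation: the reported CV fitness of the selected
  assignment is an optimistically biased estimate of generalization.
* No multiple-testing correction in the univariate screen (the source
  applies none either).
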