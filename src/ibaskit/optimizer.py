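"""Beetle Antennae Search (BAS) and its improved variant (IBAS).

BAS is a directional metaheuristic: a beetle at position ``x`` probes the
objective at two antenna tips ``x + d*b`` and ``x - d*b`` along a random
unit direction ``b`` and steps away from the worse tip,
``x <- x - delta * b * sign(f(x_r) - f(x_l))``, with antenna length ``d``
and step ``delta`` decaying geometrically each iteration.

IBAS layers three improvements on a population of 30 such beetles:

* **piecewise chaotic initialization** — the initial population is an
  orbit of a piecewise-linear chaotic map on [0, 1), spreading candidates
  near-uniformly over the search space;
* **adaptive t-distribution mutation** — each beetle's position is
  perturbed multiplicatively by Student-t noise whose degrees of freedom
  equal the iteration index, so early moves are heavy-tailed (global) and
  late moves near-Gaussian (local);
* **random-walk refinement** — the global best is polished by sampling
  neighbors in a shrinking ball; the radius halves after ``N`` consecutive
  failures and the walk stops below a step threshold.

All operators are greedy (a retained candidate is never worse than its
input), all positions are clipped to the box bounds, and every source of
randomness flows from one seeded generator, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import benchmarks

VARIANTS = ("BAS", "IBAS")


@dataclass(frozen=True)
class SearchSpace:
    """Box-constrained continuous domain."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower/upper must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if not np.all(lo < hi):
            raise ValueError("lower must be strictly below upper in every dimension")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dims(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.width))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass
class Candidate:
    position: np.ndarray
    fitness: Optional[float] = None
    origin: str = "init"  # init | bas_step | mutation | random_walk


@dataclass(frozen=True)
class OptimizerConfig:
    """Tuning knobs; ``None`` geometry fields default relative to the space.

    ``antenna_length_init``, ``step_init`` and the walk step sizes default
    to fractions of the mean bound width (0.1, 0.1, 0.1 and 1e-6
    respectively) so one config works across domains of any scale.
    """

    population_size: int = 30
    iterations: int = 200
    seed: int = 0
    antenna_length_init: Optional[float] = None
    step_init: Optional[float] = None
    decay: float = 0.95
    antenna_floor: float = 0.01
    mutation_probability: float = 0.5
    walk_failure_budget: int = 10
    walk_step_init: Optional[float] = None
    walk_step_threshold: Optional[float] = None
    walk_max_evals: int = 1000
    chaotic_P: float = 0.4
    early_stop_tol: Optional[float] = None
    early_stop_patience: Optional[int] = None

    def __post_init__(self):
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.iterations < 1:
            raise ValueError("iteration budget must be >= 1")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")
        if not 0.0 <= self.mutation_probability <= 1.0:
            raise ValueError("mutation_probability must be in [0, 1]")
        if self.walk_failure_budget < 1:
            raise ValueError("walk_failure_budget must be >= 1")
        if not 0.0 < self.chaotic_P < 0.5:
            raise ValueError("chaotic_P must be in (0, 0.5)")
        if (self.walk_step_init is not None
                and self.walk_step_threshold is not None
                and not self.walk_step_threshold < self.walk_step_init):
            raise ValueError("walk_step_threshold must be below walk_step_init")

    def antenna0(self, space: SearchSpace) -> float:
        return (self.antenna_length_init if self.antenna_length_init is not None
                else 0.1 * space.mean_width)

    def delta0(self, space: SearchSpace) -> float:
        return (self.step_init if self.step_init is not None
                else 0.1 * space.mean_width)

    def walk_init(self, space: SearchSpace) -> float:
        return (self.walk_step_init if self.walk_step_init is not None
                else 0.1 * space.mean_width)

    def walk_threshold(self, space: SearchSpace) -> float:
        return (self.walk_step_threshold if self.walk_step_threshold is not None
                else 1e-6 * space.mean_width)


@dataclass(frozen=True)
class ConvergenceTrace:
    best_fitness_per_iteration: np.ndarray
    evaluations_used: int


@dataclass(frozen=True)
class OptResult:
    best: Candidate
    trace: ConvergenceTrace
    variant: str
    config: OptimizerConfig


# -------------------------------------------------------- chaotic sampling

def _piecewise_map(x: np.ndarray, P: float) -> np.ndarray:
    y = np.empty_like(x)
    m1 = x < P
    m2 = (x >= P) & (x < 0.5)
    m3 = (x >= 0.5) & (x < 1.0 - P)
    m4 = x >= 1.0 - P
    y[m1] = x[m1] / P
    y[m2] = (x[m2] - P) / (0.5 - P)
    y[m3] = (1.0 - P - x[m3]) / (0.5 - P)
    y[m4] = (1.0 - x[m4]) / P
    return y


def _nudge(x: np.ndarray, P: float) -> np.ndarray:
    # fixed points / pre-images of fixed points would freeze the orbit
    for bad in (0.0, P, 0.5, 1.0 - P, 1.0):
        x = np.where(np.abs(x - bad) < 1e-12, x + 1e-12, x)
    return np.clip(x, 1e-12, 1.0 - 1e-12)


def piecewise_chaotic_sample(n: int, dims: int, P: float = 0.4,
                             seed: Optional[int] = None,
                             rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """``(n, dims)`` matrix whose columns are orbits of the piecewise map.

    The map on [0, 1) is ``x/P`` on [0, P), ``(x-P)/(0.5-P)`` on [P, 0.5),
    ``(1-P-x)/(0.5-P)`` on [0.5, 1-P) and ``(1-x)/P`` on [1-P, 1).  The
    first row is the seeded initial state.
    """
    if n < 1 or dims < 1:
        raise ValueError("n and dims must be >= 1")
    if not 0.0 < P < 0.5:
        raise ValueError("chaotic map parameter P must be in (0, 0.5)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.empty((n, dims))
    x = _nudge(rng.uniform(size=dims), P)
    out[0] = x
    for k in range(1, n):
        x = _nudge(_piecewise_map(x, P), P)
        out[k] = x
    return out


def scale_to_bounds(unit: np.ndarray, space: SearchSpace) -> list[Candidate]:
    """Affinely map unit-cube rows onto the search space as candidates."""
    unit = np.asarray(unit, dtype=float)
    if unit.ndim != 2 or unit.shape[1] != space.dims:
        raise ValueError(
            f"unit matrix must have {space.dims} columns, got shape {unit.shape}"
        )
    pos = space.lower + unit * space.width
    return [Candidate(position=p, fitness=None, origin="init") for p in pos]


# -------------------------------------------------------------- evaluation

def _checked(objective: Callable, x: np.ndarray) -> float:
    v = float(objective(x))
    if not np.isfinite(v):
        raise FloatingPointError(f"objective returned non-finite value at {x!r}")
    return v


class _Evaluator:
    """Counts objective calls; uses a row-batched objective when given."""

    def __init__(self, objective: Optional[Callable],
                 objective_batch: Optional[Callable] = None):
        if objective is None and objective_batch is None:
            raise ValueError("an objective is required")
        self.objective = objective
        self.objective_batch = objective_batch
        self.count = 0

    def one(self, x: np.ndarray) -> float:
        self.count += 1
        if self.objective is not None:
            v = float(self.objective(x))
        else:
            v = float(np.asarray(self.objective_batch(x[None, :]))[0])
        if not np.isfinite(v):
            raise FloatingPointError(f"objective returned non-finite value at {x!r}")
        return v

    def many(self, X: np.ndarray) -> np.ndarray:
        self.count += X.shape[0]
        if self.objective_batch is not None:
            v = np.asarray(self.objective_batch(X), dtype=float)
        else:
            v = np.array([float(self.objective(row)) for row in X])
        if not np.all(np.isfinite(v)):
            bad = X[~np.isfinite(v)][0]
            raise FloatingPointError(f"objective returned non-finite value at {bad!r}")
        return v


# ---------------------------------------------------------------- operators

def _unit_direction(rng: np.random.Generator, dims: int) -> np.ndarray:
    b = rng.standard_normal(dims)
    nrm = np.linalg.norm(b)
    while nrm == 0.0:  # pragma: no cover - probability zero
        b = rng.standard_normal(dims)
        nrm = np.linalg.norm(b)
    return b / nrm


def bas_step(c: Candidate, objective: Callable, d: float, delta: float,
             space: SearchSpace, rng: np.random.Generator) -> Candidate:
    """One antennae probe-and-step with greedy retention."""
    if d <= 0 or delta <= 0:
        raise ValueError("antenna length and step must be positive")
    ev = _Evaluator(objective)
    if c.fitness is None:
        c = replace_fitness(c, ev.one(c.position))
    b = _unit_direction(rng, space.dims)
    fr = ev.one(space.clip(c.position + d * b))
    fl = ev.one(space.clip(c.position - d * b))
    x_new = space.clip(c.position - delta * b * np.sign(fr - fl))
    f_new = ev.one(x_new)
    if f_new < c.fitness:
        return Candidate(position=x_new, fitness=f_new, origin="bas_step")
    return c


def t_mutation(c: Candidate, iteration: int, p_m: float, objective: Callable,
               space: SearchSpace, rng: np.random.Generator) -> Candidate:
    """Multiplicative Student-t perturbation with df = iteration index."""
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    if rng.uniform() >= p_m:
        return c
    ev = _Evaluator(objective)
    if c.fitness is None:
        c = replace_fitness(c, ev.one(c.position))
    t = rng.standard_t(df=iteration, size=space.dims)
    x_new = space.clip(c.position * (1.0 + t))
    f_new = ev.one(x_new)
    if f_new < c.fitness:
        return Candidate(position=x_new, fitness=f_new, origin="mutation")
    return c


def replace_fitness(c: Candidate, fitness: float) -> Candidate:
    return Candidate(position=c.position, fitness=fitness, origin=c.origin)


def _ball_points(rng: np.random.Generator, center: np.ndarray, radius: float,
                 count: int, space: SearchSpace) -> np.ndarray:
    dirs = rng.standard_normal((count, space.dims))
    nrm = np.linalg.norm(dirs, axis=1, keepdims=True)
    nrm[nrm == 0.0] = 1.0
    radii = radius * rng.uniform(size=count) ** (1.0 / space.dims)
    return space.clip(center + dirs / nrm * radii[:, None])


def random_walk(c: Candidate, objective: Callable, cfg: OptimizerConfig,
                space: SearchSpace, rng: np.random.Generator,
                objective_batch: Optional[Callable] = None) -> Candidate:
    """Shrinking-ball hill climb around the incumbent.

    Neighbors are sampled uniformly in the ball of the current step
    radius; ``walk_failure_budget`` consecutive non-improving samples
    halve the step, and the walk stops when the step falls below the
    threshold or the evaluation cap is hit.  Samples are drawn and
    evaluated in rounds of ``walk_failure_budget`` (draw order preserved),
    which is equivalent to the one-at-a-time description.
    """
    ev = _Evaluator(objective, objective_batch)
    x = np.array(c.position, dtype=float)
    f = c.fitness if c.fitness is not None else ev.one(x)
    x, f = _walk(ev, x, f, cfg, space, rng)
    return Candidate(position=x, fitness=float(f), origin="random_walk")


def _walk(ev: _Evaluator, x: np.ndarray, f: float, cfg: OptimizerConfig,
          space: SearchSpace, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    step = cfg.walk_init(space)
    threshold = cfg.walk_threshold(space)
    if not 0.0 < threshold < step:
        raise ValueError("walk_step_threshold must satisfy 0 < threshold < step_init")
    used = 0
    while step >= threshold and used < cfg.walk_max_evals:
        batch = min(cfg.walk_failure_budget, cfg.walk_max_evals - used)
        pts = _ball_points(rng, x, step, batch, space)
        fs = ev.many(pts)
        better = np.flatnonzero(fs < f)
        used += batch
        if better.size:
            # move to the first improving neighbor (draw order); samples
            # after it are discarded but still count against the budget
            j = int(better[0])
            x, f = pts[j], float(fs[j])
        elif batch == cfg.walk_failure_budget:
            step *= 0.5
    return x, float(f)


# ----------------------------------------------------------------- driver

def optimize(objective: Optional[Callable], space: SearchSpace,
             cfg: OptimizerConfig, variant: str = "IBAS",
             objective_batch: Optional[Callable] = None) -> OptResult:
    """Run one population optimization and return best + trace.

    BAS: uniform random init, one antennae step per beetle per iteration.
    IBAS: chaotic init; per iteration each beetle takes an antennae step
    then a t-mutation, and the global best is refined by a random walk.
    Both decay ``d`` and ``delta`` geometrically per iteration and track
    the best-so-far fitness (minimization).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(objective, objective_batch)
    pop, dims = cfg.population_size, space.dims

    if variant == "IBAS":
        unit = piecewise_chaotic_sample(pop, dims, cfg.chaotic_P, rng=rng)
    else:
        unit = rng.uniform(size=(pop, dims))
    X = space.lower + unit * space.width
    F = ev.many(X)

    ibest = int(np.argmin(F))
    gx, gf, gorigin = X[ibest].copy(), float(F[ibest]), "init"

    d = cfg.antenna0(space)
    delta = cfg.delta0(space)
    trace: list[float] = []
    stall = 0
    for it in range(1, cfg.iterations + 1):
        prev_best = gf
        # --- antennae step (vectorized across the population) ---
        B = rng.standard_normal((pop, dims))
        nrm = np.linalg.norm(B, axis=1, keepdims=True)
        nrm[nrm == 0.0] = 1.0
        B /= nrm
        fr = ev.many(space.clip(X + d * B))
        fl = ev.many(space.clip(X - d * B))
        Xn = space.clip(X - delta * B * np.sign(fr - fl)[:, None])
        Fn = ev.many(Xn)
        moved = Fn < F
        X[moved], F[moved] = Xn[moved], Fn[moved]

        if variant == "IBAS":
            # --- adaptive t mutation, df = iteration index ---
            mask = rng.uniform(size=pop) < cfg.mutation_probability
            T = rng.standard_t(df=it, size=(pop, dims))
            if np.any(mask):
                Xm = space.clip(X[mask] * (1.0 + T[mask]))
                Fm = ev.many(Xm)
                rows = np.flatnonzero(mask)[Fm < F[mask]]
                X[rows] = Xm[Fm < F[mask]]
                F[rows] = Fm[Fm < F[mask]]

        ibest = int(np.argmin(F))
        if F[ibest] < gf:
            gx, gf = X[ibest].copy(), float(F[ibest])
            gorigin = "bas_step" if variant == "BAS" else "mutation"

        if variant == "IBAS":
            wx, wf = _walk(ev, gx.copy(), gf, cfg, space, rng)
            if wf < gf:
                gx, gf, gorigin = wx, wf, "random_walk"
                worst = int(np.argmax(F))
                X[worst], F[worst] = gx.copy(), gf

        d = cfg.decay * d + cfg.antenna_floor
        delta = cfg.decay * delta
        trace.append(gf)

        if cfg.early_stop_tol is not None and cfg.early_stop_patience:
            stall = stall + 1 if prev_best - gf < cfg.early_stop_tol else 0
            if stall >= cfg.early_stop_patience:
                break

    best = Candidate(position=gx, fitness=gf, origin=gorigin)
    return OptResult(best=best,
                     trace=ConvergenceTrace(np.asarray(trace), ev.count),
                     variant=variant, config=cfg)


def benchmark_campaign(functions: Sequence[benchmarks.BenchmarkFunction],
                       cfg: OptimizerConfig, repeats: int = 30,
                       variants: Sequence[str] = VARIANTS,
                       seed_base: int = 1
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched-budget BAS-vs-IBAS campaign over the given functions.

    Each (function, variant) pair runs with seeds ``seed_base ..
    seed_base+repeats-1``; returns per-iteration mean/sd best-so-far
    curves and a final-best summary.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    curve_rows, summary_rows = [], []
    for fn in functions:
        space = SearchSpace(fn.lower, fn.upper)
        for variant in variants:
            finals = []
            traces = []
            for seed in range(seed_base, seed_base + repeats):
                noise_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=(fn.id, seed)))
                batch = (lambda Xb, _fn=fn, _r=noise_rng:
                         benchmarks.batch_evaluate(_fn, Xb, _r))
                res = optimize(None, space, replace(cfg, seed=seed),
                               variant=variant, objective_batch=batch)
                traces.append(res.trace.best_fitness_per_iteration)
                finals.append(res.best.fitness)
            traces = np.vstack(traces)
            mean_curve = traces.mean(axis=0)
            sd_curve = traces.std(axis=0, ddof=1) if repeats > 1 else np.zeros_like(mean_curve)
            for i, (m, s) in enumerate(zip(mean_curve, sd_curve), start=1):
                curve_rows.append({"function_id": fn.id, "variant": variant,
                                   "iteration": i, "mean_best": m, "sd_best": s})
            finals = np.asarray(finals, dtype=float)
            summary_rows.append({
                "function_id": fn.id, "function": fn.name, "variant": variant,
                "mean_final": float(finals.mean()),
                "sd_final": float(finals.std(ddof=1)) if repeats > 1 else 0.0,
            })
    return pd.DataFrame(curve_rows), pd.DataFrame(summary_rows)
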