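"""Unit and property tests for the BAS/IBAS optimizer core."""

import numpy as np
import pytest

from ibaskit import benchmarks as B
from ibaskit import optimizer as O

SPHERE2 = B.list_functions(high_dim=2)[0]
SPACE2 = O.SearchSpace(SPHERE2.lower, SPHERE2.upper)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


# ------------------------------------------------------- chaotic sampling

def test_piecewise_map_first_branch():
    # 0.2 with P=0.4 falls in [0, P): next state 0.2/0.4 = 0.5
    out = O._piecewise_map(np.array([0.2]), 0.4)
    assert out[0] == pytest.approx(0.5)


def test_chaotic_sample_deterministic_and_in_unit_interval():
    a = O.piecewise_chaotic_sample(30, 30, P=0.4, seed=3)
    b = O.piecewise_chaotic_sample(30, 30, P=0.4, seed=3)
    assert np.array_equal(a, b)
    assert a.shape == (30, 30)
    assert np.all((a >= 0.0) & (a < 1.0))


def test_chaotic_orbit_spans_most_of_unit_interval():
    """Orbits of the piecewise map are mixing: over 30 steps every
    coordinate should cover at least 0.8 of [0, 1)."""
    sample = O.piecewise_chaotic_sample(30, 30, P=0.4, seed=1)
    spans = sample.max(axis=0) - sample.min(axis=0)
    assert np.all(spans >= 0.8)


def test_chaotic_sample_validates_P():
    with pytest.raises(ValueError, match="P"):
        O.piecewise_chaotic_sample(5, 2, P=0.6, seed=0)


def test_scale_to_bounds_affine_endpoints():
    space = O.SearchSpace(np.array([-5.0, 0.0]), np.array([5.0, 100.0]))
    cands = O.scale_to_bounds(np.array([[0.0, 0.5], [0.999, 0.0]]), space)
    assert cands[0].position[0] == pytest.approx(-5.0)
    assert cands[0].position[1] == pytest.approx(50.0)
    assert all(space.contains(c.position) for c in cands)
    assert all(c.fitness is None and c.origin == "init" for c in cands)
    with pytest.raises(ValueError, match="columns"):
        O.scale_to_bounds(np.zeros((3, 3)), space)


# -------------------------------------------------------------- operators

def test_bas_step_is_greedy_and_descends_a_monotone_slope(rng):
    space = O.SearchSpace(np.array([-10.0]), np.array([10.0]))
    c = O.Candidate(np.array([1.0]), fitness=1.0)
    # tiny antenna senses the true slope; the move goes toward the optimum
    out = O.bas_step(c, sphere, d=1e-8, delta=0.1, space=space, rng=rng)
    assert out.position[0] == pytest.approx(0.9)
    assert out.fitness <= c.fitness
    for _ in range(50):
        cur = O.Candidate(rng.uniform(-10, 10, size=1))
        res = O.bas_step(cur, sphere, d=0.5, delta=1.0, space=space, rng=rng)
        assert res.fitness <= sphere(cur.position)
        assert space.contains(res.position)


def test_bas_iteration_beats_pure_random_search():
    """30 seeded runs of repeated antennae steps on the 2-D sphere beat a
    naive uniform random search given the same evaluation budget."""
    space = O.SearchSpace(np.array([-100.0, -100.0]), np.array([100.0, 100.0]))
    bas_final, rand_final = [], []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        c = O.Candidate(rng.uniform(-100, 100, size=2))
        c = O.replace_fitness(c, sphere(c.position))
        d, delta = 20.0, 20.0
        for _ in range(200):
            c = O.bas_step(c, sphere, d=d, delta=delta, space=space, rng=rng)
            d = 0.95 * d + 0.01
            delta *= 0.95
        bas_final.append(c.fitness)
        pts = rng.uniform(-100, 100, size=(601, 2))
        rand_final.append(np.min(np.sum(pts ** 2, axis=1)))
    assert np.mean(bas_final) < np.mean(rand_final)


def test_t_mutation_zero_vector_is_fixed_point(rng):
    space = O.SearchSpace(np.array([-1.0, -1.0]), np.array([1.0, 1.0]))
    c = O.Candidate(np.zeros(2), fitness=0.0)
    out = O.t_mutation(c, iteration=1, p_m=1.0, objective=sphere,
                       space=space, rng=rng)
    assert np.array_equal(out.position, np.zeros(2))


def test_t_mutation_is_greedy_and_respects_probability(rng):
    space = O.SearchSpace(np.array([-5.0] * 3), np.array([5.0] * 3))
    for _ in range(50):
        c = O.Candidate(rng.uniform(-5, 5, size=3))
        c = O.replace_fitness(c, sphere(c.position))
        out = O.t_mutation(c, iteration=3, p_m=1.0, objective=sphere,
                           space=space, rng=rng)
        assert out.fitness <= c.fitness
        assert space.contains(out.position)
    c = O.Candidate(np.ones(3), fitness=3.0)
    out = O.t_mutation(c, iteration=1, p_m=0.0, objective=sphere,
                       space=space, rng=rng)
    assert out is c


def test_low_df_mutation_has_heavier_tails():
    """The adaptive schedule relies on df=1 proposals jumping far more
    often than late-iteration (df=200) proposals."""
    rng = np.random.default_rng(42)
    early = rng.standard_t(df=1, size=100_000)
    late = rng.standard_t(df=200, size=100_000)
    assert np.mean(np.abs(early) > 6) > 20 * max(np.mean(np.abs(late) > 6), 1e-6)


def test_random_walk_never_degrades_and_descends_convex_bowl():
    space = O.SearchSpace(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))
    cfg = O.OptimizerConfig(walk_step_init=0.5, walk_step_threshold=1e-3,
                            walk_failure_budget=10)
    finals = []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        c = O.Candidate(np.array([1.0, 1.0]), fitness=2.0)
        out = O.random_walk(c, sphere, cfg, space, rng)
        assert out.fitness <= c.fitness
        assert space.contains(out.position)
        finals.append(out.fitness)
    assert all(f < 2.0 for f in finals)


def test_random_walk_respects_evaluation_cap():
    space = O.SearchSpace(np.array([-5.0]), np.array([5.0]))
    cfg = O.OptimizerConfig(walk_step_init=1.0, walk_step_threshold=1e-12,
                            walk_max_evals=100)
    calls = []

    def counting(x):
        calls.append(1)
        return sphere(x)

    O.random_walk(O.Candidate(np.array([2.0]), fitness=4.0), counting, cfg,
                  space, np.random.default_rng(0))
    assert len(calls) <= 100


# ----------------------------------------------------------------- driver

@pytest.mark.parametrize("variant", ["BAS", "IBAS"])
def test_optimize_trace_monotone_and_deterministic(variant):
    cfg = O.OptimizerConfig(population_size=10, iterations=50, seed=9)
    run = lambda: O.optimize(None, SPACE2, cfg, variant,
                             objective_batch=lambda X: B.batch_evaluate(SPHERE2, X))
    r1, r2 = run(), run()
    tr = r1.trace.best_fitness_per_iteration
    assert len(tr) == 50
    assert np.all(np.diff(tr) <= 0)
    assert r1.best.fitness == tr[-1] == np.min(tr)
    assert SPACE2.contains(r1.best.position)
    assert np.array_equal(tr, r2.trace.best_fitness_per_iteration)
    assert r1.trace.evaluations_used == r2.trace.evaluations_used


def test_bas_evaluation_budget_is_analytic():
    """BAS evaluates pop (init) + 3*pop*iters (two probes + one move)."""
    calls = []

    def counting(x):
        calls.append(1)
        return sphere(x)

    cfg = O.OptimizerConfig(population_size=7, iterations=13, seed=2)
    res = O.optimize(counting, SPACE2, cfg, "BAS")
    expected = 7 + 3 * 7 * 13
    assert len(calls) == expected == res.trace.evaluations_used


def test_ibas_evaluation_counter_matches_actual_calls():
    calls = []

    def counting(x):
        calls.append(1)
        return sphere(x)

    cfg = O.OptimizerConfig(population_size=5, iterations=10, seed=2,
                            walk_max_evals=50)
    res = O.optimize(counting, SPACE2, cfg, "IBAS")
    assert len(calls) == res.trace.evaluations_used


def test_ibas_solves_small_sphere():
    cfg = O.OptimizerConfig(population_size=30, iterations=200, seed=1)
    res = O.optimize(None, SPACE2, cfg, "IBAS",
                     objective_batch=lambda X: B.batch_evaluate(SPHERE2, X))
    assert res.best.fitness < 1e-3


def test_invalid_iteration_budget_rejected():
    with pytest.raises(ValueError, match="iteration"):
        O.OptimizerConfig(iterations=0)


def test_campaign_single_repeat_equals_single_run():
    fns = B.list_functions(high_dim=2)[:2]
    cfg = O.OptimizerConfig(population_size=5, iterations=20, seed=0)
    curves, summary = O.benchmark_campaign(fns, cfg, repeats=1)
    assert set(summary.variant) == {"BAS", "IBAS"}
    assert len(summary) == 4
    one = curves[(curves.function_id == 1) & (curves.variant == "IBAS")]
    res = O.optimize(None, O.SearchSpace(fns[0].lower, fns[0].upper),
                     O.OptimizerConfig(population_size=5, iterations=20, seed=1),
                     "IBAS",
                     objective_batch=lambda X: B.batch_evaluate(fns[0], X))
    assert np.allclose(one.mean_best.to_numpy(),
                       res.trace.best_fitness_per_iteration)
    assert np.all(one.sd_best.to_numpy() == 0.0)
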