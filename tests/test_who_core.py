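import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from who_select.who_core import (
    BoundsError,
    BoundsSpec,
    Candidate,
    ConfigError,
    EvaluationError,
    MillingSet,
    PeerSelectionError,
    Population,
    RandomSource,
    WHOConfig,
    herd_instinct,
    herd_pressure,
    initialize_population,
    local_update,
    milling,
    optimize,
    social_memory,
    starvation_avoidance,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class StubRng(RandomSource):
    """Injects a fixed sequence of theta / unit-vector draws."""

    def __init__(self, thetas=(), vectors=(), integers=()):
        super().__init__(0)
        self._thetas = list(thetas)
        self._vectors = [np.asarray(v, dtype=float) for v in vectors]
        self._integers = list(integers)

    def theta(self):
        return self._thetas.pop(0)

    def unit_vector(self, dimension):
        return self._vectors.pop(0)

    def integer(self, n):
        return self._integers.pop(0)


class TestBoundsSpec:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(BoundsError):
            BoundsSpec(np.array([0.0, 2.0]), np.array([1.0, 1.0]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(BoundsError):
            BoundsSpec(np.array([0.0]), np.array([1.0, 2.0]))

    def test_clamp_and_contains(self):
        b = BoundsSpec.cube(0.0, 1.0, 3)
        clamped = b.clamp(np.array([-1.0, 0.5, 2.0]))
        assert np.allclose(clamped, [0.0, 0.5, 1.0])
        assert b.contains(clamped)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 1},
            {"iterations": 0},
            {"milling_steps": 0},
            {"crowding_threshold": 0.0},
            {"social_memory_radius": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            WHOConfig(**kwargs)

    def test_resolve_fills_bounds_dependent_defaults(self):
        b = BoundsSpec.cube(-5.0, 5.0, 4)
        cfg = WHOConfig().resolve(b)
        assert cfg.learning_rate == pytest.approx(1.0)  # 0.1 * mean(range)
        assert cfg.crowding_threshold == pytest.approx(0.3 * np.sqrt(4 * 100.0))


class TestRandomSource:
    def test_unit_vector_norm(self):
        rng = RandomSource(5)
        for d in (1, 2, 7, 30):
            assert abs(np.linalg.norm(rng.unit_vector(d)) - 1.0) < 1e-12

    def test_same_seed_same_sequence(self):
        a, b = RandomSource(9), RandomSource(9)
        assert [a.theta() for _ in range(5)] == [b.theta() for _ in range(5)]
        assert np.array_equal(a.unit_vector(4), b.unit_vector(4))


class TestInitializePopulation:
    def test_containment(self):
        b = BoundsSpec.cube(0.0, 1.0, 5)
        pop = initialize_population(b, WHOConfig(population_size=30), RandomSource(0))
        assert len(pop.candidates) == 30
        assert all(b.contains(c.position) for c in pop.candidates)
        assert all(c.fitness is None for c in pop.candidates)
        assert pop.iteration == 0

    def test_degenerate_interval(self):
        b = BoundsSpec(np.array([0.5]), np.array([0.5]))
        pop = initialize_population(b, WHOConfig(), RandomSource(0))
        assert all(c.position[0] == 0.5 for c in pop.candidates)

    def test_same_seed_identical(self):
        b = BoundsSpec.cube(-2.0, 2.0, 3)
        p1 = initialize_population(b, WHOConfig(seed=4), RandomSource(4))
        p2 = initialize_population(b, WHOConfig(seed=4), RandomSource(4))
        for c1, c2 in zip(p1.candidates, p2.candidates):
            assert np.array_equal(c1.position, c2.position)


class TestMilling:
    def test_zero_learning_rate_probes_stay_put(self):
        b = BoundsSpec.cube(-1.0, 1.0, 2)
        cfg = WHOConfig(learning_rate=0.0, milling_steps=4)
        cand = Candidate(np.array([0.3, -0.2]))
        mset = milling(cand, sphere, b, cfg, RandomSource(1))
        for probe in mset.probes:
            assert np.array_equal(probe, cand.position)

    def test_injected_draws_forced_probe(self):
        b = BoundsSpec.cube(-10.0, 10.0, 2)
        cfg = WHOConfig(learning_rate=0.5, milling_steps=1)
        rng = StubRng(thetas=[1.0], vectors=[[1.0, 0.0]])
        mset = milling(Candidate(np.zeros(2)), sphere, b, cfg, rng)
        assert np.allclose(mset.probes[0], [0.5, 0.0])

    def test_probe_step_bounded_by_learning_rate(self):
        b = BoundsSpec.cube(-100.0, 100.0, 3)
        cfg = WHOConfig(learning_rate=0.7, milling_steps=10)
        cand = Candidate(np.zeros(3))
        mset = milling(cand, sphere, b, cfg, RandomSource(2))
        for probe in mset.probes:
            assert np.linalg.norm(probe - cand.position) <= 0.7 + 1e-12

    def test_best_probe_is_argmin(self):
        b = BoundsSpec.cube(-5.0, 5.0, 2)
        cfg = WHOConfig(learning_rate=1.0, milling_steps=5)
        mset = milling(Candidate(np.array([1.0, 1.0])), sphere, b, cfg, RandomSource(3))
        assert mset.best_fitness == min(mset.probe_fitness)
        assert sphere(mset.best_probe) == mset.best_fitness

    def test_non_finite_objective_raises_with_position(self):
        b = BoundsSpec.cube(-1.0, 1.0, 2)
        cfg = WHOConfig(learning_rate=0.1)
        with pytest.raises(EvaluationError, match="position"):
            milling(Candidate(np.zeros(2)), lambda x: np.nan, b, cfg, RandomSource(0))


class TestLocalUpdate:
    def _mset(self, z):
        z = np.asarray(z, dtype=float)
        return MillingSet([z], [sphere(z)], z, sphere(z))

    def test_alpha_one_beta_zero_moves_to_best_probe(self):
        b = BoundsSpec.cube(-5.0, 5.0, 2)
        cfg = WHOConfig(alpha1=1.0, beta1=0.0)
        out = local_update(Candidate(np.array([1.0, 1.0])), self._mset([0.5, 0.5]),
                           sphere, b, cfg)
        assert np.allclose(out.position, [0.5, 0.5])

    def test_alpha_zero_beta_one_reflects(self):
        b = BoundsSpec.cube(-5.0, 5.0, 2)
        cfg = WHOConfig(alpha1=0.0, beta1=1.0)
        out = local_update(Candidate(np.array([1.0, 1.0])), self._mset([0.4, 0.2]),
                           sphere, b, cfg)
        assert np.allclose(out.position, [0.6, 0.8])

    def test_hand_arithmetic(self):
        # alpha1=0.9, beta1=0.3, x=(1,1), z*=(0,0) -> 0.9*0 + 0.3*(1-0) = 0.3
        b = BoundsSpec.cube(-5.0, 5.0, 2)
        cfg = WHOConfig(alpha1=0.9, beta1=0.3)
        out = local_update(Candidate(np.array([1.0, 1.0])), self._mset([0.0, 0.0]),
                           sphere, b, cfg)
        assert np.allclose(out.position, [0.3, 0.3])


class TestHerdInstinct:
    def test_worse_peer_leaves_candidate_unchanged(self):
        b = BoundsSpec.cube(-5.0, 5.0, 2)
        cand = Candidate(np.array([1.0, 0.0]), 1.0)
        peer = Candidate(np.array([2.0, 0.0]), 4.0)
        out = herd_instinct(cand, peer, sphere, b, WHOConfig())
        assert out is cand

    def test_identity_weights_keep_position(self):
        b = BoundsSpec.cube(-5.0, 5.0, 2)
        cfg = WHOConfig(alpha2=1.0, beta2=0.0)
        cand = Candidate(np.array([1.0, 0.0]), 1.0)
        peer = Candidate(np.array([0.1, 0.0]), 0.01)
        out = herd_instinct(cand, peer, sphere, b, cfg)
        assert np.allclose(out.position, cand.position)
        assert out.fitness == pytest.approx(1.0)

    def test_fixed_point_when_positions_equal(self):
        b = BoundsSpec.cube(-5.0, 5.0, 2)
        cfg = WHOConfig(alpha2=0.5, beta2=0.5)
        cand = Candidate(np.array([1.0, 1.0]), 5.0)
        peer = Candidate(np.array([1.0, 1.0]), 2.0)
        out = herd_instinct(cand, peer, sphere, b, cfg)
        assert np.allclose(out.position, [1.0, 1.0])

    def test_same_object_peer_rejected(self):
        b = BoundsSpec.cube(-5.0, 5.0, 2)
        cand = Candidate(np.array([1.0, 0.0]), 1.0)
        with pytest.raises(PeerSelectionError):
            herd_instinct(cand, cand, sphere, b, WHOConfig())


class TestStarvationAvoidance:
    def test_skipped_when_improved(self):
        b = BoundsSpec.cube(0.0, 1.0, 1)
        cand = Candidate(np.array([0.5]), 0.25)
        out = starvation_avoidance(cand, 0.5, sphere, b, RandomSource(0))
        assert out is cand

    def test_injected_zero_theta_keeps_position(self):
        b = BoundsSpec.cube(0.0, 1.0, 1)
        cand = Candidate(np.array([0.5]), 0.25)
        rng = StubRng(thetas=[0.0], vectors=[[1.0]])
        out = starvation_avoidance(cand, 0.1, sphere, b, rng)
        assert np.allclose(out.position, [0.5])

    def test_hand_arithmetic(self):
        # x=0.5, range=1, theta=0.25, v=(1) -> 0.75
        b = BoundsSpec.cube(0.0, 1.0, 1)
        cand = Candidate(np.array([0.5]), 0.25)
        rng = StubRng(thetas=[0.25], vectors=[[1.0]])
        out = starvation_avoidance(cand, 0.1, sphere, b, rng)
        assert np.allclose(out.position, [0.75])


class TestHerdPressure:
    def test_far_candidate_unchanged(self):
        b = BoundsSpec.cube(-10.0, 10.0, 2)
        cfg = WHOConfig(crowding_threshold=2.0, learning_rate=0.5)
        best = Candidate(np.zeros(2), 0.0)
        cand = Candidate(np.array([5.0, 0.0]), 25.0)
        out = herd_pressure(cand, best, sphere, b, cfg, RandomSource(0))
        assert out is cand

    def test_zero_learning_rate_snaps_to_best(self):
        b = BoundsSpec.cube(-10.0, 10.0, 2)
        cfg = WHOConfig(crowding_threshold=2.0, learning_rate=0.0)
        best = Candidate(np.zeros(2), 0.0)
        cand = Candidate(np.array([1.5, 0.0]), 2.25)
        out = herd_pressure(cand, best, sphere, b, cfg, RandomSource(0))
        assert np.allclose(out.position, best.position)

    def test_displacement_equals_learning_rate(self):
        b = BoundsSpec.cube(-10.0, 10.0, 2)
        cfg = WHOConfig(crowding_threshold=2.0, learning_rate=0.3)
        best = Candidate(np.zeros(2), 0.0)
        cand = Candidate(np.array([1.5, 0.0]), 2.25)
        out = herd_pressure(cand, best, sphere, b, cfg, RandomSource(1))
        assert np.linalg.norm(out.position - best.position) == pytest.approx(0.3)

    def test_inert_when_threshold_below_lower_bound(self):
        b = BoundsSpec.cube(-10.0, 10.0, 2)
        cfg = WHOConfig(crowding_threshold=0.5, learning_rate=0.3)
        best = Candidate(np.zeros(2), 0.0)
        cand = Candidate(np.array([0.3, 0.0]), 0.09)
        out = herd_pressure(cand, best, sphere, b, cfg, RandomSource(1))
        assert out is cand


class TestSocialMemory:
    def _population(self):
        cands = [
            Candidate(np.array([0.1, 0.1]), 0.02),
            Candidate(np.array([3.0, 3.0]), 18.0),
            Candidate(np.array([1.0, 1.0]), 2.0),
        ]
        return Population(cands, best=cands[0].copy())

    def test_worst_replaced_within_radius(self):
        b = BoundsSpec.cube(-10.0, 10.0, 2)
        pop = self._population()
        best_pos = pop.best.position.copy()
        social_memory(pop, sphere, b, WHOConfig(), RandomSource(0))
        moved = pop.candidates[1]
        assert np.linalg.norm(moved.position - best_pos) == pytest.approx(0.1)

    def test_best_never_degrades(self):
        b = BoundsSpec.cube(-10.0, 10.0, 2)
        pop = self._population()
        before = pop.best.fitness
        social_memory(pop, sphere, b, WHOConfig(), RandomSource(0))
        assert pop.best.fitness <= before

    def test_identical_population_perturbs_one(self):
        b = BoundsSpec.cube(-10.0, 10.0, 2)
        cands = [Candidate(np.array([1.0, 1.0]), 2.0) for _ in range(3)]
        pop = Population(cands, best=cands[0].copy())
        social_memory(pop, sphere, b, WHOConfig(), RandomSource(0))
        moved = [c for c in pop.candidates
                 if not np.array_equal(c.position, [1.0, 1.0])]
        assert len(moved) == 1
        assert np.linalg.norm(moved[0].position - [1.0, 1.0]) <= 0.1 + 1e-12


class TestOptimize:
    def test_constant_objective(self):
        b = BoundsSpec.cube(0.0, 1.0, 3)
        result = optimize(lambda x: 7.0, b, WHOConfig(iterations=5, seed=0))
        assert result.best_fitness == 7.0

    def test_quadratic_recovery(self):
        bench_errors = []
        b = BoundsSpec.cube(0.0, 5.0, 1)
        for seed in range(10):
            r = optimize(lambda x: (x[0] - 2.0) ** 2, b,
                         WHOConfig(iterations=100, seed=seed))
            bench_errors.append(abs(r.best_position[0] - 2.0))
        assert np.median(bench_errors) < 0.05

    def test_trace_nonincreasing_and_final_entry(self):
        b = BoundsSpec.cube(-5.0, 5.0, 4)
        r = optimize(sphere, b, WHOConfig(iterations=20, seed=2))
        assert all(a >= c for a, c in zip(r.trace, r.trace[1:]))
        assert r.best_fitness == r.trace[-1]

    def test_determinism(self):
        b = BoundsSpec.cube(-5.0, 5.0, 4)
        r1 = optimize(sphere, b, WHOConfig(iterations=10, seed=7))
        r2 = optimize(sphere, b, WHOConfig(iterations=10, seed=7))
        assert np.array_equal(r1.best_position, r2.best_position)
        assert r1.best_fitness == r2.best_fitness
        assert r1.trace == r2.trace
        assert r1.evaluations == r2.evaluations

    def test_collapse_configuration_is_stationary(self):
        b = BoundsSpec.cube(0.0, 1.0, 5)  # threshold 0.3*sqrt(5) < 1: pressure inert
        cfg = WHOConfig(
            learning_rate=0.0, alpha1=1.0, beta1=0.0, alpha2=1.0, beta2=0.0,
            use_social_memory=False, iterations=10, seed=3,
        )
        pop = initialize_population(b, cfg, RandomSource(3))
        initial = [sphere(c.position) for c in pop.candidates]
        r = optimize(sphere, b, cfg)
        assert r.best_fitness == min(initial)
        assert r.trace == [min(initial)] * 10

    def test_evaluation_error_propagates(self):
        b = BoundsSpec.cube(0.0, 1.0, 2)
        with pytest.raises(EvaluationError):
            optimize(lambda x: float("inf"), b, WHOConfig(iterations=2, seed=0))

    def test_beats_random_search_on_quadratic(self):
        b = BoundsSpec.cube(0.0, 5.0, 1)
        obj = lambda x: (x[0] - 2.0) ** 2
        wins = 0
        for seed in range(10):
            r = optimize(obj, b, WHOConfig(iterations=100, seed=seed))
            rng = np.random.default_rng(seed)
            random_best = min(
                obj(rng.uniform(0.0, 5.0, 1)) for _ in range(r.evaluations)
            )
            wins += r.best_fitness <= random_best
        assert wins >= 8


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), dim=st.integers(1, 6))
def test_property_bound_containment(seed, dim):
    b = BoundsSpec.cube(-1.0, 2.0, dim)
    r = optimize(sphere, b, WHOConfig(population_size=5, iterations=3, seed=seed))
    assert b.contains(r.best_position)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_property_elitism(seed):
    b = BoundsSpec.cube(-5.0, 5.0, 3)
    rng = np.random.default_rng(seed)
    coeffs = rng.standard_normal(3)

    def obj(x):
        return float(np.sum(coeffs * x) ** 2 + 0.1 * np.sum(x**2))

    r = optimize(obj, b, WHOConfig(population_size=5, iterations=5, seed=seed))
    assert all(a >= c for a, c in zip(r.trace, r.trace[1:]))
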