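"""Unit tests for the per-site dynamics and the Monte-Carlo step loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pglattice import (
    SimulationParams,
    WorldState,
    apply_death,
    apply_move,
    benefit,
    fitness,
    monte_carlo_step,
    mutate_production,
    neighbor_sites,
    run,
    select_replicator,
)
from pglattice.testkit import fixture_world, fixture_full_3x3, fixture_isolated

from conftest import ScriptedRng


class TestNeighborSites:
    def test_toroidal_corner_has_eight_distinct_wrapped_neighbors(self):
        p = SimulationParams(width=4, height=4)
        s = WorldState.empty(p)
        nbrs = neighbor_sites(s, p, (0, 0))
        assert len(nbrs) == 8
        assert len(set(nbrs)) == 8
        assert (3, 3) in nbrs  # wrap-around across both edges

    def test_no_flux_corner_truncates_to_three(self):
        p = SimulationParams(width=4, height=4, boundary="no-flux-absorbing")
        s = WorldState.empty(p)
        assert sorted(neighbor_sites(s, p, (0, 0))) == [(0, 1), (1, 0), (1, 1)]

    def test_interior_site_has_the_eight_adjacent_sites(self):
        p = SimulationParams(width=5, height=5)
        s = WorldState.empty(p)
        nbrs = set(neighbor_sites(s, p, (2, 2)))
        expected = {(2 + dr, 2 + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)} - {(2, 2)}
        assert nbrs == expected

    def test_out_of_range_site_raises(self):
        p = SimulationParams(width=4, height=4)
        s = WorldState.empty(p)
        with pytest.raises(IndexError):
            neighbor_sites(s, p, (4, 0))


class TestBenefitAndFitness:
    def test_homogeneous_neighbourhood_gives_b_times_p(self, params3):
        # every node of a full 3x3 torus collects b * (p + 8p)/9 = b*p
        s = fixture_full_3x3(params3, p=6.0)
        assert benefit(s, params3, (1, 1)) == pytest.approx(60.0)

    def test_isolated_individual_collects_only_its_own_share(self, params3):
        s = fixture_isolated(params3, p=9.0)
        assert benefit(s, params3, (1, 1)) == pytest.approx(10.0)  # b*p/9

    def test_non_producer_with_one_producing_neighbor(self):
        p = SimulationParams(width=5, height=5)
        s = fixture_world(
            p,
            [
                [None] * 5,
                [None, 0.0, 9.0, None, None],
                [None] * 5,
                [None] * 5,
                [None] * 5,
            ],
        )
        assert benefit(s, p, (1, 1)) == pytest.approx(10.0)

    def test_empty_site_raises(self, params3):
        s = fixture_isolated(params3)
        with pytest.raises(ValueError):
            benefit(s, params3, (0, 0))
        with pytest.raises(ValueError):
            fitness(s, params3, (0, 0))

    def test_fitness_difference_of_benefit_and_cost(self, params3):
        s = fixture_full_3x3(params3.with_(c=4.0), p=6.0)
        assert fitness(s, params3.with_(c=4.0), (1, 1)) == pytest.approx(60.0 - 24.0)

    def test_fitness_clamped_at_zero_when_costs_exceed_benefits(self, params3):
        p = params3.with_(c=4.0)
        s = fixture_isolated(p, p=9.0)  # B = 10, C = 36
        assert fitness(s, p, (1, 1)) == 0.0

    def test_zero_producer_fitness_equals_benefit(self, params3):
        p = params3.with_(c=4.0)
        s = fixture_world(p, [[6.0, None, None], [None, 0.0, None], [None] * 3])
        assert fitness(s, p, (1, 1)) == pytest.approx(benefit(s, p, (1, 1)))

    def test_strong_altruism_excludes_own_share(self, params3):
        weak = params3.with_(altruism="weak")
        strong8 = params3.with_(altruism="strong", strong_share="split8")
        strong9 = params3.with_(altruism="strong", strong_share="discard9")
        s = fixture_full_3x3(params3, p=6.0)
        assert benefit(s, weak, (1, 1)) == pytest.approx(10.0 * 54.0 / 9.0)
        assert benefit(s, strong8, (1, 1)) == pytest.approx(10.0 * 48.0 / 8.0)
        assert benefit(s, strong9, (1, 1)) == pytest.approx(10.0 * 48.0 / 9.0)


class TestSelectReplicator:
    def test_no_occupied_neighbours_returns_none(self, params3, rng):
        s = fixture_world(params3, [[None] * 3] * 3)
        assert select_replicator(s, params3, (1, 1), rng) is None

    def test_occupied_site_raises(self, params3, rng):
        s = fixture_full_3x3(params3)
        with pytest.raises(ValueError):
            select_replicator(s, params3, (1, 1), rng)

    def test_single_competitor_with_fitness_ln2_wins_half_the_time(self):
        # isolated competitor: f = p * (b/9 - c); pick b, c, p so f = ln 2
        p = SimulationParams(width=5, height=5, b=9.0, c=0.0)
        s = fixture_world(
            p,
            [
                [None] * 5,
                [None, math.log(2.0), None, None, None],
                [None] * 5,
                [None] * 5,
                [None] * 5,
            ],
        )
        assert fitness(s, p, (1, 1)) == pytest.approx(math.log(2.0))
        g = np.random.default_rng(0)
        n = 40_000
        wins = sum(select_replicator(s, p, (1, 2), g) is not None for _ in range(n))
        sigma = math.sqrt(n * 0.25)
        assert abs(wins - 0.5 * n) < 4 * sigma

    def test_zero_total_fitness_yields_none(self):
        p = SimulationParams(width=3, height=3, c=100.0)  # costs swamp benefits
        s = fixture_full_3x3(p, p=6.0)
        s.occupancy[1, 1] = False
        s.production[1, 1] = 0.0
        s.strain_label[1, 1] = -1
        g = np.random.default_rng(3)
        assert select_replicator(s, p, (1, 1), g) is None

    def test_scripted_draw_picks_competitor_by_cumulative_fitness(self):
        # competitors (1,1)->f=1 and (1,3)->f=3 on a 5x5 (b=18, c=1)
        p = SimulationParams(width=5, height=5, b=18.0, c=1.0)
        s = fixture_world(
            p,
            [
                [None] * 5,
                [None, 1.0, None, 3.0, None],
                [None] * 5,
                [None] * 5,
                [None] * 5,
            ],
        )
        p1 = 0.25 * -math.expm1(-4.0)
        assert select_replicator(s, p, (1, 2), ScriptedRng([p1 * 0.99])) == (1, 1)
        assert select_replicator(s, p, (1, 2), ScriptedRng([p1 * 1.01])) == (1, 3)
        assert select_replicator(s, p, (1, 2), ScriptedRng([1.0 - 0.5 * math.exp(-4)])) is None


class TestMutateProduction:
    def test_no_mutation_leaves_p_unchanged(self, params3):
        assert mutate_production(5.0, params3, ScriptedRng([0.99])) == 5.0

    def test_mutation_adds_scaled_uniform(self, params3):
        # draw 0.8 -> offset (0.8 - 0.5) * 0.1 = +0.03
        assert mutate_production(5.0, params3, ScriptedRng([0.0, 0.8])) == pytest.approx(5.03)

    def test_clip_at_lower_bound(self, params3):
        assert mutate_production(0.02, params3, ScriptedRng([0.0, 0.0])) == 0.0

    def test_clip_at_cap(self, params3):
        assert mutate_production(9.99, params3, ScriptedRng([0.0, 1.0])) == params3.p_max

    @given(p=st.floats(0.0, 10.0), u=st.floats(0.0, 1.0), v=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_result_always_within_bounds(self, p, u, v):
        params = SimulationParams()
        out = mutate_production(p, params, ScriptedRng([u, v]))
        assert 0.0 <= out <= params.p_max


class TestMoveAndDeath:
    def test_k_move_zero_leaves_state_unchanged(self, params3, rng):
        s = fixture_isolated(params3)
        before = s.copy()
        apply_move(s, params3.with_(k_move=0.0), (1, 1), rng)
        assert s.equals(before)

    def test_swap_with_empty_neighbour_conserves_count(self, params3):
        p = params3.with_(k_move=1.0)
        s = fixture_isolated(p, p=4.0)
        apply_move(s, p, (1, 1), ScriptedRng([0.0, 0.0]))
        assert s.population_size() == 1
        assert s.production_values()[0] == 4.0

    def test_move_into_absorbing_ring_removes_individual(self):
        p = SimulationParams(width=4, height=4, boundary="no-flux-absorbing", k_move=1.0)
        s = WorldState.empty(p)
        s.occupancy[1, 1] = True
        s.production[1, 1] = 5.0
        s.strain_label[1, 1] = 0
        # direction draw 0.0 -> first listed neighbour (0, 0), a ring node
        apply_move(s, p, (1, 1), ScriptedRng([0.0, 0.0]))
        assert s.population_size() == 0

    def test_death_probability_one_always_empties(self, params3, rng):
        s = fixture_isolated(params3)
        apply_death(s, params3.with_(k_death=1.0), (1, 1), rng)
        assert s.population_size() == 0

    def test_death_probability_zero_never_empties(self, params3, rng):
        s = fixture_isolated(params3)
        for _ in range(50):
            apply_death(s, params3.with_(k_death=0.0), (1, 1), rng)
        assert s.population_size() == 1

    def test_empirical_death_fraction_matches_k_death(self, params3):
        g = np.random.default_rng(11)
        n, k_death = 20_000, 0.2
        p = params3.with_(k_death=k_death)
        deaths = 0
        for _ in range(n):
            s = fixture_isolated(p)
            apply_death(s, p, (1, 1), g)
            deaths += s.population_size() == 0
        sigma = math.sqrt(n * k_death * (1 - k_death))
        assert abs(deaths - n * k_death) < 3 * sigma

    def test_empty_site_raises(self, params3, rng):
        s = fixture_isolated(params3)
        with pytest.raises(ValueError):
            apply_move(s, params3, (0, 0), rng)
        with pytest.raises(ValueError):
            apply_death(s, params3, (0, 0), rng)


class TestMonteCarloStep:
    def test_all_empty_lattice_stays_empty(self, rng):
        p = SimulationParams(width=8, height=8)
        s = WorldState.empty(p)
        monte_carlo_step(s, p, rng)
        assert s.population_size() == 0
        assert s.t == 1

    def test_zero_fitness_individual_never_replicates(self):
        # isolated individual at p = 9 with c = 4: B = 10 < C = 36 -> f = 0
        p = SimulationParams(width=5, height=5, c=4.0, k_move=0.0, k_death=0.0)
        s = WorldState.empty(p)
        s.occupancy[2, 2] = True
        s.production[2, 2] = 9.0
        s.strain_label[2, 2] = 0
        g = np.random.default_rng(5)
        for _ in range(50):
            monte_carlo_step(s, p, g)
        assert s.population_size() == 1

    def test_survival_probability_of_isolated_individual(self):
        p = SimulationParams(width=3, height=3, c=4.0, k_move=0.0, k_death=0.2)
        g = np.random.default_rng(17)
        n = 5000
        survived = 0
        for _ in range(n):
            s = WorldState.empty(p)
            s.occupancy[1, 1] = True
            s.production[1, 1] = 9.0  # f = 0 under c = 4
            s.strain_label[1, 1] = 0
            monte_carlo_step(s, p, g)
            survived += s.population_size()
        expect = n * (1 - p.k_death)
        sigma = math.sqrt(n * p.k_death * (1 - p.k_death))
        assert abs(survived - expect) < 3 * sigma

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_invariants_hold_along_any_trajectory(self, seed):
        p = SimulationParams(width=12, height=12, c=3.0, seed=seed)
        g = np.random.default_rng(seed)
        s = WorldState.random_fill(p, 0.7, 8.0, g)
        for _ in range(5):
            monte_carlo_step(s, p, g)
        s.check_invariants(p)

    def test_movement_conserves_population_on_torus(self):
        # no death, no replication possible (every fitness clamped to 0)
        p = SimulationParams(width=10, height=10, c=100.0, k_move=0.5, k_death=0.0)
        g = np.random.default_rng(23)
        s = WorldState.random_fill(p, 0.5, 5.0, g)
        n0 = s.population_size()
        vals0 = np.sort(s.production_values())
        for _ in range(20):
            monte_carlo_step(s, p, g)
        assert s.population_size() == n0
        assert np.array_equal(np.sort(s.production_values()), vals0)


class TestRun:
    def test_zero_steps_yields_single_initial_record(self, rng):
        p = SimulationParams(width=8, height=8)
        s = WorldState.filled(p, 5.0)
        records = run(p, s, 0, rng=rng)
        assert len(records) == 1
        assert records[0].t == 0
        assert records[0].population_size == 64

    def test_certain_death_flags_extinction(self):
        p = SimulationParams(width=6, height=6, c=100.0, k_death=1.0, k_move=0.0)
        s = WorldState.filled(p, 5.0)
        records = run(p, s, 10, sample_every=1, rng=np.random.default_rng(1))
        assert records[-1].population_size == 0
        assert records[-1].t == 1  # everyone dies on the first step

    def test_same_seed_gives_bit_identical_trajectories(self):
        p = SimulationParams(width=16, height=16, c=4.5)
        out = []
        for _ in range(2):
            s = WorldState.filled(p, p.p_max)
            out.append(run(p, s, 30, sample_every=10, rng=np.random.default_rng(99)))
        for a, b in zip(out[0], out[1]):
            assert a.t == b.t
            assert a.population_size == b.population_size
            assert a.mean_p == b.mean_p  # exact float equality
            assert np.array_equal(a.histogram, b.histogram)

    def test_histogram_mass_equals_population(self, rng):
        p = SimulationParams(width=16, height=16, c=2.0)
        s = WorldState.filled(p, p.p_max)
        for rec in run(p, s, 50, sample_every=10, rng=rng):
            assert rec.histogram.sum() == rec.population_size
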