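import numpy as np
import pytest

from rankforage import (
    SimConfig,
    init_world,
    play_all_games,
    reproduction_phase,
    run_condition,
    run_replicate,
    run_update,
)


def _cfg(**kw):
    base = dict(grid_side=10, updates=100, sample_interval=10, window=50, replicates=2)
    base.update(kw)
    return SimConfig(**base)


def _is_rank_permutation(world) -> bool:
    return sorted(world.ranks) == list(range(1, world.n_agents + 1))


class TestWorldSetup:
    def test_full_occupancy_and_rank_permutation(self, rng):
        world = init_world(_cfg(grid_side=12), rng)
        assert world.n_agents == 144
        assert world.genomes.shape == (144, 5)
        assert (world.resources == 0).all()
        assert _is_rank_permutation(world)


class TestPlayAllGames:
    def test_one_game_per_cell_five_decisions_each(self, rng):
        cfg = _cfg(grid_side=6)
        world = init_world(cfg, rng)
        income, decisions = play_all_games(world, cfg, rng)
        assert decisions.shape == (36, 5)  # 36 games x 5 members
        assert income.shape == (36,)

    def test_forced_solo_success_gives_full_income(self, rng):
        cfg = _cfg(solo_success=1.0)
        world = init_world(cfg, rng)
        world.genomes[:] = 0.0  # everyone always solo hunts
        income, decisions = play_all_games(world, cfg, rng)
        assert not decisions.any()
        assert income == pytest.approx(np.full(world.n_agents, 5.0))

    def test_mean_income_of_solo_population_is_bernoulli_mean(self, rng):
        cfg = _cfg()
        world = init_world(cfg, rng)
        world.genomes[:] = 0.0
        incomes = [play_all_games(world, cfg, rng)[0].mean() for _ in range(200)]
        assert np.mean(incomes) == pytest.approx(2.5, abs=0.05)

    def test_all_one_genomes_always_group_hunt(self, rng):
        cfg = _cfg(mutation_rate=0.0)
        world = init_world(cfg, rng)
        world.genomes[:] = 1.0
        for _ in range(20):
            stats = run_update(world, cfg, rng)
            assert stats.decisions.all()  # closed under reproduction at mu=0


class TestReproductionPhase:
    def test_no_candidates_changes_nothing(self, rng):
        cfg = _cfg()
        world = init_world(cfg, rng)
        world.resources[:] = 10.0
        genomes = world.genomes.copy()
        births, destroyed = reproduction_phase(world, cfg, rng)
        assert births == 0 and destroyed == 0.0
        assert (world.genomes == genomes).all()

    def test_single_parent_at_threshold(self, rng):
        cfg = _cfg(mutation_rate=0.0)
        world = init_world(cfg, rng)
        world.resources[:] = 0.0
        world.resources[37] = 50.0
        world.genomes[37] = 0.123  # recognisable heritable strategy
        births, destroyed = reproduction_phase(world, cfg, rng)
        assert births == 1
        assert world.resources[37] == 0.0  # paid the full cost, no remainder
        assert world.n_agents == 100  # population size unchanged
        assert _is_rank_permutation(world)
        assert (world.genomes == 0.123).all(axis=1).sum() == 2  # parent + child

    def test_rich_parent_births_once_and_keeps_remainder(self, rng):
        cfg = _cfg()
        world = init_world(cfg, rng)
        world.resources[:] = 0.0
        world.resources[5] = 120.0
        births, _ = reproduction_phase(world, cfg, rng)
        assert births == 1
        assert world.resources[5] == pytest.approx(70.0)

    def test_offspring_rank_sits_directly_below_parent(self, rng):
        cfg = _cfg(mutation_rate=0.0)
        world = init_world(cfg, rng)
        world.resources[:] = 0.0
        parent = int(np.argmax(world.ranks == 3))  # agent holding rank 3
        world.resources[parent] = 50.0
        world.genomes[parent] = 0.777
        reproduction_phase(world, cfg, rng)
        child_cells = np.flatnonzero(
            (world.genomes == 0.777).all(axis=1)
            & (np.arange(world.n_agents) != parent)
        )
        assert child_cells.size == 1
        # Maternal rank inheritance: nobody sits between parent and child,
        # even after the victim's rank is compacted away.
        assert world.ranks[child_cells[0]] == world.ranks[parent] + 1
        assert world.ranks[parent] <= 3  # can only move up if the victim outranked it


class TestUpdateLoop:
    def test_invariants_hold_over_smoke_run(self, rng):
        # 500-update sweep: occupancy is structural (fixed arrays); ranks must
        # remain a permutation and the resource ledger must balance exactly.
        cfg = _cfg(grid_side=8, updates=500)
        world = init_world(cfg, rng)
        credited = spent = destroyed = 0.0
        for _ in range(500):
            stats = run_update(world, cfg, rng)
            credited += stats.income_total
            spent += cfg.reproduction_cost * stats.births
            destroyed += stats.resources_destroyed
            assert _is_rank_permutation(world)
            assert (world.resources >= 0).all()
        assert world.resources.sum() == pytest.approx(
            credited - spent - destroyed, abs=1e-6
        )
        assert world.update_index == 500

    def test_zero_updates_returns_initial_world(self, rng):
        cfg = _cfg(updates=10, sample_interval=10, window=10)
        world = init_world(cfg, rng)
        genomes = world.genomes.copy()
        # no run_update calls: world untouched by construction
        assert world.update_index == 0
        assert (world.genomes == genomes).all()


class TestReplicates:
    def test_identical_seed_is_bit_identical(self):
        cfg = _cfg(grid_side=8, updates=60, sample_interval=10, window=20)
        a = run_replicate(cfg, (3, 0))
        b = run_replicate(cfg, (3, 0))
        assert (a.world.genomes == b.world.genomes).all()
        assert (a.world.ranks == b.world.ranks).all()
        for ma, mb in zip(a.samples, b.samples):
            assert (
                ma.group_decisions_by_relative_rank
                == mb.group_decisions_by_relative_rank
            ).all()
        assert a.total_births == b.total_births

    def test_different_seeds_diverge(self):
        cfg = _cfg(grid_side=8, updates=60, sample_interval=10, window=20)
        a = run_replicate(cfg, (3, 0))
        b = run_replicate(cfg, (4, 0))
        assert not (a.world.genomes == b.world.genomes).all()

    def test_window_sample_count_matches_schedule(self):
        cfg = _cfg(grid_side=8, updates=100, sample_interval=10, window=50)
        res = run_replicate(cfg, (0, 0))
        assert res.summary.n_samples == 6  # 50/10 + 1, endpoints inclusive

    def test_condition_aggregates_all_replicates(self):
        cfg = _cfg(grid_side=6, updates=40, sample_interval=10, window=20, replicates=3)
        result = run_condition(cfg)
        assert len(result.replicates) == 3
        assert result.summary.n_replicates == 3
        assert set(result.timeseries["replicate"]) == {0, 1, 2}


class TestEvolutionaryDirection:
    def test_neutral_payoffs_leave_genomes_drifting_near_half(self):
        # Equal expected payoff for both choices: tolerance 1, multiplier 1,
        # and a lone group hunter as likely to succeed as a solo hunter.
        cfg = SimConfig(
            grid_side=20,
            tolerance=1.0,
            payoff_multiplier=1.0,
            lone_group_success=0.5,
            updates=300,
            sample_interval=100,
            window=100,
            replicates=1,
            seed=0,
        )
        res = run_replicate(cfg, (0, 0))
        assert 0.3 < res.world.genomes.mean() < 0.7

    def test_equal_sharing_with_double_payoff_selects_group_hunting(self):
        cfg = SimConfig(
            grid_side=16,
            tolerance=1.0,
            payoff_multiplier=2.0,
            updates=2000,
            sample_interval=1000,
            window=1000,
            replicates=1,
            seed=0,
        )
        res = run_replicate(cfg, (0, 0))
        assert res.world.genomes.mean() > 0.7
        assert res.summary.population_rate > 0.7
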