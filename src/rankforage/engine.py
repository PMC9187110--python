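"""The world-update loop.

A :class:`World` is a full-occupancy square torus: every cell always holds
exactly one living agent, so the population is constant at ``grid_side**2``.
Agents cannot move; they differ only in genome, accumulated resources and
global dominance rank.  Each update:

1.  every cell hosts one hunting game (the cell's agent plus its four von
    Neumann neighbours), so every agent plays in exactly 5 games;
2.  each agent's income for the update is the arithmetic mean of its 5 game
    payoffs and is credited to its resource pool;
3.  every agent whose resources reach the reproduction cost becomes a birth
    candidate; candidates are processed one at a time in uniformly random
    order — a candidate displaced earlier in the phase forfeits its birth.
    A surviving candidate pays the cost (keeping the remainder), its
    offspring receives a mutated genome copy, zero resources, a uniformly
    random cell among the 24 within Chebyshev radius 2 of the parent, and
    the rank directly below the parent (all lower-ranked agents shift down
    one).  The displaced occupant dies and its resources are destroyed;
4.  ranks are renumbered to a gapless 1..N.

The engine is array-based and vectorised: agents are identified with their
(fixed) cells, genomes live in an (N, 5) matrix, ranks and resources in
length-N vectors.  RNG consumption per update is fixed — decision draws
(N, 5), group-success draws (N,), solo draws (N, 5), then the reproduction
permutation and per-birth draws — so runs are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GROUP_SIZE, SimConfig, replicate_seeds, validate_config
from .game import resolve_decision_matrix
from .grid import hunting_group_indices, offspring_candidate_indices
from .metrics import (
    ConditionSummary,
    ReplicateSummary,
    UpdateMetrics,
    rates_from_decisions,
    sample_schedule,
    summarize_condition,
    summarize_replicate,
    timeseries_frame,
)


@dataclass
class World:
    """Full-occupancy toroidal world state; cell ``c`` is row-major index."""

    side: int
    genomes: np.ndarray  # (N, 5) group-hunt probabilities by relative rank
    ranks: np.ndarray  # (N,) global ranks, a permutation of 1..N
    resources: np.ndarray  # (N,) accumulated points
    update_index: int = 0

    @property
    def n_agents(self) -> int:
        return self.side * self.side


@dataclass
class UpdateStats:
    """Bookkeeping emitted by one update (for metrics and ledger checks)."""

    decisions: np.ndarray  # (N, 5) bool, column j = relative rank j+1
    income_total: float
    births: int
    resources_destroyed: float


@dataclass
class ReplicateResult:
    """Everything one replicate run returns."""

    summary: ReplicateSummary
    samples: list[UpdateMetrics]
    total_births: int
    world: World


def init_world(cfg: SimConfig, rng: np.random.Generator) -> World:
    """Fresh world: uniform random genomes, uniformly random ranks, no resources."""
    n = cfg.n_agents
    return World(
        side=cfg.grid_side,
        genomes=rng.random((n, cfg.genome_length)),
        ranks=rng.permutation(n) + 1,
        resources=np.zeros(n),
    )


def _relative_positions(ranks_of_members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-game rank ordering.

    Returns ``order`` (slot indices sorted by ascending global rank) and
    ``relpos`` (0-based relative rank of each slot), both (n_games, 5).
    """
    order = np.argsort(ranks_of_members, axis=1)
    relpos = np.argsort(order, axis=1)
    return order, relpos


def play_all_games(
    world: World, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Play one game per cell; return per-agent income and the decision matrix.

    Income is the mean of the agent's 5 game payoffs.  The decision matrix is
    (n_games, 5) boolean with columns in relative-rank order, ready for
    :func:`rankforage.metrics.rates_from_decisions`.
    """
    members = hunting_group_indices(world.side)  # (N, 5) cell indices
    order, relpos = _relative_positions(world.ranks[members])

    # Each member's decision probability is its genome site at its relative rank.
    p = world.genomes[members, relpos]
    dec_slot = rng.random(p.shape) < p

    dec_rank = np.take_along_axis(dec_slot, order, axis=1)
    pay_rank = resolve_decision_matrix(dec_rank, cfg, rng)
    pay_slot = np.take_along_axis(pay_rank, relpos, axis=1)

    income = np.bincount(
        members.ravel(), weights=pay_slot.ravel(), minlength=world.n_agents
    ) / GROUP_SIZE
    return income, dec_rank


def reproduction_phase(
    world: World, cfg: SimConfig, rng: np.random.Generator
) -> tuple[int, float]:
    """Apply all births for this update; return (births, resources destroyed).

    Candidates are the agents holding >= ``reproduction_cost`` at phase start,
    processed sequentially in uniformly random order; each birth's rank
    insertion uses the parent's rank at that moment, and the phase ends with
    a renumbering to 1..N.
    """
    candidates = np.flatnonzero(world.resources >= cfg.reproduction_cost)
    births = 0
    destroyed = 0.0
    if candidates.size:
        candidates = candidates[rng.permutation(candidates.size)]
        sites = offspring_candidate_indices(world.side)
        replaced = np.zeros(world.n_agents, dtype=bool)
        ranks = world.ranks
        for parent in candidates:
            if replaced[parent]:
                continue  # displaced earlier this phase: forfeits the birth
            world.resources[parent] -= cfg.reproduction_cost
            target = sites[parent, rng.integers(sites.shape[1])]
            child = world.genomes[parent].copy()
            hit = rng.random(child.size) < cfg.mutation_rate
            n_hit = int(hit.sum())
            if n_hit:
                child[hit] = rng.random(n_hit)
            parent_rank = ranks[parent]
            # Maternal rank inheritance: offspring slots in directly below the
            # parent; everyone previously below shifts down one.  The dead
            # occupant's rank simply leaves a gap until compaction.
            ranks[ranks > parent_rank] += 1
            destroyed += world.resources[target]
            world.genomes[target] = child
            world.resources[target] = 0.0
            ranks[target] = parent_rank + 1
            replaced[target] = True
            births += 1
        # Compact to a gapless 1..N (ranks are distinct, so ordinary argsort
        # ranking is unambiguous).
        world.ranks = np.argsort(np.argsort(ranks)) + 1
    return births, destroyed


def run_update(world: World, cfg: SimConfig, rng: np.random.Generator) -> UpdateStats:
    """One full update: games -> income -> reproduction -> rank compaction."""
    income, dec_rank = play_all_games(world, cfg, rng)
    world.resources += income
    births, destroyed = reproduction_phase(world, cfg, rng)
    world.update_index += 1
    return UpdateStats(
        decisions=dec_rank,
        income_total=float(income.sum()),
        births=births,
        resources_destroyed=destroyed,
    )


def probe_rates(world: World, rng: np.random.Generator) -> np.ndarray:
    """Decision matrix of a measurement-only pass (no payoffs, no state change).

    Used for the update-0 sample: decisions are drawn from the current
    genomes exactly as in a real update, from a dedicated RNG stream.
    """
    members = hunting_group_indices(world.side)
    order, relpos = _relative_positions(world.ranks[members])
    p = world.genomes[members, relpos]
    dec_slot = rng.random(p.shape) < p
    return np.take_along_axis(dec_slot, order, axis=1)


def run_replicate(cfg: SimConfig, seed) -> ReplicateResult:
    """Run one replicate from a fresh world for ``cfg.updates`` updates.

    ``seed`` is any :class:`numpy.random.SeedSequence` entropy (an int or a
    tuple); the main stream and the update-0 probe stream are spawned from
    it, so identical (cfg, seed) pairs give bit-identical trajectories.
    """
    validate_config(cfg)
    ss = np.random.SeedSequence(seed)
    main_ss, probe_ss = ss.spawn(2)
    rng = np.random.default_rng(main_ss)
    probe_rng = np.random.default_rng(probe_ss)

    world = init_world(cfg, rng)
    schedule, in_window = sample_schedule(cfg.updates, cfg.sample_interval, cfg.window)
    sampled = set(int(u) for u in schedule)

    samples: list[UpdateMetrics] = []
    if 0 in sampled:
        samples.append(rates_from_decisions(probe_rates(world, probe_rng), 0))
    total_births = 0
    for u in range(1, cfg.updates + 1):
        stats = run_update(world, cfg, rng)
        total_births += stats.births
        if u in sampled:
            samples.append(rates_from_decisions(stats.decisions, u))

    window_start = cfg.updates - cfg.window
    window_rates = np.stack(
        [m.rate_by_relative_rank for m in samples if m.update_index >= window_start]
    )
    return ReplicateResult(
        summary=summarize_replicate(window_rates),
        samples=samples,
        total_births=total_births,
        world=world,
    )


@dataclass
class ConditionResult:
    """All replicates of one condition plus their aggregate."""

    cfg: SimConfig
    replicates: list[ReplicateResult]
    summary: ConditionSummary
    timeseries: pd.DataFrame = field(repr=False)

    @property
    def replicate_summaries(self) -> list[ReplicateSummary]:
        return [r.summary for r in self.replicates]


def run_condition(cfg: SimConfig, progress=None) -> ConditionResult:
    """Run all replicates of one condition (replicate r seeded by (cfg.seed, r)).

    ``progress``, if given, is called with the replicate index after each
    replicate finishes (hook for CLI progress reporting).
    """
    results = []
    frames = []
    for r, entropy in replicate_seeds(cfg):
        res = run_replicate(cfg, entropy)
        results.append(res)
        frames.append(timeseries_frame(cfg, r, res.samples))
        if progress is not None:
            progress(r)
    if len(results) >= 2:
        summary = summarize_condition([res.summary for res in results])
    else:  # single replicate: a cross-replicate SE is undefined
        summary = ConditionSummary(
            mean_by_relative_rank=results[0].summary.rate_by_relative_rank.copy(),
            se_by_relative_rank=np.full(GROUP_SIZE, np.nan),
            n_replicates=1,
        )
    return ConditionResult(
        cfg=cfg,
        replicates=results,
        summary=summary,
        timeseries=pd.concat(frames, ignore_index=True),
    )
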