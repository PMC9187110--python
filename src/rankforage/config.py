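"""Run configuration: parameters, validation, serialization, and the sweep grid.

A :class:`SimConfig` carries every knob of one experimental condition.  The
defaults reproduce the published experiment: a 60x60 toroidal world of 3,600
non-moving agents, solo-hunt payoff 5 points with 50% success, group hunts
succeeding 50% of the time (5% for a lone joiner), reproduction at 50 points,
and a 0.05% per-site mutation probability at birth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import yaml

#: Tolerance levels of the published sweep (1 = equal split, lower = more despotic).
PAPER_TOLERANCES = (1.0, 0.96, 0.88, 0.76, 0.64)

#: Group-hunt per-capita payoff as a multiple of the solo payoff.
PAPER_MULTIPLIERS = (2.0, 1.2)

#: Members per hunting group (an agent and its four von Neumann neighbours).
GROUP_SIZE = 5


@dataclass(frozen=True)
class SimConfig:
    """All parameters of one simulation condition.

    Parameters
    ----------
    grid_side
        Cells per side of the square toroidal grid; population is ``grid_side**2``.
    tolerance
        Payoff-sharing skew in ``(0, 1]``: each successively lower-ranked group
        hunter receives ``tolerance`` times the share of the hunter ranked
        immediately above it.  1.0 is an equal split.
    payoff_multiplier
        Per-capita average group-hunt payoff as a multiple of ``solo_payoff``.
    solo_payoff
        Points for a successful solo hunt.
    solo_success
        Probability a solo hunt succeeds.
    group_success
        Probability a group hunt with at least two hunters succeeds.
    lone_group_success
        Probability a "group" hunt attempted by a single hunter succeeds.
    reproduction_cost
        Resource points consumed to produce one offspring.
    mutation_rate
        Per-genome-site probability that an offspring's site is redrawn
        uniformly on [0, 1].
    genome_length
        Number of genome sites; equals the hunting-group size (5).
    updates
        World updates per replicate.
    sample_interval
        Metrics are sampled at every update index divisible by this.
    window
        Length (in updates) of the terminal averaging window.
    replicates
        Independent replicate simulations per condition.
    seed
        Master seed for the condition; replicate ``r`` derives its stream
        deterministically from ``(seed, r)``.
    """

    grid_side: int = 60
    tolerance: float = 1.0
    payoff_multiplier: float = 2.0
    solo_payoff: float = 5.0
    solo_success: float = 0.5
    group_success: float = 0.5
    lone_group_success: float = 0.05
    reproduction_cost: float = 50.0
    mutation_rate: float = 0.0005
    genome_length: int = GROUP_SIZE
    updates: int = 1_000_000
    sample_interval: int = 1_000
    window: int = 100_000
    replicates: int = 200
    seed: int = 0

    @property
    def n_agents(self) -> int:
        return self.grid_side * self.grid_side

    @property
    def per_capita(self) -> float:
        """Per-capita average payoff of a successful group hunt, in points."""
        return self.payoff_multiplier * self.solo_payoff

    def replace(self, **overrides) -> "SimConfig":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @property
    def condition_id(self) -> str:
        return f"t{self.tolerance:g}_m{self.payoff_multiplier:g}"


def validate_config(cfg: SimConfig) -> SimConfig:
    """Return ``cfg`` unchanged if every invariant holds; raise otherwise.

    Raises
    ------
    ValueError
        Naming the first violated invariant.
    """
    if not 0.0 < cfg.tolerance <= 1.0:
        raise ValueError("tolerance out of range (must be in (0, 1])")
    for name in ("solo_success", "group_success", "lone_group_success", "mutation_rate"):
        p = getattr(cfg, name)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} out of range (must be a probability in [0, 1])")
    if cfg.grid_side < 5:
        raise ValueError(
            "grid too small for offspring radius (grid_side must be >= 5 so the "
            "24 offspring-candidate cells are distinct on the torus)"
        )
    if cfg.payoff_multiplier <= 0:
        raise ValueError("payoff_multiplier must be positive")
    if cfg.solo_payoff <= 0:
        raise ValueError("solo_payoff must be positive")
    if cfg.reproduction_cost <= 0:
        raise ValueError("reproduction_cost must be positive")
    if cfg.genome_length != GROUP_SIZE:
        raise ValueError(f"genome_length must equal the hunting-group size ({GROUP_SIZE})")
    for name in ("updates", "sample_interval", "window", "replicates"):
        if getattr(cfg, name) < 1:
            raise ValueError(f"{name} must be a positive integer")
    if cfg.window > cfg.updates:
        raise ValueError("window must not exceed updates")
    if cfg.window % cfg.sample_interval != 0:
        raise ValueError("sample_interval must divide window")
    return cfg


def paper_condition_grid(**overrides) -> list[SimConfig]:
    """The published 5 x 2 sweep: tolerances {1.0, 0.96, 0.88, 0.76, 0.64}
    crossed with payoff multipliers {2.0, 1.2}, all else at defaults.

    ``overrides`` (e.g. ``grid_side=30, updates=30_000``) apply to every
    member, which is how desk-scale versions of the sweep are built.
    """
    grid = []
    for tol in PAPER_TOLERANCES:
        for mult in PAPER_MULTIPLIERS:
            cfg = SimConfig(tolerance=tol, payoff_multiplier=mult, **overrides)
            grid.append(validate_config(cfg))
    return grid


def save_config(cfg: SimConfig, path: str | Path) -> None:
    """Write a config as a flat YAML document with every field explicit."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> SimConfig:
    """Read a YAML config written by :func:`save_config` (validated)."""
    return validate_config(SimConfig.from_dict(yaml.safe_load(Path(path).read_text())))


def replicate_seeds(cfg: SimConfig) -> Iterator[tuple[int, tuple[int, int]]]:
    """Yield ``(replicate_index, seed_pair)`` entropy for each replicate.

    Replicate ``r`` of a condition is seeded by the pair ``(cfg.seed, r)``,
    fed to :class:`numpy.random.SeedSequence`, so sweeps are reproducible and
    replicates independent without a global draw order.
    """
    for r in range(cfg.replicates):
        yield r, (cfg.seed, r)
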