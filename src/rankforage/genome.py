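"""The 5-site probabilistic strategy genome.

Site ``i`` (0-based ``i-1``) holds the probability that its carrier chooses
to group hunt when it is the ``i``-th ranking member of a hunting group.
Genomes mutate only at birth: each site is independently redrawn uniformly
on [0, 1] with probability ``mutation_rate``; there is no recombination and
no memory of past games.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .config import GROUP_SIZE


class Decision(Enum):
    GROUP = "group"
    SOLO = "solo"


def random_genome(rng: np.random.Generator, genome_length: int = GROUP_SIZE) -> np.ndarray:
    """Each site drawn independently uniform on [0, 1].

    The initial population is seeded with these; uniform matches the mutation
    operator's redraw distribution and biases no strategy.
    """
    return rng.random(genome_length)


def mutate(parent: np.ndarray, mutation_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Copy of ``parent`` with each site redrawn uniform [0,1] w.p. ``mutation_rate``."""
    child = np.array(parent, dtype=float, copy=True)
    hit = rng.random(child.size) < mutation_rate
    n_hit = int(hit.sum())
    if n_hit:
        child[hit] = rng.random(n_hit)
    return child


def decide(genome: np.ndarray, relative_rank: int, rng: np.random.Generator) -> Decision:
    """One hunting decision at the given relative rank (1-based).

    Consumes exactly one RNG draw: GROUP iff the draw falls below the site
    value, so a site of 1.0 always group hunts and 0.0 never does.
    """
    if not 1 <= relative_rank <= len(genome):
        raise ValueError("relative_rank out of range for this genome")
    return Decision.GROUP if rng.random() < genome[relative_rank - 1] else Decision.SOLO
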