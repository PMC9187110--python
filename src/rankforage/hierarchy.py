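"""The strict linear dominance hierarchy.

Every living agent holds a unique global rank 1..N (1 = most dominant).  A
``RankOrder`` is represented as a sequence of agent identifiers ordered by
rank: the agent at list position ``i`` holds rank ``i + 1``.  Offspring take
the rank immediately below their parent (maternal rank inheritance),
displacing all lower-ranked agents down one; deaths are followed by
renumbering so ranks stay a gapless 1..N.

Inside a 5-member hunting group, members are re-ranked 1..5 by their global
ranks (*relative rank*, the genome index), and the subset that chose to group
hunt is re-ranked again 1..k (*sharing rank*, the payoff-division index).
"""

from __future__ import annotations

from typing import Hashable, Sequence

import numpy as np

RankOrder = list


def initial_rank_assignment(n_agents: int, rng: np.random.Generator) -> RankOrder:
    """Uniformly random rank order over agent ids ``0..n_agents-1``."""
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    return list(rng.permutation(n_agents))


def relative_ranks(global_ranks_of_members: Sequence[int]) -> np.ndarray:
    """Positions 1..5 of the group members ordered by ascending global rank.

    ``out[i]`` is member i's relative rank; the member with the smallest
    global rank number (most dominant) gets position 1.
    """
    ranks = np.asarray(global_ranks_of_members)
    if len(np.unique(ranks)) != ranks.size:
        raise ValueError("global ranks within a group must be distinct")
    return np.argsort(np.argsort(ranks)) + 1


def payoff_ranks_among_hunters(hunter_relative_ranks: Sequence[int]) -> np.ndarray:
    """Contiguous sharing ranks 1..k for the group hunters, preserving order.

    E.g. group members at relative ranks {1, 3, 5} share at ranks {1, 2, 3}.
    """
    rel = np.asarray(hunter_relative_ranks)
    if rel.size == 0:
        raise ValueError("at least one hunter required")
    return np.argsort(np.argsort(rel)) + 1


def insert_offspring_rank(order: RankOrder, parent: Hashable, offspring: Hashable) -> RankOrder:
    """New order with ``offspring`` at the rank directly below ``parent``.

    Every agent previously ranked below the parent shifts down one rank.
    """
    try:
        pos = order.index(parent)
    except ValueError:
        raise ValueError("parent not found in rank order") from None
    return order[: pos + 1] + [offspring] + order[pos + 1 :]


def remove_and_compact(order: RankOrder, dead: set) -> RankOrder:
    """Drop dead agents and renumber survivors 1..N preserving relative order."""
    return [a for a in order if a not in dead]
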