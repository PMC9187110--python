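"""Toroidal grid geometry.

Cells live on a square torus of side ``grid_side``; both axes wrap.  Two
neighbourhoods matter: the von Neumann radius-1 cross (a cell and its four
orthogonal neighbours) that forms a hunting group, and the Chebyshev radius-2
square minus the centre (24 cells) into which offspring are placed.

Scalar coordinate functions operate on ``(x, y)`` pairs; the ``*_indices``
builders return flat row-major index arrays used by the vectorised engine.
Flat index of cell ``(x, y)`` is ``x * grid_side + y``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

Coord = tuple[int, int]

#: Canonical hunting-group member order: centre, north, south, east, west.
#: Fixed purely so RNG consumption is reproducible.
_GROUP_OFFSETS = ((0, 0), (0, -1), (0, 1), (1, 0), (-1, 0))


def wrap(raw: Coord, grid_side: int) -> Coord:
    """Reduce a raw coordinate pair to its canonical representative on the torus."""
    if grid_side < 1:
        raise ValueError("grid_side must be >= 1")
    return (raw[0] % grid_side, raw[1] % grid_side)


def hunting_group_locations(center: Coord, grid_side: int) -> list[Coord]:
    """The 5 cells of the hunting group centred on ``center``.

    Order is canonical (centre, N, S, E, W).  Cells are distinct whenever
    ``grid_side >= 3``.
    """
    if grid_side < 3:
        raise ValueError("grid_side must be >= 3 for 5 distinct group cells")
    return [wrap((center[0] + dx, center[1] + dy), grid_side) for dx, dy in _GROUP_OFFSETS]


def offspring_candidate_locations(parent: Coord, grid_side: int) -> set[Coord]:
    """The 24 cells within Chebyshev distance 2 of ``parent``, excluding it.

    The square reading of "2-cell radius" is forced by the count: a 5x5 block
    minus its centre has 24 cells (a Manhattan ball would have 12).
    """
    if grid_side < 5:
        raise ValueError("grid_side must be >= 5 for 24 distinct candidate cells")
    cells = {
        wrap((parent[0] + dx, parent[1] + dy), grid_side)
        for dx in range(-2, 3)
        for dy in range(-2, 3)
        if (dx, dy) != (0, 0)
    }
    return cells


@lru_cache(maxsize=None)
def hunting_group_indices(grid_side: int) -> np.ndarray:
    """(N, 5) int array: row c lists the flat indices of the group centred on cell c.

    Columns follow the canonical member order (centre, N, S, E, W).
    """
    if grid_side < 3:
        raise ValueError("grid_side must be >= 3")
    x, y = np.divmod(np.arange(grid_side * grid_side), grid_side)
    cols = [
        ((x + dx) % grid_side) * grid_side + (y + dy) % grid_side
        for dx, dy in _GROUP_OFFSETS
    ]
    out = np.stack(cols, axis=1)
    out.setflags(write=False)
    return out


@lru_cache(maxsize=None)
def offspring_candidate_indices(grid_side: int) -> np.ndarray:
    """(N, 24) int array: row c lists flat indices of cell c's offspring candidates.

    Candidate order is fixed (row-major over the 5x5 block, centre skipped)
    so placement draws are reproducible.
    """
    if grid_side < 5:
        raise ValueError("grid_side must be >= 5")
    x, y = np.divmod(np.arange(grid_side * grid_side), grid_side)
    cols = [
        ((x + dx) % grid_side) * grid_side + (y + dy) % grid_side
        for dx in range(-2, 3)
        for dy in range(-2, 3)
        if (dx, dy) != (0, 0)
    ]
    out = np.stack(cols, axis=1)
    out.setflags(write=False)
    return out
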