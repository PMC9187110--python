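"""Resolution of a single 5-member hunting game.

Each member decides GROUP or SOLO.  Solo hunters roll independent
Bernoulli(``solo_success``) trials for the fixed ``solo_payoff``.  All k
group hunters share one success roll — probability ``group_success`` when
k >= 2, ``lone_group_success`` when a single agent attempts a group hunt —
because the hunt succeeds or fails as a unit.  On success the pot is
``k * payoff_multiplier * solo_payoff`` (the per-capita average is conserved
regardless of k) and is divided geometrically by sharing rank: each hunter
receives ``tolerance`` times the share of the hunter ranked just above it.
Failed hunts, solo or group, pay nothing.

:func:`expected_payoffs` enumerates all 2^5 decision profiles and is the
exact analytic counterpart of the stochastic resolver, used as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .config import GROUP_SIZE, SimConfig
from .genome import Decision


def share_vector(k: int, tolerance: float, per_capita: float) -> np.ndarray:
    """Payoff shares for ``k`` successful group hunters, by sharing rank.

    Shares are proportional to ``tolerance**(i-1)`` for sharing rank i and
    normalised so their sum is exactly ``k * per_capita`` (the per-capita
    average is conserved whatever the skew).  ``tolerance == 1`` is an exact
    equal split, avoiding the 0/0 in the geometric normalisation.
    """
    if k < 1:
        raise ValueError("at least one hunter required")
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance out of range (must be in (0, 1])")
    if tolerance == 1.0:
        return np.full(k, per_capita)
    weights = tolerance ** np.arange(k)
    return k * per_capita * weights / weights.sum()


@dataclass
class GameOutcome:
    """Record of one resolved game; members indexed by relative rank (pos 0 = rank 1)."""

    decisions: list[Decision]
    group_success: bool | None  # None when nobody group hunted
    solo_success: list[bool | None]  # None for group hunters
    payoffs: np.ndarray


def resolve_decision_matrix(
    decisions: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Resolve a batch of games whose members are already in relative-rank order.

    Parameters
    ----------
    decisions
        (n_games, 5) boolean; column j is the decision (True = GROUP) of the
        member holding relative rank j+1.
    rng
        Consumes, in order, one group-success draw per game then one solo
        draw per member slot (drawn for every slot regardless of decision,
        so consumption is independent of the decisions).

    Returns
    -------
    (n_games, 5) payoffs in points, aligned with ``decisions``.
    """
    dec = np.asarray(decisions, dtype=bool)
    if dec.ndim != 2 or dec.shape[1] != GROUP_SIZE:
        raise ValueError(f"decisions must be (n_games, {GROUP_SIZE})")
    n = dec.shape[0]
    k = dec.sum(axis=1)

    group_p = np.where(k >= 2, cfg.group_success, cfg.lone_group_success)
    group_ok = (rng.random(n) < group_p) & (k >= 1)
    solo_ok = rng.random((n, GROUP_SIZE)) < cfg.solo_success

    # Columns are already rank-ordered, so a hunter's sharing rank is simply
    # the count of hunters at or before its column.
    sharing_rank = np.cumsum(dec, axis=1)  # 1-based where dec is True
    t = cfg.tolerance
    if t == 1.0:
        share = np.full((n, GROUP_SIZE), cfg.per_capita)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            share = (
                k[:, None]
                * cfg.per_capita
                * (1.0 - t)
                * t ** (sharing_rank - 1)
                / (1.0 - t ** k[:, None])
            )
        share = np.where(k[:, None] > 0, share, 0.0)

    payoffs = np.where(
        dec,
        np.where(group_ok[:, None], share, 0.0),
        np.where(solo_ok, cfg.solo_payoff, 0.0),
    )
    return payoffs


def resolve_game(
    decisions: list[Decision] | np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> GameOutcome:
    """Resolve one game whose 5 decisions are listed by relative rank."""
    if len(decisions) != GROUP_SIZE:
        raise ValueError(f"expected {GROUP_SIZE} decisions, got {len(decisions)}")
    dec = np.array(
        [d is Decision.GROUP if isinstance(d, Decision) else bool(d) for d in decisions]
    )
    k = int(dec.sum())
    payoffs = resolve_decision_matrix(dec[None, :], cfg, rng)[0]
    # Shares and the solo payoff are strictly positive, so success flags are
    # recoverable from the payoffs themselves.
    return GameOutcome(
        decisions=[Decision.GROUP if d else Decision.SOLO for d in dec],
        group_success=bool(payoffs[dec].sum() > 0) if k >= 1 else None,
        solo_success=[None if d else bool(pay > 0) for d, pay in zip(dec, payoffs)],
        payoffs=payoffs,
    )


def expected_payoffs(profile: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Exact expected payoff of each member, by relative rank.

    ``profile`` gives each member's group-hunt probability (0/1 encodes a
    deterministic strategy).  Enumerates the 2^5 decision outcomes, weighting
    each by its profile probability and the success probabilities; this is
    the closed-form oracle against which the stochastic resolver is checked.
    """
    p = np.asarray(profile, dtype=float)
    if p.shape != (GROUP_SIZE,):
        raise ValueError(f"profile must have length {GROUP_SIZE}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("profile entries must be probabilities")

    out = np.zeros(GROUP_SIZE)
    for dec in product((False, True), repeat=GROUP_SIZE):
        dec = np.array(dec)
        weight = np.prod(np.where(dec, p, 1.0 - p))
        if weight == 0.0:
            continue
        k = int(dec.sum())
        contrib = np.where(dec, 0.0, cfg.solo_success * cfg.solo_payoff)
        if k >= 1:
            p_succ = cfg.group_success if k >= 2 else cfg.lone_group_success
            contrib[dec] = p_succ * share_vector(k, cfg.tolerance, cfg.per_capita)
        out += weight * contrib
    return out


def monte_carlo_payoffs(
    profile: np.ndarray, cfg: SimConfig, rng: np.random.Generator, n_trials: int
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo mean payoff per relative rank, with its standard error.

    Draws ``n_trials`` games from ``profile`` and resolves them through
    :func:`resolve_decision_matrix` — the same code path as the world engine
    and :func:`resolve_game`.
    """
    p = np.asarray(profile, dtype=float)
    dec = rng.random((n_trials, GROUP_SIZE)) < p
    payoffs = resolve_decision_matrix(dec, cfg, rng)
    mean = payoffs.mean(axis=0)
    se = payoffs.std(axis=0, ddof=1) / np.sqrt(n_trials)
    return mean, se
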