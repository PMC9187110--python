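"""Group-hunt rate metrics: per-update rates by relative rank, the
sampling/windowing protocol, replicate and condition aggregation, and tidy
CSV output.

The published protocol samples every 1,000 updates and averages the last
100,000 updates of each replicate (101 samples, window endpoints inclusive),
then averages across replicates, reporting +/-2 standard errors of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import GROUP_SIZE, SimConfig, save_config

#: Relative-rank labels used in all tabular outputs (1 = highest in group).
RANKS = tuple(range(1, GROUP_SIZE + 1))


@dataclass(frozen=True)
class UpdateMetrics:
    """Group-hunt decision rates at one sampled update."""

    update_index: int
    group_decisions_by_relative_rank: np.ndarray  # 5 counts
    games_played: int

    @property
    def rate_by_relative_rank(self) -> np.ndarray:
        return self.group_decisions_by_relative_rank / self.games_played

    @property
    def population_rate(self) -> float:
        # Each relative rank occurs exactly once per game, so the unweighted
        # mean of the 5 rank rates is the population decision rate.
        return float(self.rate_by_relative_rank.mean())


def rates_from_decisions(decisions: np.ndarray, update_index: int = 0) -> UpdateMetrics:
    """Metrics for one update from its (n_games, 5) GROUP/SOLO decision matrix.

    Column j holds the decisions of the rank-(j+1) members across games; each
    game contributes exactly one decision per relative rank, so the rank-j
    rate is a plain decision frequency with the game count as denominator.
    """
    dec = np.asarray(decisions, dtype=bool)
    if dec.ndim != 2 or dec.shape[1] != GROUP_SIZE:
        raise ValueError(f"decision matrix must be (n_games, {GROUP_SIZE})")
    if dec.shape[0] == 0:
        raise ValueError("no games in decision record")
    return UpdateMetrics(
        update_index=update_index,
        group_decisions_by_relative_rank=dec.sum(axis=0),
        games_played=dec.shape[0],
    )


def sample_schedule(
    updates: int, sample_interval: int, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled update indices and their terminal-window membership.

    Samples sit at every multiple of ``sample_interval`` in [0, updates]; the
    window covers [updates - window, updates] with both endpoints inclusive
    (1,000,000 updates at interval 1,000 with a 100,000 window gives 101
    window samples).
    """
    if window > updates:
        raise ValueError("window must not exceed updates")
    if window % sample_interval != 0:
        raise ValueError("sample_interval must divide window")
    samples = np.arange(0, updates + 1, sample_interval)
    in_window = samples >= updates - window
    return samples, in_window


@dataclass(frozen=True)
class ReplicateSummary:
    """Window-mean group-hunt rates of one replicate."""

    rate_by_relative_rank: np.ndarray  # 5 window means
    n_samples: int

    @property
    def population_rate(self) -> float:
        return float(self.rate_by_relative_rank.mean())


def summarize_replicate(window_rates: np.ndarray) -> ReplicateSummary:
    """Per-rank arithmetic mean over the (n_window_samples, 5) rate matrix."""
    rates = np.atleast_2d(np.asarray(window_rates, dtype=float))
    if rates.shape[0] == 0:
        raise ValueError("empty sampling window")
    if rates.shape[1] != GROUP_SIZE:
        raise ValueError(f"window rates must have {GROUP_SIZE} columns")
    return ReplicateSummary(
        rate_by_relative_rank=rates.mean(axis=0), n_samples=rates.shape[0]
    )


@dataclass(frozen=True)
class ConditionSummary:
    """Cross-replicate mean and standard error, per relative rank."""

    mean_by_relative_rank: np.ndarray
    se_by_relative_rank: np.ndarray
    n_replicates: int

    @property
    def two_se(self) -> np.ndarray:
        return 2.0 * self.se_by_relative_rank

    @property
    def population_rate(self) -> float:
        return float(self.mean_by_relative_rank.mean())


def summarize_condition(replicates: Sequence[ReplicateSummary]) -> ConditionSummary:
    """Mean and SE of the window means across replicates (needs >= 2)."""
    if len(replicates) < 2:
        raise ValueError("at least 2 replicates required for a standard error")
    rates = np.stack([r.rate_by_relative_rank for r in replicates])
    return ConditionSummary(
        mean_by_relative_rank=rates.mean(axis=0),
        se_by_relative_rank=rates.std(axis=0, ddof=1) / np.sqrt(rates.shape[0]),
        n_replicates=rates.shape[0],
    )


def _meta(cfg: SimConfig) -> dict:
    return {
        "condition_id": cfg.condition_id,
        "tolerance": cfg.tolerance,
        "payoff_multiplier": cfg.payoff_multiplier,
    }


def timeseries_frame(
    cfg: SimConfig, replicate: int, samples: Sequence[UpdateMetrics]
) -> pd.DataFrame:
    """Long-format per-update sampled rates for one replicate."""
    rows = []
    for m in samples:
        rates = m.rate_by_relative_rank
        for r in RANKS:
            rows.append(
                {
                    **_meta(cfg),
                    "replicate": replicate,
                    "update": m.update_index,
                    "relative_rank": r,
                    "group_hunt_rate": rates[r - 1],
                }
            )
    return pd.DataFrame(rows)


def replicate_summary_frame(
    cfg: SimConfig, summaries: Sequence[ReplicateSummary]
) -> pd.DataFrame:
    rows = []
    for rep, s in enumerate(summaries):
        for r in RANKS:
            rows.append(
                {
                    **_meta(cfg),
                    "replicate": rep,
                    "relative_rank": r,
                    "mean_group_hunt_rate": s.rate_by_relative_rank[r - 1],
                    "n_samples": s.n_samples,
                }
            )
    return pd.DataFrame(rows)


def condition_summary_frame(cfg: SimConfig, summary: ConditionSummary) -> pd.DataFrame:
    rows = []
    for r in RANKS:
        rows.append(
            {
                **_meta(cfg),
                "relative_rank": r,
                "mean_group_hunt_rate": summary.mean_by_relative_rank[r - 1],
                "two_se": summary.two_se[r - 1],
                "n_replicates": summary.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def write_outputs(
    cfg: SimConfig,
    timeseries: pd.DataFrame,
    replicate_summaries: pd.DataFrame,
    condition_summary: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three tidy CSVs plus a config echo into ``out_dir``.

    Rows are sorted on the identifying columns and columns keep a fixed
    order, so re-running with the same seed reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cid = cfg.condition_id
    paths = {
        "timeseries": out / f"{cid}_timeseries.csv",
        "replicates": out / f"{cid}_replicates.csv",
        "condition": out / f"{cid}_condition.csv",
        "config": out / f"{cid}_config.yaml",
    }
    sort_keys = {
        "timeseries": ["condition_id", "replicate", "update", "relative_rank"],
        "replicates": ["condition_id", "replicate", "relative_rank"],
        "condition": ["condition_id", "relative_rank"],
    }
    frames = {
        "timeseries": timeseries,
        "replicates": replicate_summaries,
        "condition": condition_summary,
    }
    for key, df in frames.items():
        df.sort_values(sort_keys[key]).to_csv(paths[key], index=False)
    save_config(cfg, paths["config"])
    return paths
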