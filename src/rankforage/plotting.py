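"""Convenience plot of condition summaries (rate vs tolerance, by relative rank).

Not part of the tested core; requires matplotlib (``pip install rankforage[plot]``).
"""

from __future__ import annotations

import pandas as pd


def plot_condition_summary(summary: pd.DataFrame, ax=None):
    """Mean group-hunt rate against tolerance, one line per relative rank.

    ``summary`` is a condition-summary table (columns ``tolerance``,
    ``relative_rank``, ``mean_group_hunt_rate``, ``two_se``) for a single
    payoff multiplier; error bars show +/-2 SE across replicates.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for rank, df in summary.groupby("relative_rank"):
        df = df.sort_values("tolerance")
        ax.errorbar(
            df["tolerance"],
            df["mean_group_hunt_rate"],
            yerr=df.get("two_se"),
            marker="o",
            capsize=3,
            label=f"rank {rank}",
        )
    ax.set_xlabel("tolerance")
    ax.set_ylabel("mean group-hunt rate")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(title="relative rank", fontsize="small")
    return ax
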