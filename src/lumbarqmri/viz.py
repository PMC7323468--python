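"""Quick plots of level-wise profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .roi import LEVELS, MUSCLES

__all__ = ["plot_level_profiles"]


def plot_level_profiles(table, metric: str, ax=None):
    """Mean ± SD of `metric` per level, one line per muscle."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for muscle in MUSCLES:
        sub = table[table["muscle"] == muscle]
        g = sub.groupby("level")[metric]
        means = g.mean().reindex(list(LEVELS))
        sds = g.std().reindex(list(LEVELS))
        ax.errorbar(range(len(LEVELS)), means, yerr=sds, marker="o", capsize=3,
                    label=muscle.replace("_", " "))
    ax.set_xticks(range(len(LEVELS)), LEVELS)
    ax.set_ylabel(metric)
    ax.set_xlabel("vertebral level")
    ax.legend()
    return ax
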