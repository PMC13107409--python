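"""Forest-style display of strategy validity and power."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import pandas as pd


def forest_plot(table: pd.DataFrame, scenario_fp: str = "null_balanced",
                scenario_power: str = "alt_balanced", threshold: float = 0.10):
    """Two-panel forest plot of a tidy results table: false-positive rate on
    the left, power on the right, strategies sorted by estimand then name,
    Wilson intervals as horizontal bars.

    Returns the matplotlib Figure.
    """
    needed = {"strategy", "estimand", "scenario", "rate", "ci_low", "ci_high"}
    missing = sorted(needed - set(table.columns))
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    order = (
        table[["strategy", "estimand"]]
        .drop_duplicates()
        .sort_values(["estimand", "strategy"], kind="stable")
        .reset_index(drop=True)
    )
    fig, axes = plt.subplots(
        1, 2, figsize=(9, 0.32 * len(order) + 1.5), sharey=True
    )
    y = range(len(order))
    for ax, scen, label in (
        (axes[0], scenario_fp, "false-positive rate"),
        (axes[1], scenario_power, "power"),
    ):
        sub = table[table["scenario"] == scen].set_index("strategy")
        for yi, row in order.iterrows():
            if row["strategy"] not in sub.index:
                continue
            r = sub.loc[row["strategy"]]
            ax.plot([r["ci_low"], r["ci_high"]], [yi, yi], "-", color="0.5", lw=1.5)
            ax.plot(r["rate"], yi, "o", color="C0", ms=4)
        ax.set_xlabel(label)
        ax.set_xlim(0, 1)
        ax.grid(axis="x", alpha=0.3)
    axes[0].axvline(threshold, color="C3", ls="--", lw=1)
    axes[0].set_yticks(list(y))
    axes[0].set_yticklabels(order["strategy"])
    axes[0].invert_yaxis()
    fig.tight_layout()
    return fig
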