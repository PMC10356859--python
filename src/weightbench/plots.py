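"""Optional Tukey-style plots of the weekly summary tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_weekly_summaries(
    summaries: pd.DataFrame,
    statistic: str,
    path: str | Path,
    *,
    ylabel: str | None = None,
) -> None:
    """Draw weekly Tukey boxes (one colour per model) from precomputed stats."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summaries[summaries.statistic == statistic]
    if sub.empty:
        raise ValueError(f"no rows for statistic {statistic!r}")
    fig, ax = plt.subplots(figsize=(7, 4))
    models = sorted(sub.model.unique())
    width = 0.8 / max(len(models), 1)
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for j, model in enumerate(models):
        rows = sub[sub.model == model].sort_values("week")
        boxes = [
            {
                "med": r.median,
                "q1": r.q1,
                "q3": r.q3,
                "whislo": r.whisker_low,
                "whishi": r.whisker_high,
                "mean": r.mean,
                "fliers": [],
                "label": str(int(r.week)),
            }
            for r in rows.itertuples()
        ]
        positions = [w + (j - (len(models) - 1) / 2) * width for w in rows.week]
        color = colors[j % len(colors)]
        ax.bxp(
            boxes,
            positions=positions,
            widths=width * 0.9,
            showmeans=True,
            boxprops={"color": color},
            whiskerprops={"color": color},
            capprops={"color": color},
            medianprops={"color": color},
            meanprops={"markerfacecolor": color, "markeredgecolor": color},
        )
        ax.plot([], [], color=color, label=model)
    ax.set_xlabel("program week")
    ax.set_ylabel(ylabel or statistic)
    ax.set_xticks(sorted(sub.week.unique()))
    ax.set_xticklabels([str(int(w)) for w in sorted(sub.week.unique())])
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
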