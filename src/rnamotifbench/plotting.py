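"""Bar-chart summaries of metric reports (matplotlib, imported lazily)."""

from __future__ import annotations

__all__ = ["plot_metric_bars"]

_METRICS = ("sn", "ppv", "sp")


def plot_metric_bars(reports: dict[str, dict], out_path) -> None:
    """Grouped bars of overall Sn/PPV/Sp, one group per metric, one bar per
    tool.  ``reports`` maps a tool label to a report dictionary (the
    ``as_dict`` form of a :class:`~rnamotifbench.scoring.MetricsReport`)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    labels = list(reports)
    x = np.arange(len(_METRICS), dtype=float)
    width = 0.8 / max(len(labels), 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, label in enumerate(labels):
        overall = reports[label]["overall"]
        heights = [
            overall.get(m) if overall.get(m) is not None else 0.0
            for m in _METRICS
        ]
        ax.bar(x + k * width, heights, width, label=label)
    ax.set_xticks(x + width * (len(labels) - 1) / 2)
    ax.set_xticklabels([m.upper() for m in _METRICS])
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("score")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
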