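"""Plot helpers for the evaluation outputs: rarefaction curves, per-stage
read accounting, and OTU category composition."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple


def plot_rarefaction(curves: Dict[str, List[Tuple[int, float]]], path) -> None:
    """One rarefaction curve per labelled series (depth on x, OTUs on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, points in curves.items():
        xs, ys = zip(*points)
        ax.plot(xs, ys, marker="o", markersize=3, label=label)
    ax.set_xlabel("reads sampled")
    ax.set_ylabel("expected OTUs")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stage_accounting(rows: Sequence, path) -> None:
    """Bar chart of reads removed per stage."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    stages = [r.stage for r in rows]
    removed = [r.removed for r in rows]
    ax.bar(stages, removed)
    ax.set_ylabel("reads removed")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_otu_categories(categories: Dict[str, str], path) -> None:
    """Pie of the four OTU categories (original/chimeric/contaminant/other)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = ["original", "chimeric", "contaminant", "other"]
    counts = [sum(1 for c in categories.values() if c == cat) for cat in order]
    fig, ax = plt.subplots(figsize=(4, 4))
    present = [(cat, n) for cat, n in zip(order, counts) if n > 0]
    ax.pie([n for _, n in present], labels=[c for c, _ in present],
           autopct="%d%%")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
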