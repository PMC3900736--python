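"""Optional QC figure: fold-change bars (mean ± SD) with significance stars."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stats import GroupComparison, ReplicateSummary

__all__ = ["fold_bar_plot"]


def fold_bar_plot(summaries: Sequence[ReplicateSummary], path: str | Path,
                  stars: Mapping[str, str] | None = None,
                  title: str = "Fold change vs reference") -> Path:
    """Bar chart of per-class mean fold ± SD across experiments.

    ``stars`` optionally maps class label → significance label (e.g. from a
    pooled :class:`~symquant.stats.GroupComparison`) to annotate the bars.
    """
    path = Path(path)
    labels = [s.class_label for s in summaries]
    means = [s.mean_fold for s in summaries]
    sds = [s.sd_fold for s in summaries]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 1.5, 3.2))
    ax.bar(labels, means, yerr=sds, capsize=4, color="#4878a8")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("fold change (signed)")
    ax.set_title(title)
    if stars:
        for i, lbl in enumerate(labels):
            if lbl in stars:
                offset = 0.05 * max(abs(m) + s for m, s in zip(means, sds))
                y = means[i] + (sds[i] + offset if means[i] >= 0
                                else -sds[i] - offset)
                ax.text(i, y, stars[lbl], ha="center",
                        va="bottom" if means[i] >= 0 else "top")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
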