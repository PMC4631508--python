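"""Mean-and-SEM ribbon plots of aligned cohorts."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .alignment import AlignedGroup


def plot_groups(groups: dict[str, AlignedGroup], descriptor: str,
                path, onset_time: float | None = None,
                ylabel: str | None = None) -> Path:
    """Plot per-group mean ± SEM ribbons over aligned time.

    ``onset_time`` (s, aligned axis) draws an arrowhead marking the median
    cytokinesis-onset call.
    """
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for name, g in groups.items():
        s = g.summary
        t = s["time_s"].to_numpy() / 60.0
        m = s[f"{descriptor}_mean"].to_numpy()
        sem = s[f"{descriptor}_sem"].to_numpy()
        line, = ax.plot(t, m, label=f"{name} (n={g.n})")
        ax.fill_between(t, m - sem, m + sem, alpha=0.3,
                        color=line.get_color())
    if onset_time is not None:
        ax.annotate("", xy=(onset_time / 60.0, ax.get_ylim()[1]),
                    xytext=(onset_time / 60.0,
                            ax.get_ylim()[1] + 0.06 * np.diff(ax.get_ylim())[0]),
                    arrowprops=dict(arrowstyle="-|>", color="k"))
    ax.set_xlabel("time from elongation onset (min)")
    ax.set_ylabel(ylabel or descriptor.replace("_", " "))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
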