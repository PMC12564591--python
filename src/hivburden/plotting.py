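"""Optional PNG rendering for the scatter, radar, and heatmap views.

Thin matplotlib layer over the tabular outputs; nothing here feeds back
into the analysis.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .burden import DomainProfile, GroupProfile, ScatterRefs
from .catalog import DOMAINS


def plot_scatter(df: pd.DataFrame, refs: ScatterRefs, path: str | Path) -> None:
    """Disclosure vs isolation scatter with the median and cutoff reference lines."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["x_jit"], df["y_jit"], alpha=0.8)
    ax.axvline(refs.x_median, color="tab:blue", linestyle="--", label="median disclosures")
    ax.axhline(refs.y_threshold, color="tab:red", linestyle="--", label="isolation cutoff")
    ax.set_xlabel("people told (capped)")
    ax.set_ylabel("isolation score (0–15)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_radar(profiles: Sequence[DomainProfile], path: str | Path) -> None:
    """Seven-domain burden radar, one trace per disclosure group."""
    angles = np.linspace(0, 2 * np.pi, len(DOMAINS), endpoint=False)
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"projection": "polar"})
    for prof in profiles:
        vals = [prof.values[d] for d in DOMAINS]
        closed_a = np.concatenate([angles, angles[:1]])
        closed_v = vals + vals[:1]
        ax.plot(closed_a, closed_v, label=f"{prof.label} (n={prof.n})")
        ax.fill(closed_a, closed_v, alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(DOMAINS, fontsize=8)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(profiles: Sequence[GroupProfile], path: str | Path) -> None:
    """Group-by-indicator percentage heatmap with 'count (pct%)' annotations."""
    indicators = list(profiles[0].cells)
    mat = np.full((len(indicators), len(profiles)), np.nan)
    for j, prof in enumerate(profiles):
        for i, iid in enumerate(indicators):
            cell = prof.cells[iid]
            if cell.percent is not None:
                mat[i, j] = cell.percent
    fig, ax = plt.subplots(figsize=(1.6 * len(profiles) + 2, 0.45 * len(indicators) + 2))
    im = ax.imshow(mat, cmap="Reds", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(len(profiles)))
    ax.set_xticklabels([f"{p.label}\n(n={p.n})" for p in profiles], fontsize=8)
    ax.set_yticks(range(len(indicators)))
    ax.set_yticklabels(indicators, fontsize=8)
    for j, prof in enumerate(profiles):
        for i, iid in enumerate(indicators):
            cell = prof.cells[iid]
            if cell.percent is not None:
                ax.text(
                    j,
                    i,
                    f"{cell.count} ({cell.percent:.0f}%)",
                    ha="center",
                    va="center",
                    fontsize=7,
                )
    fig.colorbar(im, ax=ax, label="% reporting")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
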