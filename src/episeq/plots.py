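"""Optional matplotlib figures (imported lazily; install the `plot` extra).

Axis clipping in the concordance scatter follows the display convention of
showing out-of-range points 0.1 beyond the limit — purely cosmetic, the
fitted statistics never see clipped values.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .concordance import AttenuationFit
from .cyclephase import PhaseEnrichmentResult
from .tables import MergedTable


def phase_dot_whisker(
    results: Sequence[PhaseEnrichmentResult], path: str, title: str = ""
) -> None:
    """Dot = median percentile rank, whiskers = IQR, one row per phase."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 0.6 * len(results) + 1))
    ys = np.arange(len(results))[::-1]
    for y, r in zip(ys, results):
        ax.plot([r.iqr[0], r.iqr[1]], [y, y], color="0.4", lw=2)
        ax.plot(r.median_rank, y, "o", color="C0")
    ax.axvline(0.5, color="0.7", ls="--", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels([r.phase for r in results])
    ax.set_xlim(0, 1)
    ax.set_xlabel("percentile rank of log2 fold change (WT/KO)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def concordance_scatter(
    merged: MergedTable,
    selected: set[str],
    fit: AttenuationFit,
    path: str,
    lim: float = 3.0,
) -> None:
    """Scatter of the selected genes' fold changes with the fitted line.

    Points beyond +/-lim are drawn at lim + 0.1 with open markers.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = merged.data[merged.data["gene"].isin(selected)]
    x = df[f"log2fc_{merged.label_b}"].to_numpy(dtype=float)
    y = df[f"log2fc_{merged.label_a}"].to_numpy(dtype=float)
    clip = (np.abs(x) > lim) | (np.abs(y) > lim)
    xc = np.clip(x, -lim - 0.1, lim + 0.1)
    yc = np.clip(y, -lim - 0.1, lim + 0.1)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(xc[~clip], yc[~clip], s=8, alpha=0.5)
    if clip.any():
        ax.scatter(xc[clip], yc[clip], s=12, facecolors="none", edgecolors="C3")
    grid = np.linspace(-lim, lim, 2)
    ax.plot(grid, fit.beta0 + fit.beta_upstream * grid, color="C1", lw=1.5)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(f"log2FC {merged.label_b}")
    ax.set_ylabel(f"log2FC {merged.label_a}")
    ax.set_title(f"slope {fit.beta_upstream:.2f} (n={fit.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
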