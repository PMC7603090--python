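"""Plot helpers for scan and structure results (matplotlib, file output only)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .types import ScanResult  # noqa: E402


def manhattan(result: ScanResult, statistic: str, path) -> None:
    """Genome-wide scatter of one statistic, candidates highlighted in red."""
    values = getattr(result, statistic)
    mask = getattr(result, f"candidate_{statistic}")
    pos = result.variants.pos
    chroms = result.variants.chrom
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, tick_labels = [], []
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        x = pos[sel] + offset
        ax.scatter(x, values[sel], s=4, c="grey", linewidths=0)
        if mask is not None:
            ax.scatter(x[mask[sel]], values[sel][mask[sel]], s=6, c="red", linewidths=0)
        ticks.append(x.mean())
        tick_labels.append(str(chrom))
        offset = x.max()
    thr = result.thresholds.get(statistic)
    if thr is not None:
        ax.axhline(thr, ls="--", lw=0.8, c="black")
    ax.set_xticks(ticks, tick_labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(statistic)
    ax.set_title(result.breed_pair)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(coords: np.ndarray, sample_pops: list[str], path) -> None:
    """PC1 vs PC2 colored by population."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for pop in dict.fromkeys(sample_pops):
        sel = np.array([p == pop for p in sample_pops])
        ax.scatter(coords[sel, 0], coords[sel, 1], s=18, label=pop)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
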