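"""Optional figures: fold-change scatter and enrichment ratio bars.

Requires matplotlib (``pip install speccount[plot]``); imported lazily so
the core pipeline has no plotting dependency.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence, Union

from .records import EnrichmentResult, FoldChangeRecord, ThresholdPair


def _pyplot():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_fold_change_scatter(
    records: Sequence[FoldChangeRecord],
    thresholds: ThresholdPair,
    path: Union[str, Path],
) -> None:
    """log2 fold change vs log2 total spectra, with the ±1 SD cutoff lines."""
    plt = _pyplot()
    shared = [r for r in records if r.log2fc is not None]
    x = [math.log2(r.total) for r in shared]
    y = [r.log2fc for r in shared]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, s=6, alpha=0.4, linewidths=0)
    for level in (thresholds.lower, thresholds.upper):
        ax.axhline(level, linestyle="-.", color="k", linewidth=0.8)
    ax.plot([], [], " ", label=f"mean {thresholds.mean_fc:.3f}")
    ax.axhline(thresholds.mean_fc, color="r", linewidth=0.6)
    ax.set_xlabel("log2 total spectra per protein")
    ax.set_ylabel("log2 fold change (B / A)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enrichment_ratios(
    results: Sequence[EnrichmentResult],
    path: Union[str, Path],
    top: int = 15,
) -> None:
    """Horizontal bars of the ratio of enrichment for the top categories."""
    plt = _pyplot()
    shown = [r for r in results if r.significant][:top] or list(results)[:top]
    names = [r.name for r in shown][::-1]
    ratios = [r.ratio for r in shown][::-1]
    fig, ax = plt.subplots(figsize=(6, 0.35 * max(4, len(shown)) + 1))
    ax.barh(names, ratios, color="steelblue")
    ax.set_xlabel("ratio of enrichment (observed / expected)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
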