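"""Minimal plotting helpers (cohort learning curves, interval histograms).

These are conveniences for quick inspection; figure styling is left to the
caller's matplotlib configuration.
"""

from __future__ import annotations

from typing import Mapping, Tuple

import numpy as np

from .metrics import LogHistogram, PerformanceMatrix


def plot_performance_curve(matrix: PerformanceMatrix, ax=None, label=None):
    """Column means across mice with standard-error bars, in percent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    means = matrix.column_means() * 100.0
    sems = matrix.column_sem() * 100.0
    positions = np.arange(len(means))
    ax.errorbar(positions, means.to_numpy(), yerr=sems.to_numpy(),
                marker="o", capsize=3, label=label)
    ax.set_xticks(positions)
    ax.set_xticklabels(list(means.index), rotation=45, ha="right")
    ax.set_ylabel(
        "% correct first nosepokes"
        if matrix.mode == "discrimination"
        else "% visits to rewarded corner"
    )
    ax.set_ylim(0, 100)
    if matrix.mode == "corner_preference":
        ax.axhline(25.0, linestyle=":", linewidth=1)  # 4-corner chance level
    return ax


def plot_interval_histograms(
    histograms: Mapping[Tuple[int, int], LogHistogram], axes=None
):
    """One log-x bar panel per (cage, corner)."""
    import matplotlib.pyplot as plt

    keys = sorted(histograms)
    if axes is None:
        _, axes = plt.subplots(1, len(keys), squeeze=False,
                               figsize=(3 * len(keys), 3))
        axes = axes[0]
    for ax, key in zip(axes, keys):
        histogram = histograms[key]
        lefts = [lo for lo, _ in histogram.bins]
        widths = [hi - lo for lo, hi in histogram.bins]
        ax.bar(lefts, histogram.counts, width=widths, align="edge")
        ax.set_xscale("log")
        for reference in (1.0, 60.0, 3600.0):  # second, minute, hour
            ax.axvline(reference, linestyle=":", linewidth=1)
        ax.set_title(f"cage {key[0]} corner {key[1]}")
        ax.set_xlabel("inter-visit interval (s)")
    return axes
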