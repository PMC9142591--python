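"""Minimal ERP and contrast plots (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pls import PLSResult


def plot_erp(
    erps: dict[str, np.ndarray], times_ms: np.ndarray, channel_index: int,
    ax=None, title: str = "",
):
    """Overlay condition-mean waveforms for one channel; negative up."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for label, wave in erps.items():
        ax.plot(times_ms, wave[channel_index], label=label)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (μV)")
    ax.invert_yaxis()
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    return ax


def plot_contrast(result: PLSResult, cell_names: list[str], ax=None, title: str = ""):
    """Bar plot of the design salience (overall contrast) of the tested LV."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(len(cell_names)), result.design_saliences[:, 0])
    ax.set_xticks(range(len(cell_names)))
    ax.set_xticklabels(cell_names, rotation=30, ha="right", fontsize=7)
    ax.set_ylabel("design salience")
    if title:
        ax.set_title(f"{title} (p = {result.p_value:.3f})")
    return ax
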