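"""Plots: three-panel 96-context profile comparison and weight pie chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; no display server needed
import matplotlib.pyplot as plt
import numpy as np

from .contexts import SUBSTITUTIONS
from .refit import RefitResult

#: Conventional substitution-class palette used by signature profile plots.
SUBSTITUTION_COLORS = {
    "C>A": "#03BCEE",
    "C>G": "#010101",
    "C>T": "#E32926",
    "T>A": "#CAC9C9",
    "T>C": "#A1CE63",
    "T>G": "#EBC6C4",
}

_BAR_COLORS = [SUBSTITUTION_COLORS[sub] for sub in SUBSTITUTIONS for _ in range(16)]


def _context_panel(ax, values: np.ndarray, title: str, ylim=None):
    ax.bar(np.arange(96), values, color=_BAR_COLORS, width=0.8)
    ax.set_xlim(-1, 96)
    if ylim is not None:
        ax.set_ylim(*ylim)
    ax.set_ylabel(title)
    ax.set_xticks(np.arange(8, 96, 16))
    ax.set_xticklabels(SUBSTITUTIONS)
    ax.tick_params(axis="x", length=0)


def plot_signatures(result: RefitResult, path: str | Path, fmt: str | None = None):
    """Three stacked bar panels: tumor profile, reconstruction, residual.

    Tumor and reconstruction panels share a common y-scale so they are
    visually comparable; the residual panel is annotated with the SSE.
    Returns the written path.
    """
    tumor = result.reconstructed + result.residual
    fig, axes = plt.subplots(3, 1, figsize=(12, 7), sharex=True)
    top = max(float(tumor.max()), float(result.reconstructed.max())) * 1.1 or 1.0
    _context_panel(axes[0], tumor, "tumor", ylim=(0, top))
    axes[0].set_title(result.sample_id)
    _context_panel(axes[1], result.reconstructed, "reconstructed", ylim=(0, top))
    _context_panel(axes[2], result.residual, "error")
    lim = max(abs(float(result.residual.min())), abs(float(result.residual.max())), 1e-3)
    axes[2].set_ylim(-1.2 * lim, 1.2 * lim)
    axes[2].axhline(0, color="0.6", lw=0.5)
    axes[2].annotate(
        f"SSE = {result.sse:.3g}", xy=(0.99, 0.9), xycoords="axes fraction",
        ha="right", va="top",
    )
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format=fmt)
    plt.close(fig)
    return path


def make_pie(
    weights: dict[str, float], unknown: float, path: str | Path,
    title: str = "", fmt: str | None = None,
):
    """Pie chart of assigned signature weights, plus an 'unknown' wedge.

    Zero-weight signatures draw no wedge; weights plus unknown must sum to 1.
    """
    wedges = {k: v for k, v in weights.items() if v > 0}
    if unknown > 0:
        wedges["unknown"] = unknown
    total = sum(wedges.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"weights + unknown sum to {total:.6g}, expected 1")
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.pie(
        list(wedges.values()),
        labels=list(wedges.keys()),
        autopct="%1.1f%%",
        startangle=90,
        counterclock=False,
    )
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, format=fmt)
    plt.close(fig)
    return path
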