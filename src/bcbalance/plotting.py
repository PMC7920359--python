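"""Fraction-profile plotting: one series per nucleotide across positions."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .balance import CriterionSpec, FractionMatrix
from .panel import VALID_BASES

_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#000000",
                "T": "#d62728"}


def fraction_profile_series(fm: FractionMatrix) -> dict[str, list[float]]:
    """The plotted data: base -> fractions at positions 1..L."""
    return {
        base: [float(v) for v in fm.values[:, i]]
        for i, base in enumerate(VALID_BASES)
    }


def plot_fraction_profile(fm: FractionMatrix,
                          criteria: Sequence[CriterionSpec],
                          path: str | Path) -> None:
    """Plot per-position nucleotide fractions with criterion corridors.

    Each base is one line over positions 1..L.  Corridor bounds are drawn
    as horizontal lines: bold for wide (lite-style) corridors, thin for
    tight ones, so nested corridors remain distinguishable.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series = fraction_profile_series(fm)
    positions = list(range(1, fm.L + 1))
    fig, ax = plt.subplots(figsize=(7, 4.2))
    for base, values in series.items():
        ax.plot(positions, values, marker="o", label=base,
                color=_BASE_COLORS[base])
    widths = sorted({c.upper - c.lower for c in criteria})
    for crit in criteria:
        lw = 2.4 if widths and (crit.upper - crit.lower) == widths[-1] \
            and len(widths) > 1 else 1.0
        for bound in (crit.lower, crit.upper):
            ax.axhline(bound, color="gray", linewidth=lw, linestyle="--")
        ax.text(fm.L + 0.15, crit.upper, crit.name, fontsize=8,
                va="center", color="gray")
    ax.axhline(0.25, color="lightgray", linewidth=0.8)
    ax.set_xlabel("barcode position (cycle)")
    ax.set_ylabel("nucleotide fraction")
    ax.set_xticks(positions)
    ax.set_ylim(-0.02, min(1.02, max(0.55, fm.values.max() + 0.1)))
    ax.legend(title="base", loc="upper right", fontsize=8)
    ax.set_title("Per-position nucleotide fractions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
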