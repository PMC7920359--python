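"""Pairwise Hamming distances and mismatch-tolerance safety checks.

Barcodes on a synchronous-cycle platform are fixed-length and read
position by position, so substitution-only Hamming distance is the right
dissimilarity: indels do not occur between cycles.  The minimum pairwise
distance d_min of a pool governs how many read errors demultiplexing can
tolerate before two samples merge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel import BarcodePanel, PanelError


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric integer Hamming-distance matrix over a panel.

    ``d_min``/``d_max`` are the extremes over distinct pairs, with one
    witnessing pair each (first in panel order).  They are ``None`` for a
    single-barcode matrix, where no distinct pair exists.
    """

    ids: tuple[str, ...]
    d: np.ndarray
    d_min: int | None
    d_max: int | None
    argmin_pair: tuple[str, str] | None
    argmax_pair: tuple[str, str] | None

    def __len__(self) -> int:
        return len(self.ids)

    def pairs_at_most(self, threshold: int) -> list[tuple[str, str, int]]:
        """All distinct pairs with distance <= threshold, in panel order."""
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                dij = int(self.d[i, j])
                if dij <= threshold:
                    out.append((self.ids[i], self.ids[j], dij))
        return out

    def to_dict(self) -> dict:
        return {
            "ids": list(self.ids),
            "distances": self.d.tolist(),
            "d_min": self.d_min,
            "d_max": self.d_max,
            "argmin_pair": list(self.argmin_pair) if self.argmin_pair else None,
            "argmax_pair": list(self.argmax_pair) if self.argmax_pair else None,
        }


def hamming_matrix(panel: BarcodePanel) -> DistanceMatrix:
    """All pairwise Hamming distances within a panel."""
    enc = panel.encoded()
    d = (enc[:, None, :] != enc[None, :, :]).sum(axis=2).astype(int)
    n = len(panel)
    if n < 2:
        return DistanceMatrix(
            ids=tuple(panel.ids), d=d, d_min=None, d_max=None,
            argmin_pair=None, argmax_pair=None,
        )
    iu = np.triu_indices(n, k=1)
    upper = d[iu]
    kmin = int(upper.argmin())
    kmax = int(upper.argmax())
    ids = panel.ids
    return DistanceMatrix(
        ids=tuple(ids),
        d=d,
        d_min=int(upper.min()),
        d_max=int(upper.max()),
        argmin_pair=(ids[iu[0][kmin]], ids[iu[1][kmin]]),
        argmax_pair=(ids[iu[0][kmax]], ids[iu[1][kmax]]),
    )


@dataclass(frozen=True)
class DecodabilityReport:
    """Safety of a pool against a mismatch tolerance m.

    Two conditions are reported, clearly separated:

    * ``no_merge_ok`` — the per-pool requirement that the number of read
      errors stays strictly below d_min (m < d_min).  When it fails,
      a read from one barcode can land exactly on another barcode and the
      samples merge silently.
    * ``unique_decode_ok`` — the standard coding-theory guarantee
      d_min >= 2m + 1: every read with at most m errors has a *unique*
      nearest barcode within m.  Weaker pools may still decode most reads
      but some error patterns land midway between two barcodes and must
      be discarded as ambiguous.
    """

    m: int
    d_min: int | None
    no_merge_ok: bool
    unique_decode_ok: bool
    merge_risk_pairs: tuple[tuple[str, str, int], ...]
    ambiguous_risk_pairs: tuple[tuple[str, str, int], ...]

    def to_dict(self) -> dict:
        return {
            "mismatch_tolerance": self.m,
            "d_min": self.d_min,
            "no_merge_ok": self.no_merge_ok,
            "unique_decode_ok": self.unique_decode_ok,
            "merge_risk_pairs": [list(p) for p in self.merge_risk_pairs],
            "ambiguous_risk_pairs": [
                list(p) for p in self.ambiguous_risk_pairs
            ],
        }


def decodability_check(panel: BarcodePanel, m: int) -> DecodabilityReport:
    """Check whether mismatch tolerance ``m`` is safe for this pool.

    ``panel`` may be a full panel or the subset actually pooled
    (``panel.subset(ids)``).
    """
    if m < 0:
        raise PanelError("mismatch tolerance must be >= 0")
    dm = hamming_matrix(panel)
    if dm.d_min is None:
        return DecodabilityReport(
            m=m, d_min=None, no_merge_ok=True, unique_decode_ok=True,
            merge_risk_pairs=(), ambiguous_risk_pairs=(),
        )
    merge = tuple(dm.pairs_at_most(m))
    ambiguous = tuple(dm.pairs_at_most(2 * m))
    return DecodabilityReport(
        m=m,
        d_min=dm.d_min,
        no_merge_ok=m < dm.d_min,
        unique_decode_ok=dm.d_min >= 2 * m + 1,
        merge_risk_pairs=merge,
        ambiguous_risk_pairs=ambiguous,
    )


def heatmap_annotations(dm: DistanceMatrix) -> list[list[str]]:
    """Cell labels for the distance heatmap (the integer distances)."""
    return [[str(int(v)) for v in row] for row in dm.d]


def plot_distance_heatmap(dm: DistanceMatrix, path: str | Path) -> None:
    """Render the pairwise-distance matrix as an annotated heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(dm)
    fig, ax = plt.subplots(figsize=(max(4, n * 0.45), max(3.5, n * 0.45)))
    im = ax.imshow(dm.d, cmap="viridis", vmin=0)
    labels = heatmap_annotations(dm)
    threshold = dm.d.max() / 2 if dm.d.size else 0
    for i in range(n):
        for j in range(n):
            ax.text(j, i, labels[i][j], ha="center", va="center",
                    fontsize=7,
                    color="white" if dm.d[i, j] < threshold else "black")
    ax.set_xticks(range(n), dm.ids, rotation=90, fontsize=7)
    ax.set_yticks(range(n), dm.ids, fontsize=7)
    ax.set_title("Pairwise Hamming distances")
    fig.colorbar(im, ax=ax, shrink=0.8, label="differing positions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
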