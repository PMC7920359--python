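"""Weighted per-position nucleotide fractions and balance criteria.

The quantity at the heart of the package: for a pooled set of barcodes
with mixing weights ``w_i``, the fraction of base ``b`` at barcode
position ``p`` is

    f(p, b) = sum_i w_i * [seq_i[p] == b] / sum_i w_i

On a patterned flow cell every barcode position is read in one chemistry
cycle across all DNA nanoballs simultaneously, and basecalling relies on
all four fluorophore channels being represented among neighbouring spots.
A pool is *color balanced* when every f(p, b) sits near the ideal 0.25;
imbalance at a cycle degrades the sequencer's per-cycle signal-to-noise
and inflates the share of unassignable (undecoded) reads.

Balance is judged against a *corridor* [lower, upper] around 0.25.  Two
corridors ship as defaults: ``strong`` (tight, modelled on vendor-approved
combination sets, which are exactly balanced) and ``lite`` (wide, the
empirical tolerance of the instrument).  A narrow band of width
``border_tol`` around each bound classifies positions as "on the border".
A set passes a criterion when the number of positions falling outside the
corridor does not exceed ``max_outside`` (0 by default: no position may
violate the corridor; expert use may allow up to 2).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .panel import BarcodePanel, PanelError, WeightedBarcodeSet, VALID_BASES

INSIDE = "inside"
BORDER = "border"
OUTSIDE = "outside"
_STATUS_RANK = {INSIDE: 0, BORDER: 1, OUTSIDE: 2}


@dataclass(frozen=True)
class FractionMatrix:
    """Per-position x per-base weighted nucleotide fractions.

    ``values[p, b]`` is f(p+1, base) with bases ordered A, C, G, T.
    Rows sum to 1; entries lie in [0, 1].
    """

    values: np.ndarray
    total_weight: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != 4:
            raise ValueError(f"fraction matrix must be L x 4, got {v.shape}")
        if self.total_weight <= 0:
            raise ValueError("total_weight must be positive")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("fractions must lie in [0, 1]")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1 at every position")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def max_deviation(self) -> float:
        """Largest |f(p,b) - 0.25| over all cells."""
        return float(np.abs(self.values - 0.25).max())

    def fraction(self, position: int, base: str) -> float:
        """f at 1-based ``position`` for ``base``."""
        return float(self.values[position - 1, VALID_BASES.index(base)])

    def to_dict(self) -> dict:
        return {
            "bases": list(VALID_BASES),
            "positions": list(range(1, self.L + 1)),
            "values": self.values.tolist(),
            "total_weight": self.total_weight,
        }


@dataclass(frozen=True)
class CriterionSpec:
    """A balance corridor with border tolerance and violation allowance.

    ``lower``/``upper`` bracket the ideal fraction 0.25.  A cell is
    outside when f < lower - border_tol or f > upper + border_tol, on the
    border when within border_tol of either bound, inside otherwise.  A
    corridor may be degenerate ([0.25, 0.25]) when derived from perfectly
    balanced reference sets.
    """

    name: str
    lower: float
    upper: float
    border_tol: float = 0.01
    max_outside: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= 0.25 <= self.upper <= 1.0):
            raise ValueError(
                f"corridor [{self.lower}, {self.upper}] must bracket 0.25 "
                "within [0, 1]"
            )
        if self.border_tol < 0:
            raise ValueError("border_tol must be non-negative")
        if self.upper > self.lower and \
                self.border_tol >= (self.upper - self.lower) / 2:
            raise ValueError("border_tol must be < half the corridor width")
        if self.max_outside < 0:
            raise ValueError("max_outside must be non-negative")

    def classify(self, f: float) -> str:
        if f < self.lower - self.border_tol or f > self.upper + self.border_tol:
            return OUTSIDE
        if abs(f - self.lower) <= self.border_tol or \
                abs(f - self.upper) <= self.border_tol:
            return BORDER
        return INSIDE

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lower": self.lower,
            "upper": self.upper,
            "border_tol": self.border_tol,
            "max_outside": self.max_outside,
        }


@dataclass(frozen=True)
class BalanceVerdict:
    """Per-position classification of a fraction matrix under a criterion."""

    criterion: CriterionSpec
    per_position: tuple[str, ...]
    max_deviation: float
    offending: tuple[tuple[int, str, float], ...]

    @property
    def n_inside(self) -> int:
        return sum(s == INSIDE for s in self.per_position)

    @property
    def n_border(self) -> int:
        return sum(s == BORDER for s in self.per_position)

    @property
    def n_outside(self) -> int:
        return sum(s == OUTSIDE for s in self.per_position)

    @property
    def passed(self) -> bool:
        return self.n_outside <= self.criterion.max_outside

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion.to_dict(),
            "pass": self.passed,
            "n_inside": self.n_inside,
            "n_border": self.n_border,
            "n_outside": self.n_outside,
            "max_deviation": self.max_deviation,
            "per_position": list(self.per_position),
            "offending": [
                {"position": p, "base": b, "fraction": f}
                for p, b, f in self.offending
            ],
        }


def compute_fraction_matrix(wset: WeightedBarcodeSet,
                            panel: BarcodePanel) -> FractionMatrix:
    """Weighted per-position nucleotide fractions of a pooled set.

    Invariant under rescaling all weights by a positive constant.
    """
    sub = panel.subset(wset.members)  # raises on unknown member ids
    enc = sub.encoded()  # (n, L)
    w = wset.normalized_weights  # (n,)
    L = panel.L
    values = np.zeros((L, 4))
    for b in range(4):
        values[:, b] = ((enc == b) * w[:, None]).sum(axis=0)
    return FractionMatrix(values=values, total_weight=wset.total_weight)


def evaluate_criterion(fm: FractionMatrix,
                       crit: CriterionSpec) -> BalanceVerdict:
    """Classify every position of a fraction matrix against a corridor.

    A position's status is the worst status among its four bases
    (outside > border > inside) — violating *positions* are counted, not
    violating cells.  The verdict passes when the number of outside
    positions does not exceed ``crit.max_outside``.
    """
    per_position: list[str] = []
    offending: list[tuple[int, str, float]] = []
    for p in range(fm.L):
        worst = INSIDE
        for b in range(4):
            status = crit.classify(float(fm.values[p, b]))
            if status == OUTSIDE:
                offending.append(
                    (p + 1, VALID_BASES[b], float(fm.values[p, b]))
                )
            if _STATUS_RANK[status] > _STATUS_RANK[worst]:
                worst = status
        per_position.append(worst)
    return BalanceVerdict(
        criterion=crit,
        per_position=tuple(per_position),
        max_deviation=fm.max_deviation,
        offending=tuple(offending),
    )


def default_criteria() -> tuple[CriterionSpec, CriterionSpec]:
    """The default (strong, lite) corridors.

    The strong corridor models the tight balance of vendor-approved
    combination sets; the lite corridor models the wider tolerance the
    instrument exhibits in practice.  Both are configuration-first: users
    with a vendor panel should regenerate the strong corridor with
    :func:`derive_corridor_from_sets`, and any bound can be overridden
    from a TOML criterion file.
    """
    strong = CriterionSpec("strong", lower=0.15, upper=0.35,
                           border_tol=0.01, max_outside=0)
    lite = CriterionSpec("lite", lower=0.05, upper=0.45,
                         border_tol=0.01, max_outside=0)
    return strong, lite


def get_criterion(name_or_path: str) -> CriterionSpec:
    """Resolve ``strong``, ``lite`` or a TOML criterion file path."""
    strong, lite = default_criteria()
    if name_or_path == "strong":
        return strong
    if name_or_path == "lite":
        return lite
    path = Path(name_or_path)
    if path.exists():
        return load_criterion(path)
    raise PanelError(
        f"criterion must be 'strong', 'lite' or a TOML file; "
        f"got {name_or_path!r}"
    )


def load_criterion(path: str | Path) -> CriterionSpec:
    """Load a criterion from a TOML file.

    Keys: ``name``, ``lower``, ``upper``, ``border_tol``, ``max_outside``
    (either top-level or under a ``[criterion]`` table).  Missing keys
    fall back to the strong defaults.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "criterion" in data:
        data = data["criterion"]
    strong, _ = default_criteria()
    return CriterionSpec(
        name=str(data.get("name", "custom")),
        lower=float(data.get("lower", strong.lower)),
        upper=float(data.get("upper", strong.upper)),
        border_tol=float(data.get("border_tol", strong.border_tol)),
        max_outside=int(data.get("max_outside", strong.max_outside)),
    )


def dump_criterion(crit: CriterionSpec, path: str | Path) -> None:
    """Write a criterion as TOML readable by :func:`load_criterion`."""
    Path(path).write_text(
        "[criterion]\n"
        f'name = "{crit.name}"\n'
        f"lower = {crit.lower!r}\n"
        f"upper = {crit.upper!r}\n"
        f"border_tol = {crit.border_tol!r}\n"
        f"max_outside = {crit.max_outside}\n"
    )


def derive_corridor_from_sets(reference_sets: Sequence[WeightedBarcodeSet],
                              panel: BarcodePanel,
                              name: str = "derived",
                              border_tol: float | None = None,
                              max_outside: int | None = None) -> CriterionSpec:
    """Derive a corridor as the envelope of reference fraction matrices.

    The corridor is [min, max] over every f(p, b) of every reference set —
    the empirical band spanned by sets known to sequence well.  A single
    perfectly balanced reference yields the degenerate corridor
    [0.25, 0.25].  ``border_tol`` and ``max_outside`` default to the
    strong-criterion values.
    """
    if not reference_sets:
        raise PanelError("need at least one reference set")
    strong, _ = default_criteria()
    lo, hi = 1.0, 0.0
    for wset in reference_sets:
        fm = compute_fraction_matrix(wset, panel)
        lo = min(lo, float(fm.values.min()))
        hi = max(hi, float(fm.values.max()))
    tol = strong.border_tol if border_tol is None else border_tol
    if hi > lo and tol >= (hi - lo) / 2:
        tol = (hi - lo) / 2 * 0.99
    return CriterionSpec(
        name=name,
        lower=min(lo, 0.25),
        upper=max(hi, 0.25),
        border_tol=tol if hi > lo else 0.0,
        max_outside=strong.max_outside if max_outside is None else max_outside,
    )
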