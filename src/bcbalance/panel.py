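"""Barcode panels and weighted barcode sets.

A *panel* is the universe of fixed-length index (barcode) oligos a lab can
draw from — e.g. the 96/128-barcode list a sequencer vendor ships.  A
*weighted set* is the subset of a panel actually pooled on one lane,
together with the mixing proportions of the corresponding libraries.

Panels are stored either as a two-column TSV (``id<TAB>sequence``, header
required, ``#`` comment lines skipped) or as plain FASTA with one barcode
per record.  Sequences are uppercased on input; any character outside
``ACGT`` is a hard error — the balance computation counts exact nucleotide
identities, so IUPAC ambiguity codes have no meaning here.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(VALID_BASES)}


class PanelError(ValueError):
    """Raised for invalid barcode panels, sets or panel files."""


@dataclass(frozen=True)
class Barcode:
    """A single identified barcode sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise PanelError("barcode id must be non-empty")
        if any(c.isspace() for c in self.id):
            raise PanelError(f"barcode id {self.id!r} contains whitespace")
        object.__setattr__(self, "seq", self.seq.upper())
        for pos, c in enumerate(self.seq, start=1):
            if c not in _BASE_INDEX:
                raise PanelError(
                    f"non-ACGT character {c!r} at {self.id} position {pos}"
                )
        if not self.seq:
            raise PanelError(f"barcode {self.id} has empty sequence")


class BarcodePanel:
    """An ordered collection of unique, equal-length barcodes.

    Order is file order and is preserved through round-trips; all
    deterministic outputs elsewhere in the package (rankings, reports)
    break ties in this order.
    """

    def __init__(self, barcodes: Iterable[Barcode]):
        self.barcodes: list[Barcode] = list(barcodes)
        if not self.barcodes:
            raise PanelError("panel must contain at least one barcode")
        lengths = sorted({len(b.seq) for b in self.barcodes})
        if len(lengths) > 1:
            raise PanelError(
                f"ragged barcode lengths: found lengths {lengths}"
            )
        self.L: int = lengths[0]
        seen_ids: dict[str, str] = {}
        seen_seqs: dict[str, str] = {}
        for bc in self.barcodes:
            if bc.id in seen_ids:
                raise PanelError(f"duplicate barcode id {bc.id!r}")
            dup = seen_seqs.get(bc.seq)
            if dup is not None:
                raise PanelError(
                    f"duplicate sequence {bc.seq} shared by {dup} and {bc.id}"
                )
            seen_ids[bc.id] = bc.seq
            seen_seqs[bc.seq] = bc.id
        self._by_id = {bc.id: bc for bc in self.barcodes}

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self) -> Iterator[Barcode]:
        return iter(self.barcodes)

    def __contains__(self, barcode_id: str) -> bool:
        return barcode_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BarcodePanel):
            return NotImplemented
        return self.barcodes == other.barcodes

    @property
    def ids(self) -> list[str]:
        return [bc.id for bc in self.barcodes]

    def get(self, barcode_id: str) -> Barcode:
        try:
            return self._by_id[barcode_id]
        except KeyError:
            raise PanelError(f"unknown barcode id {barcode_id!r}") from None

    def subset(self, ids: Sequence[str]) -> "BarcodePanel":
        """Panel restricted to ``ids``, in the given order."""
        return BarcodePanel(self.get(i) for i in ids)

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix with A,C,G,T mapped to 0..3."""
        return encode_seqs([bc.seq for bc in self.barcodes])


def encode_seqs(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length ACGT strings as an (n, L) uint8 array."""
    lut = np.zeros(128, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return lut[flat].reshape(len(seqs), -1)


def decode_seq(row: np.ndarray) -> str:
    return "".join(VALID_BASES[i] for i in row)


@dataclass
class WeightedBarcodeSet:
    """A chosen subset of a panel with positive mixing proportions.

    Weights are on an arbitrary scale (``9:9:9:9:5:5:5:5:5:5`` is as valid
    as the normalized equivalent); every computation downstream uses
    ``normalized_weights`` and is therefore invariant to rescaling.
    """

    members: list[str]
    weights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = list(self.members)
        if not self.members:
            raise PanelError("weighted set must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise PanelError("weighted set members must be distinct")
        if not self.weights:
            self.weights = [1.0] * len(self.members)
        self.weights = [float(w) for w in self.weights]
        if len(self.weights) != len(self.members):
            raise PanelError(
                f"{len(self.members)} members but {len(self.weights)} weights"
            )
        if any(w <= 0 for w in self.weights):
            raise PanelError("all weights must be positive")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights))

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()

    @classmethod
    def equal(cls, members: Sequence[str]) -> "WeightedBarcodeSet":
        """Equal proportions — the default when no shares are given."""
        return cls(list(members))


# ---------------------------------------------------------------------------
# File I/O


def _read_panel_tsv(text: str, source: str) -> BarcodePanel:
    lines = [
        ln for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise PanelError(f"{source}: empty panel file")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header[:2] != ["id", "sequence"]:
        raise PanelError(
            f"{source}: expected header 'id<TAB>sequence', got {lines[0]!r}"
        )
    barcodes = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) < 2:
            raise PanelError(f"{source} line {lineno}: expected 2 columns")
        barcodes.append(Barcode(parts[0].strip(), parts[1].strip()))
    return BarcodePanel(barcodes)


def _read_panel_fasta(handle: io.TextIOBase) -> BarcodePanel:
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise PanelError("no FASTA records found")
    return BarcodePanel(Barcode(r.id, str(r.seq)) for r in records)


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if path.suffix.lower() in {".tsv", ".txt"}:
        return "tsv"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "tsv"
    return "tsv"


def read_panel(path: str | Path, format: str = "auto") -> BarcodePanel:
    """Read a barcode panel from a TSV or FASTA file.

    Sequences are uppercased; duplicate ids or sequences, non-ACGT
    characters and ragged lengths raise :class:`PanelError` naming the
    offending record.
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")
    if format == "auto":
        format = _sniff_format(path)
    if format == "tsv":
        return _read_panel_tsv(path.read_text(), str(path))
    if format == "fasta":
        with open(path) as fh:
            return _read_panel_fasta(fh)
    raise PanelError(f"unknown panel format {format!r}")


def write_panel(panel: BarcodePanel, path: str | Path,
                format: str = "auto") -> None:
    """Write a panel so that :func:`read_panel` recovers an equal panel."""
    if str(path) == "":
        raise PanelError("empty output path")
    path = Path(path)
    if format == "auto":
        format = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} \
            else "tsv"
    if format == "tsv":
        lines = ["id\tsequence"]
        lines += [f"{bc.id}\t{bc.seq}" for bc in panel]
        path.write_text("\n".join(lines) + "\n")
    elif format == "fasta":
        records = [
            SeqRecord(Seq(bc.seq), id=bc.id, description="") for bc in panel
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        raise PanelError(f"unknown panel format {format!r}")


def read_set_spec(path: str | Path) -> WeightedBarcodeSet:
    """Read a set specification TSV: columns ``id<TAB>weight``.

    The weight column is optional; a missing weight means 1.0 (equal
    shares when omitted everywhere).
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"set spec file not found: {path}")
    members: list[str] = []
    weights: list[float] = []
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    start = 0
    if lines and lines[0].split("\t")[0].strip().lower() == "id":
        start = 1
    for ln in lines[start:]:
        parts = ln.split("\t")
        members.append(parts[0].strip())
        if len(parts) > 1 and parts[1].strip():
            try:
                weights.append(float(parts[1]))
            except ValueError:
                raise PanelError(
                    f"{path}: bad weight {parts[1]!r} for {parts[0]!r}"
                ) from None
        else:
            weights.append(1.0)
    return WeightedBarcodeSet(members, weights)


# ---------------------------------------------------------------------------
# Synthetic fixtures


def make_balanced_set(n_barcodes: int, L: int = 10,
                      seed: int | None = None) -> BarcodePanel:
    """Generate a panel that is exactly color-balanced at equal weights.

    Each position (sequencing cycle) receives exactly ``n/4`` copies of
    every nucleotide, shuffled independently per column, so the fraction
    of each base at each position is 0.25 by construction when all
    barcodes are pooled in equal proportions.

    ``n_barcodes`` must be a positive multiple of 4.
    """
    if n_barcodes < 4 or n_barcodes % 4 != 0:
        raise PanelError(
            f"n_barcodes must be a positive multiple of 4, got {n_barcodes}"
        )
    rng = np.random.default_rng(seed)
    column_pool = np.repeat(np.arange(4, dtype=np.uint8), n_barcodes // 4)
    for _ in range(1000):
        mat = np.column_stack(
            [rng.permutation(column_pool) for _ in range(L)]
        )
        seqs = [decode_seq(row) for row in mat]
        if len(set(seqs)) == n_barcodes:
            width = len(str(n_barcodes))
            return BarcodePanel(
                Barcode(f"BC{i + 1:0{width}d}", s)
                for i, s in enumerate(seqs)
            )
    raise PanelError(
        "could not generate distinct balanced barcodes; increase L"
    )


def make_random_panel(n: int, L: int = 10, min_distance: int = 0,
                      seed: int | None = None,
                      max_attempts: int | None = None) -> BarcodePanel:
    """Generate a random panel with a guaranteed minimum pairwise distance.

    Rejection sampling: candidate sequences are drawn uniformly and kept
    only if their Hamming distance to every accepted barcode is at least
    ``min_distance``.  This emulates the structure of vendor panels, whose
    barcodes differ in at least 4 of 10 positions.
    """
    if n < 1:
        raise PanelError("n must be >= 1")
    if min_distance > L:
        raise PanelError(f"min_distance {min_distance} exceeds length {L}")
    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = max(10_000, 2_000 * n)
    accepted: list[np.ndarray] = []
    accepted_mat = np.empty((0, L), dtype=np.uint8)
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PanelError(
                f"could not place {n} barcodes of length {L} with minimum "
                f"distance {min_distance} in {max_attempts} attempts; "
                "reduce n or min_distance"
            )
        cand = rng.integers(0, 4, size=L, dtype=np.uint8)
        if accepted_mat.shape[0]:
            d = (accepted_mat != cand).sum(axis=1)
            if d.min() < max(min_distance, 1):
                continue
        accepted.append(cand)
        accepted_mat = np.vstack([accepted_mat, cand])
    width = len(str(n))
    return BarcodePanel(
        Barcode(f"BC{i + 1:0{width}d}", decode_seq(row))
        for i, row in enumerate(accepted)
    )
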