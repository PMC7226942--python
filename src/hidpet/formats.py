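"""Domain types and readers/writers for every external format the pipeline touches.

All genomic coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Two intervals overlap iff ``a.start < b.end and
b.start < a.end``.  This module is the single home for coordinate
conventions and parse errors; nothing downstream re-parses text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomicInterval",
    "IntervalSet",
    "Loop",
    "PWMRecord",
    "PPIEdge",
    "read_intervals",
    "write_intervals",
    "read_loops",
    "write_loops",
    "read_pwms",
    "write_pwms",
    "read_edge_table",
    "write_edge_table",
    "read_expression",
    "write_expression",
    "read_fasta",
    "write_fasta",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open span on a chromosome.

    ``label`` carries whatever the fourth BED column held: a chromatin
    state, a TF name, or a gene name.  Ordering is genomic
    (chrom, start, end).
    """

    chrom: str
    start: int
    end: int
    label: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """A named collection of intervals, grouped per chromosome, sorted by start.

    Exposes cached numpy start/end arrays per chromosome so overlap and
    nearest-neighbour queries downstream run on sorted arrays rather
    than Python loops.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval] = ()):
        self.name = name
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort()
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def on(self, chrom: str) -> Sequence[GenomicInterval]:
        return self._by_chrom.get(chrom, ())

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for ``chrom``, sorted by start; empty arrays if absent."""
        if chrom not in self._arrays:
            ivs = self._by_chrom.get(chrom, ())
            starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs))
            ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs))
            self._arrays[chrom] = (starts, ends)
        return self._arrays[chrom]

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.name == other.name and list(self) == list(other)

    def __repr__(self) -> str:
        return f"IntervalSet({self.name!r}, n={len(self)})"

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals overlapping ``query`` by >= 1 bp."""
        ivs = self._by_chrom.get(query.chrom, ())
        return [iv for iv in ivs if iv.start < query.end and query.start < iv.end]


def _canonical_anchor_order(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[GenomicInterval, GenomicInterval, bool]:
    if (a.chrom, a.start, a.end) <= (b.chrom, b.start, b.end):
        return a, b, False
    return b, a, True


@dataclass
class Loop:
    """A chromatin contact: two anchors plus a tag-count evidence weight.

    Intra-chromosomal loops are stored in canonical genome order
    (``anchor_a`` upstream); the constructor swaps if needed.  State
    label sets are filled by :mod:`hidpet.loops`.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    tags: int
    states_a: frozenset[str] = frozenset()
    states_b: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.tags < 0:
            raise ValidationError(f"negative tag count {self.tags}")
        a, b, swapped = _canonical_anchor_order(self.anchor_a, self.anchor_b)
        if swapped:
            self.anchor_a, self.anchor_b = a, b
            self.states_a, self.states_b = self.states_b, self.states_a
        self.states_a = frozenset(self.states_a)
        self.states_b = frozenset(self.states_b)

    @property
    def coords(self) -> tuple:
        """Hashable anchor-coordinate key (canonical orientation)."""
        a, b = self.anchor_a, self.anchor_b
        return (a.chrom, a.start, a.end, b.chrom, b.start, b.end)


@dataclass(frozen=True)
class PWMRecord:
    """A position probability matrix over A,C,G,T for one TF motif."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # width x 4, rows sum to 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValidationError(f"PWM {self.motif_id}: matrix must be width x 4")
        if (m < 0).any():
            raise ValidationError(f"PWM {self.motif_id}: negative probabilities")
        sums = m.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-4:
            raise ValidationError(
                f"PWM {self.motif_id}: row sums deviate from 1 by more than 1e-4"
            )
        object.__setattr__(self, "matrix", m / sums[:, None])

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class PPIEdge:
    """One undirected protein-protein interaction record.

    STRING rows carry a combined score; BioGRID rows carry an evidence
    system string.  Stored with ``protein_a <= protein_b``
    lexicographically so duplicates collapse under set semantics.
    """

    protein_a: str
    protein_b: str
    source: str  # "string_db" | "biogrid"
    score: float | None = None
    evidence: str | None = None

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValidationError(f"self edge {self.protein_a}")
        if self.source not in ("string_db", "biogrid"):
            raise ValidationError(f"unknown PPI source {self.source!r}")
        if self.protein_a > self.protein_b:
            a, b = self.protein_a, self.protein_b
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, format_hint: str = "bed3") -> IntervalSet:
    """Read a BED3/BED4/BED6 file into an :class:`IntervalSet`.

    The set name is the file stem.  Column 4, when present, becomes the
    interval label; column 6 the strand.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            label = cols[3] if len(cols) >= 4 else None
            strand = cols[5] if len(cols) >= 6 else None
            try:
                intervals.append(
                    GenomicInterval(cols[0], start, end, label=label, strand=strand)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(path.stem, intervals)


def write_intervals(iset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None or iv.strand is not None:
                cols.append(iv.label if iv.label is not None else ".")
            if iv.strand is not None:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BEDPE loops
# ---------------------------------------------------------------------------

def read_loops(path: str | Path) -> list[Loop]:
    """Read a BEDPE-like contact list; column 7 is the PET tag count."""
    path = Path(path)
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                a = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
                b = GenomicInterval(cols[3], int(cols[4]), int(cols[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad anchor coordinates: {exc}") from exc
            try:
                tags = int(cols[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer tag count {cols[6]!r}") from exc
            loops.append(Loop(a, b, tags))
    return loops


def write_loops(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor_a, lp.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{lp.tags}\n"
            )


# ---------------------------------------------------------------------------
# MEME motif format
# ---------------------------------------------------------------------------
# The established MEME parsers silently renormalize probability rows; the
# pipeline's contract is to reject rows whose sum deviates from 1 by more
# than 1e-4 (and renormalize smaller drift), so the block parser lives here.

def read_pwms(path: str | Path) -> list[PWMRecord]:
    """Parse a MEME motif file into :class:`PWMRecord` objects, in file order."""
    path = Path(path)
    records: list[PWMRecord] = []
    motif_id = tf_name = None
    rows: list[list[float]] = []
    expect_width: int | None = None

    def flush() -> None:
        nonlocal motif_id, tf_name, rows, expect_width
        if motif_id is None:
            return
        if not rows:
            raise ParseError(f"{path}: MOTIF {motif_id} has no probability matrix")
        if expect_width is not None and len(rows) != expect_width:
            raise ParseError(
                f"{path}: MOTIF {motif_id}: expected {expect_width} rows, got {len(rows)}"
            )
        records.append(PWMRecord(motif_id, tf_name or motif_id, np.array(rows)))
        motif_id = tf_name = None
        rows = []
        expect_width = None

    with open(path) as fh:
        in_matrix = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("MOTIF"):
                flush()
                parts = stripped.split()
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: MOTIF line without identifier")
                motif_id = parts[1]
                tf_name = parts[2] if len(parts) > 2 else parts[1]
                in_matrix = False
            elif stripped.startswith("letter-probability matrix"):
                in_matrix = True
                for tok_key, tok_val in zip(stripped.split()[:-1], stripped.split()[1:]):
                    if tok_key == "w=":
                        expect_width = int(tok_val)
            elif in_matrix and stripped and stripped[0] in "0123456789.":
                try:
                    vals = [float(x) for x in stripped.split()]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad matrix row") from exc
                if len(vals) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 columns in matrix row")
                rows.append(vals)
            elif in_matrix and not stripped:
                in_matrix = False
        flush()
    if not records:
        raise ParseError(f"{path}: no MOTIF blocks found")
    return records


def write_pwms(pwms: Iterable[PWMRecord], path: str | Path,
               background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*background))
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id} {p.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width} nsites= 20 E= 0\n")
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# PPI edge tables
# ---------------------------------------------------------------------------

def read_edge_table(path: str | Path) -> list[PPIEdge]:
    """Read a TSV of PPI records (protein_a, protein_b, source, score_or_evidence).

    Self edges are skipped (with a logged count); exact duplicates
    collapse to one record.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_a", "protein_b", "source", "score_or_evidence"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    edges: dict[tuple, PPIEdge] = {}
    n_self = 0
    for row in df.itertuples(index=False):
        if row.protein_a == row.protein_b:
            n_self += 1
            continue
        if row.source == "string_db":
            edge = PPIEdge(row.protein_a, row.protein_b, "string_db",
                           score=float(row.score_or_evidence))
        elif row.source == "biogrid":
            edge = PPIEdge(row.protein_a, row.protein_b, "biogrid",
                           evidence=str(row.score_or_evidence))
        else:
            raise ValidationError(f"{path}: unknown source token {row.source!r}")
        edges[(edge.protein_a, edge.protein_b, edge.source,
               edge.score, edge.evidence)] = edge
    if n_self:
        log.warning("%s: skipped %d self edges", path, n_self)
    return list(edges.values())


def write_edge_table(edges: Iterable[PPIEdge], path: str | Path) -> None:
    rows = []
    for e in edges:
        val = e.score if e.source == "string_db" else e.evidence
        rows.append((e.protein_a, e.protein_b, e.source, val))
    pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "source", "score_or_evidence"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression tables and FASTA
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression table (TSV, first column = gene name)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene names in expression table")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain in-memory FASTA: name -> uppercase sequence."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
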