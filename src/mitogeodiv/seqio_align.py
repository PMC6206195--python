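"""FASTA alignment I/O, gap-column elimination, and partition concatenation.

An :class:`Alignment` is an ordered set of equal-length sequences over the
alphabet ``{A, C, G, T, -, N}``.  ``-`` marks an alignment gap; ``N`` marks
missing data (e.g. a locus that was never sequenced for a specimen).  All
column coordinates in this package are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    DuplicateIdentifierError,
    EmptyAlignmentError,
)

ALPHABET = frozenset("ACGT-N")
#: Residues that carry information for distance computations.
VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Alignment:
    """Ordered multiple-sequence alignment with unique names.

    Parameters
    ----------
    names
        Sequence identifiers, in input order.
    rows
        Uppercase sequence strings, one per name, all the same length.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentShapeError("names and rows differ in count")
        if not self.rows:
            raise EmptyAlignmentError("alignment has no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        if lengths == {0}:
            raise EmptyAlignmentError("alignment has zero columns")
        if len(set(self.names)) != len(self.names):
            seen: set[str] = set()
            dup = next(n for n in self.names if n in seen or seen.add(n))
            raise DuplicateIdentifierError(f"duplicate identifier: {dup!r}")
        for name, row in zip(self.names, self.rows):
            bad = set(row) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"illegal character(s) {sorted(bad)} in record {name!r}"
                )

    @property
    def length(self) -> int:
        """Number of columns (bp)."""
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def to_matrix(self) -> np.ndarray:
        """Return the alignment as a (n, L) uint8 matrix of ASCII codes."""
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_sequences, self.length)

    def subset(self, names: Sequence[str]) -> "Alignment":
        """Alignment restricted to ``names``, in the order given."""
        return Alignment(tuple(names), tuple(self.row(n) for n in names))


@dataclass(frozen=True)
class PartitionSpec:
    """Half-open column interval [start, end) of a named partition."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AlignmentShapeError(
                f"invalid partition interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _make_alignment(names: Iterable[str], rows: Iterable[str]) -> Alignment:
    return Alignment(tuple(names), tuple(r.upper() for r in rows))


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Input order is preserved, lowercase is mapped to uppercase, and any
    character outside ``{A, C, G, T, -, N}`` is rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyAlignmentError(f"no FASTA records in {path}")
    return _make_alignment(
        (r.id for r in records), (str(r.seq) for r in records)
    )


def write_fasta(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA with 60-column line wrap."""
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def eliminate_gap_positions(aln: Alignment) -> Alignment:
    """Drop every column in which at least one row carries a gap.

    Emulates stripping the poorly aligned gapped flanks of a control-region
    alignment down to its common core; columns are removed whenever any row
    has ``-``.  Row order and names are preserved.
    """
    mat = aln.to_matrix()
    keep = ~(mat == ord("-")).any(axis=0)
    if not keep.any():
        raise EmptyAlignmentError("every column contains a gap")
    kept = mat[:, keep]
    rows = [bytes(r).decode("ascii") for r in kept]
    return Alignment(aln.names, tuple(rows))


def concatenate(
    parts: Sequence[Alignment], pad: str = "N"
) -> tuple[Alignment, list[PartitionSpec]]:
    """Concatenate partitions, padding specimens absent from a partition.

    A specimen missing from some partition (e.g. only one locus amplified)
    receives ``pad`` across that partition's columns.  The union of names is
    ordered by first appearance across partitions.
    """
    if not parts:
        raise EmptyAlignmentError("no partitions to concatenate")
    if pad not in ALPHABET or pad == "-":
        raise AlphabetError(f"pad symbol {pad!r} not a valid missing state")
    names: list[str] = []
    for part in parts:
        for n in part.names:
            if n not in names:
                names.append(n)
    specs: list[PartitionSpec] = []
    offset = 0
    pieces: dict[str, list[str]] = {n: [] for n in names}
    for i, part in enumerate(parts):
        specs.append(PartitionSpec(f"partition_{i + 1}", offset, offset + part.length))
        lookup = dict(zip(part.names, part.rows))
        filler = pad * part.length
        for n in names:
            pieces[n].append(lookup.get(n, filler))
        offset += part.length
    rows = ["".join(pieces[n]) for n in names]
    return Alignment(tuple(names), tuple(rows)), specs


def slice_partition(aln: Alignment, spec: PartitionSpec) -> Alignment:
    """Extract one partition's columns from a concatenated alignment."""
    if spec.end > aln.length:
        raise AlignmentShapeError(
            f"partition [{spec.start}, {spec.end}) exceeds alignment length "
            f"{aln.length}"
        )
    return Alignment(aln.names, tuple(r[spec.start:spec.end] for r in aln.rows))


def write_partition_table(specs: Sequence[PartitionSpec], path: str | Path) -> None:
    """Write partitions as a TSV: name, start, end (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\n")
        for s in specs:
            fh.write(f"{s.name}\t{s.start}\t{s.end}\n")
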